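# Methods

This note documents the models and procedures implemented in `stromasig`,
the assumptions they rest on, the defaults and why, and what the synthetic
data do and do not establish about behavior on real cohorts.

## Survival-signature discovery

### Model and procedure

The discovery pipeline assumes a normalized, log-scale expression matrix
(probes or genes × samples) whose survival annotation is right-censored:
per sample a follow-up time in months and an event indicator. Upstream
normalization and batch correction are treated as already done; the
pipeline starts from the post-normalization matrix.

Stages, in order:

1. **Variance filter.** Keep the fraction of rows with the highest sample
   variance (default `keep_fraction = 0.5`). No principled cutoff exists
   for this step; 0.5 is ordinary array practice and the setting is
   exposed. On the synthetic cohorts the recovery results are insensitive
   to values in 0.3–1.0 because planted signal genes carry excess variance
   and survive any reasonable cut.
2. **Probe collapse.** One row per gene: the highest-variance probe wins,
   variance ties go to the lexicographically smallest probe id (a
   deterministic, documented tie-break). Unmapped probes are dropped with
   a logged count.
3. **FAST screening.** For standardized expression z the statistic is the
   Cox partial-likelihood score at β = 0 divided by n, computed through
   the martingale-residual identity s = z·w/n with
   w_j = δ_j − Ĥ(t_j) (Ĥ the Nelson–Aalen cumulative hazard). Samples
   whose time equals an event time are in that risk set (Breslow-style tie
   handling). The null distribution comes from jointly permuting the
   (time, event) pairs against the sample axis; because the statistic is
   linear in w, one permutation stream is shared by all transcripts and
   the screen is a single matrix product per permutation block. P-values
   are add-one: p = (1 + #{|s*| ≥ |s|}) / (B + 1), never zero. Screening
   is two-sided on |s|, since both hazardous and protective transcripts
   are wanted. Default B = 10,000 (desk-scale; the screen is exact in the
   permutation limit and B only sets the p-value resolution, 1/(B+1)).
4. **Local FDR selection.** The local false discovery rate at p is
   η̂₀ / f̂(p), where f̂ is the Grenander estimator — the non-increasing
   density given by the slopes of the least concave majorant of the
   empirical CDF of the p-values — and η̂₀ = #{p > 0.8} / (0.2 m) is the
   null proportion read off the flat tail. Values are clipped to [0, 1];
   transcripts with lfdr < 0.15 are selected. Working on p-values (rather
   than on the signed statistics) makes the estimator one-sided and
   monotone: lfdr is non-decreasing in p by construction. At least 50
   p-values are required for the density to have mass.
5. **PCA metagenes.** Selected rows are mean-centered across samples and
   decomposed by SVD; components are ordered by explained variance, and a
   sample's component score is the loading-weighted sum of its centered
   expression. The raw SVD sign is fixed deterministically
   (largest-magnitude loading positive) and then the *hazard-positive*
   orientation is applied: the component sign is chosen so the FAST
   statistic of the score vector is positive, i.e. a higher score means a
   higher hazard. Transcripts with positive oriented loadings form the
   hazardous set, negative the protective set; exact-zero loadings go to
   the protective set with a warning. The partition is asserted exhaustive
   and disjoint on every model.
6. **Leave-one-out cross-validation.** For each held-out sample the whole
   pipeline is re-run on the remainder and the held-out sample is scored
   with the fold's oriented loadings (centered by training row means).
   Folds that select no transcript are skipped and counted. The
   out-of-fold score vector is then itself tested with the FAST statistic
   and its permutation p-value. Inside folds the permutation count is
   reduced (default 1,000) for tractability; only the fold-level
   *selection* uses the reduced count, the final association p-value uses
   the full count.

### Risk scoring and cross-species transfer

A fitted signature scores a new cohort by z-scoring each matched gene
across samples, multiplying by the hazard-oriented loading and summing per
sample. Matching is case-insensitive exact symbol matching (with an
optional user ortholog table), which handles the human/mouse convention
(`LOX` ↔ `Lox`) without a lookup service. Unmatched genes are dropped and
the matched fraction reported; zero-variance genes are dropped with a
warning since their z-score is undefined. Scores sum to zero within a
cohort by centering.

### Hypoxia meta-signature

From a GMT collection, the sets whose names contain "HYPOXIA"
(case-insensitive) are selected; genes present in strictly more than 20%
of those sets form the meta-signature ("more than" is a strict
inequality, so exactly 20% is excluded). A cohort is scored on the first
principal axis of the mean-centered meta-signature genes. The published
description conflates loadings and scores; here the sample-side
coordinates are the scores and the gene-side weights carry the
orientation: the whole component is flipped if the anchor gene (VEGFA, a
canonical hypoxia-induced transcript) has a negative weight, making the
rule idempotent. Scoring fails loudly if the anchor is absent, because
the orientation rule cannot be applied.

The reference meta-signature sizes (22 hypoxia sets, 1,377 union genes,
55 meta-signature genes from MSigDB v3.0 c2) depend on licensed external
data and are not reproduced in tests; the logic is exercised on synthetic
collections with planted membership frequencies.

### Over-representation

Each gene set, intersected with the universe, is tested with the
hypergeometric upper tail P(X ≥ k); empty-after-intersection sets are
skipped. The universe defaults to the collection's declared universe (or
the union of sets and query) and should in practice be the filtered,
collapsed array. P-values are corrected with Benjamini–Yekutieli (BH
step-up × Σ 1/i), which keeps FDR control under the arbitrary positive
and negative dependence of overlapping gene sets; significance is strict
`adjusted < α`. All tested sets are corrected jointly.

### Supporting statistics

Kaplan–Meier estimation and the log-rank test are delegated to lifelines,
Mann–Whitney and Spearman to scipy; the Yates-corrected chi-square is the
closed form N(max(|ad−bc|−N/2, 0))²/((a+b)(c+d)(a+c)(b+d)) with a 1-df
upper tail, cross-checked against an independent implementation in the
tests. Median survival is the first time the curve reaches 0.5 or below
(conservative convention). Mann–Whitney is exact for min(n, m) ≤ 8
without ties — the mouse-cohort regime — and tie-corrected normal
otherwise.

## Collagen texture

### Procedure

A stack is reduced to a maximum-intensity projection; Otsu's threshold on
the projection gives the fibrillar mask and the percent area. Texture is
computed only from pixel pairs with *both* pixels in the mask (out-of-mask
pixels are excluded from pair counting, not zero-filled, so background
does not bias the parameters): in-mask intensities are quantized to 64
gray levels over the in-mask range, and a symmetric, normalized
co-occurrence matrix is built for every offset distance 1..100 px in four
directions (0°, 45°, 90°, 135°). Masking is implemented by assigning
out-of-mask pixels a sentinel gray level and discarding its row and
column from the co-occurrence counts. Diagonal offsets follow the
euclidean-distance convention (offset components rounded from d·sin θ,
d·cos θ), so a given distance means the same physical separation in every
direction.

Five parameters are computed per (distance, direction): contrast,
correlation, energy (angular second moment), homogeneity (inverse
difference moment) and entropy — a conventional Haralick five; the
original set is not named in the source description. Distances with no
in-mask pair are recorded as missing and skipped by the fits.

### Decay model

Each direction-averaged parameter curve f(d) is fit by least squares to
A₁e^(−d/λ₁) + A₂e^(−d/λ₂) + c with A, λ ≥ 0 and a bounded non-negative
offset, using 10 multistarts with log-uniform decay scales in [1, D]
(deterministic given the seed); the best-residual fit is kept and
components are reported ordered by scale. The scalar summary is the
amplitude-weighted mean decay distance (A₁λ₁ + A₂λ₂)/(A₁ + A₂); a
component whose amplitude is negligible (< 10⁻⁶ of the total) is excluded
so that a genuinely single-exponential curve reports its one true scale.

Curves that rise with distance (contrast, entropy) cannot be represented
by this non-negative-amplitude decay model; they are fit on their
reflection (max − value), which has the same decay scales, and flagged
`inverted`. The default headline parameter is **correlation**: it decays
directly — it is literally the spatial decorrelation of the signal versus
offset — and across synthetic replicates its fitted decay distance
separates planted correlation lengths of 2, 6 and 18 px with
non-overlapping interquartile ranges, whereas the reflected contrast fit
leaves the two scales poorly identified (its plateau and the slow
component trade off). All five fits are reported.

Depth profiles binarize each slice against one global threshold (Otsu
over the stack by default, or a user rule) and report per-slice
foreground percent and total foreground pixels.

## Synthetic data: what it emulates, and what it does not

`generate_survival_cohort` emulates a post-normalization cohort of
(default) 120 samples × 2,000 genes. A latent factor loads on 300
signature genes with Gaussian loadings (unit scale); additional factors
(default 3 total) load on random gene subsets to mimic non-prognostic
covariation; unit-variance Gaussian noise is added, plus optional additive
per-(gene, batch) shifts emulating residual batch structure. Survival is
exponential proportional hazards: rate 0.05/month at factor zero (≈14-
month median, the resected-PDAC range) times exp(1.0 per SD of factor 1).
Censoring is independent exponential with its rate solved numerically so
the expected censoring fraction is 0.3; the follow-up pattern of any real
registry cohort is not modeled, as the source material does not state one.
All generators are pure functions of their spec including the seed.

`generate_ortholog_cohort` simulates cross-species transfer by title-
casing a fraction of the signature symbols (random dropout for the rest)
and shifting mapped hazardous-gene expression by +effect·SD in
metastatic samples. `generate_geneset_collection` plants exact membership
frequencies across hypoxia-named sets with the anchor gene in all of
them. `generate_shg_stack` draws anti-aliased fiber segments with
per-fiber depth bands, blurs them with a Gaussian whose scale sets the
spatial correlation length, and thresholds the projection at the quantile
matching the target area fraction, with a pedestal that keeps foreground
and background bimodal for automatic thresholding; it is artifact
plumbing with a controllable decay scale, not an optical model of
second-harmonic generation.

Consequences for interpretation: passing recovery tests shows the
pipeline recovers linear-Gaussian planted structure under proportional
hazards with independent censoring. It does not establish performance
under heavy-tailed expression, informative censoring, non-linear
hazard–expression relationships, or imaging artifacts (speckle,
depth-dependent attenuation, anisotropic PSFs), none of which the
generators produce.

## Numerical choices and edge cases

- Standardization uses the sample SD (ddof = 1); constant expression rows
  get statistic 0 with a warning rather than NaN propagation.
- Permutation p-values are add-one valued in {1/(B+1), …, 1}.
- The Grenander density is computed by an exact concave-majorant scan;
  lfdr values are clipped to [0, 1] and η̂₀ to ≤ 1.
- PCA refuses more components than the numerical rank (singular values
  below s₁·10⁻¹²).
- Quantile stratification uses type-7 (linear interpolation) empirical
  quantiles; "low" is ≤ the lower cut, "high" strictly above the upper
  cut; degenerate (all-equal) scores are an error.
- GLCM correlation of a degenerate (zero-variance) co-occurrence matrix
  is defined as 1.
- A constant image yields an empty mask and 0% area with a warning; a
  constant stack in the depth profile falls back to threshold 0 so a
  uniformly positive stack is 100% foreground.
- All written numbers carry 10 significant digits so reruns diff cleanly.

## Problem sizes used in the automated checks

Tests and the acceptance script run the discovery conditions at
n = 120 samples × 2,000 genes with 1,000-permutation screens (and
1,000-permutation fold screens in cross-validation), 20 replicate seeds
for recovery medians and detection rates, 10 replicates per correlation
length for texture recovery, and 192×192×8 image stacks with 100 offset
distances. These sizes give stable medians and complete in minutes; the
permutation count only coarsens the p-value grid relative to larger runs,
and the default `n_perm = 10,000` (or more) is recommended for real
cohorts.

## Known limitations

- The local-FDR estimator is a Grenander/tail-proportion variant; other
  lfdr estimators (spline-based, two-component parametric mixtures) can
  give mildly different selections near the threshold.
- Permutation p-values of strongly correlated transcripts are themselves
  correlated; the selection controls lfdr marginally, not family-wise.
- Symbol-based ortholog matching misses genes whose human/mouse symbols
  differ beyond case; supply an explicit ortholog table for those.
- The double-exponential fit is a phenomenological summary; its two
  scales are weakly identified when the true decay is single-exponential
  or when the curve has not decayed appreciably within the distance
  window.
- The texture pipeline assumes isotropic pixel spacing; physical units
  are pixels throughout.
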