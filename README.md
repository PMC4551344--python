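# stromasig

Tools for two linked analyses of the tumor stroma in pancreatic ductal
adenocarcinoma (PDAC) and similar settings:

1. **Transcriptomics** — discover a principal-component survival signature
   from a bulk expression cohort (FAST-statistic permutation screening,
   local-FDR transcript selection, PCA metagenes, leave-one-out
   cross-validation), transfer it across cohorts and species as a
   per-sample risk score, build and apply a hypoxia meta-signature from a
   gene-set collection, and test gene-set over-representation.
2. **Imaging** — quantify fibrillar collagen in second-harmonic-generation
   (SHG) image stacks: maximum projection, automatic masking, gray-level
   co-occurrence (GLCM) texture parameters across offset distances, a
   double-exponential decay fit, and the weighted mean decay distance as a
   scalar collagen-texture score.

The package is aimed at computational biologists who want these bespoke
pipeline stages as tested, reusable functions, exercisable end to end on
synthetic data with planted ground truth.

## The statistics at the core

**Screening.** For transcript *g* with standardized expression
*z<sub>g</sub>*, survival times *t* and event indicators *δ*, the FAST
statistic is

s*<sub>g</sub>* = (1/n) Σ<sub>i: δ<sub>i</sub>=1</sub>
[ z<sub>g,i</sub> − mean { z<sub>g,j</sub> : t<sub>j</sub> ≥ t<sub>i</sub> } ],

the Cox partial-likelihood score at β = 0 scaled by 1/n. Significance
comes from jointly permuting the (t, δ) pairs against samples (add-one
p-values, one permutation stream shared across transcripts); transcripts
are kept when their local false discovery rate — estimated from the
permutation p-values with a Grenander (monotone) density and a tail-based
null proportion — falls below 0.15.

**Metagenes.** Selected transcripts are mean-centered and decomposed by
PCA. The leading component is oriented so that a higher score means a
higher hazard; transcripts with positive oriented loadings form the
hazardous set, the rest the protective set. A new cohort's **risk score**
is Σ<sub>g</sub> w<sub>g</sub> z<sub>g,sample</sub> over matched signature
genes (each gene z-scored across samples).

**Hypoxia meta-signature.** Genes present in strictly more than 20% of the
hypoxia-named sets of a GMT collection; samples are scored by the first
principal axis of the meta-signature genes, sign-anchored so that VEGFA
carries a positive weight.

**Texture decay.** Direction-averaged GLCM parameter curves
*f*(d) over offset distances d = 1..100 px are fit by
A₁e^(−d/λ₁) + A₂e^(−d/λ₂) + c (A, λ ≥ 0); the weighted mean decay
distance is (A₁λ₁ + A₂λ₂)/(A₁ + A₂).

## Worked example

```python
from stromasig.synthetic import CohortSpec, generate_survival_cohort
from stromasig.discovery import DiscoveryConfig, discover_signature
from stromasig.scoring import risk_score, stratify_scores
from stromasig.survival import km_estimate, logrank_test

cohort, truth = generate_survival_cohort(CohortSpec(seed=3))
model, screen = discover_signature(cohort, DiscoveryConfig(n_perm=1000, seed=3))
print(len(model.hazardous_set), len(model.protective_set))
scores = stratify_scores(risk_score(cohort, model), "tertile")
low = scores.stratum == "low"
high = scores.stratum == "high"
print(round(km_estimate(cohort.time[low], cohort.event[low]).median, 1),
      round(km_estimate(cohort.time[high], cohort.event[high]).median, 1))
print(logrank_test([(cohort.time[low], cohort.event[low]),
                    (cohort.time[high], cohort.event[high])]))
```

prints

```
91 73
43.3 4.3
(50.01046732838478, 1.5292800416612205e-12)
```

— from a 120-sample cohort with a planted hazardous metagene, the screen
keeps 164 transcripts (91 hazardous / 73 protective), and the risk-score
tertiles separate survival sharply: median survival 43.3 months in the
lowest tertile versus 4.3 months in the highest, log-rank χ² = 50.0,
p ≈ 1.5 × 10⁻¹².

The same stages are available from the shell:

```bash
stromasig simulate --seed 3 --out work/
stromasig discover --expr work/expression.tsv --clinical work/clinical.tsv \
    --n-perm 10000 --seed 3 --out work/sig/
stromasig survtest chi2 --table 0,8,3,0
stromasig texture --stack stack.tif --out work/tex/
```

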