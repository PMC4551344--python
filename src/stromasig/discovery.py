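"""Discovery of a principal-component survival signature.

The pipeline mirrors the common microarray practice for deriving a
prognostic metagene from a resected-tumor cohort:

1. variance-filter probes, collapse to one row per gene (highest-variance
   probe);
2. screen each transcript for univariate survival association with the
   FAST statistic — the Cox partial-likelihood score at beta = 0, scaled by
   1/n — against a permutation null in which the (time, event) pairs are
   jointly permuted;
3. select transcripts whose local false discovery rate, estimated from the
   permutation p-values with a Grenander (monotone) density, falls below a
   threshold (default 0.15);
4. decompose the selected transcripts into metagenes by PCA, orient the
   leading component so that a higher score means a higher hazard, and
   split it into hazardous (positive oriented loading) and protective
   (negative) transcript sets;
5. assess each component by leave-one-out cross-validation of the entire
   pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import ExpressionCohort, ScreenResult, SignatureModel, check_screen_result

__all__ = [
    "DiscoveryConfig",
    "variance_filter",
    "collapse_probes",
    "fast_statistic",
    "fast_score_weights",
    "permutation_pvalue",
    "local_fdr",
    "screen_transcripts",
    "pca_metagenes",
    "orient_component",
    "split_signature",
    "discover_signature",
    "evaluate_components_loocv",
    "LoocvResult",
]

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryConfig:
    """Tunable parameters of the discovery pipeline."""

    keep_fraction: float = 0.5
    n_perm: int = 10_000
    lfdr_threshold: float = 0.15
    n_components: int = 1
    #: reduced permutation count used inside each cross-validation fold
    cv_n_perm: int = 1_000
    seed: int = 0


# ---------------------------------------------------------------------------
# filtering and probe collapse

def variance_filter(cohort: ExpressionCohort, keep_fraction: float) -> ExpressionCohort:
    """Keep the ``keep_fraction`` of rows with the highest sample variance.

    Row order is preserved. Ties are broken by original row order.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if cohort.n_samples < 2:
        raise ValueError("variance undefined with fewer than 2 samples")
    var = cohort.matrix.var(axis=1, ddof=1).to_numpy()
    n_keep = max(1, int(round(keep_fraction * len(var))))
    keep_idx = np.sort(np.argsort(-var, kind="stable")[:n_keep])
    return cohort.with_matrix(cohort.matrix.iloc[keep_idx])


def collapse_probes(cohort: ExpressionCohort) -> ExpressionCohort:
    """Collapse probe rows to one row per gene (highest-variance probe).

    Unmapped probes are dropped with a logged count. Variance ties are
    broken by the lexicographically smallest probe id.
    """
    if not cohort.probe_to_gene:
        raise ValueError("probe_to_gene map is required to collapse probes")
    p2g = cohort.probe_to_gene
    var = cohort.matrix.var(axis=1, ddof=1)
    mapped = [p for p in cohort.row_ids if p in p2g]
    n_dropped = len(cohort.row_ids) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise ValueError("no probes map to a gene")
    best: dict = {}
    for probe in mapped:
        gene = p2g[probe]
        cur = best.get(gene)
        if cur is None or (var[probe], _neg_lex(probe)) > (var[cur], _neg_lex(cur)):
            best[gene] = probe
    # preserve the input probe order of the winning probes
    order = [p for p in mapped if best[p2g[p]] == p]
    matrix = cohort.matrix.loc[order]
    matrix.index = [p2g[p] for p in order]
    return cohort.with_matrix(matrix, probe_to_gene=None)


class _neg_lex(str):
    """Reverses lexicographic order so max() prefers the smallest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# FAST screening

def fast_score_weights(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-sample weights w such that the FAST statistic is z . w / n.

    w_j = event_j - H(t_j), where H is the Nelson-Aalen cumulative hazard
    (Breslow tie handling: risk set is {j : t_j >= t_i}). These are the
    Cox martingale residuals at beta = 0, so z . w equals the partial-
    likelihood score at zero.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events: survival association undefined")
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    n = len(time)
    # events per unique time and at-risk counts
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    d = np.add.reduceat(e_sorted, first_idx)
    at_risk = n - first_idx
    increments = d / at_risk
    cumhaz_at_uniq = np.cumsum(increments)
    # H(t_j) for each sample: cumulative hazard at its own time
    pos = np.searchsorted(uniq, time, side="right") - 1
    H = cumhaz_at_uniq[pos]
    return event - H


def _standardize_rows(matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores; zero-variance rows become all-zero."""
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    sd = np.where(sd == 0, 1.0, sd)
    z = (matrix - mean) / sd
    z[degenerate] = 0.0
    return z, degenerate


def fast_statistic(expression: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> float:
    """FAST univariate survival-screening statistic for one transcript.

    Standardizes the expression vector and returns (1/n) times the Cox
    partial-likelihood score at beta = 0 of the z-scores. Constant
    expression yields 0 with a warning.
    """
    expression = np.asarray(expression, dtype=float)
    z, degenerate = _standardize_rows(expression[None, :])
    if degenerate[0]:
        warnings.warn("constant expression vector: FAST statistic set to 0")
        return 0.0
    w = fast_score_weights(time, event)
    return float(z[0] @ w / len(expression))


def permutation_pvalue(matrix: np.ndarray, time: np.ndarray,
                       event: np.ndarray, n_perm: int, seed: int = 0,
                       chunk: int = 2000):
    """Two-sided permutation p-values of the FAST statistic per row.

    The (time, event) pairs are jointly permuted against the samples; the
    same permutation stream is shared across all transcripts. Returns
    (observed statistics, add-one p-values): p = (1 + #{|s*| >= |s|}) /
    (n_perm + 1), so p is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[1]
    z, _ = _standardize_rows(matrix)
    w = fast_score_weights(time, event)
    obs = z @ w / n
    rng = np.random.default_rng(seed)
    exceed = np.zeros(matrix.shape[0], dtype=np.int64)
    done = 0
    abs_obs = np.abs(obs)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.empty((n, b))
        for j in range(b):
            perms[:, j] = w[rng.permutation(n)]
        stats = np.abs(z @ perms / n)
        exceed += (stats >= abs_obs[:, None]).sum(axis=1)
        done += b
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    return obs, pvals


# ---------------------------------------------------------------------------
# local false discovery rate

def _grenander_density(p_sorted: np.ndarray) -> np.ndarray:
    """Grenander estimate f(p_i): slopes of the least concave majorant of
    the empirical CDF, evaluated at each sorted p-value."""
    m = len(p_sorted)
    # unique support points with CDF values; anchor at (0, 0) and (1, 1)
    x_u, counts = np.unique(p_sorted, return_counts=True)
    y_u = np.cumsum(counts) / m
    xs = np.concatenate(([0.0], x_u))
    ys = np.concatenate(([0.0], y_u))
    if xs[-1] < 1.0:
        xs = np.append(xs, 1.0)
        ys = np.append(ys, 1.0)
    # upper (concave) hull by monotone scan
    hull = [0]
    for i in range(1, len(xs)):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = ((xs[i1] - xs[i0]) * (ys[i] - ys[i0])
                     - (ys[i1] - ys[i0]) * (xs[i] - xs[i0]))
            if cross >= 0:  # middle point below the chord: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    hx = xs[hull]
    hy = ys[hull]
    slopes = np.diff(hy) / np.diff(hx)
    seg = np.clip(np.searchsorted(hx, p_sorted, side="left") - 1,
                  0, len(slopes) - 1)
    return slopes[seg]


def local_fdr(p_values: Sequence[float], eta0_tail: float = 0.8):
    """Local false discovery rate from p-values.

    lfdr(p) = eta0 / f(p), where f is the Grenander (non-increasing)
    density of the p-values and eta0 the null proportion estimated from
    the flat tail p > ``eta0_tail``. Values are clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) < 50:
        raise ValueError("local FDR estimation needs at least 50 p-values")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    f = _grenander_density(p_sorted)
    eta0 = min(1.0, float((p > eta0_tail).mean() / (1.0 - eta0_tail)))
    lfdr_sorted = np.clip(eta0 / np.maximum(f, 1e-300), 0.0, 1.0)
    out = np.empty_like(lfdr_sorted)
    out[order] = lfdr_sorted
    return out


def screen_transcripts(cohort: ExpressionCohort, n_perm: int = 10_000,
                       lfdr_threshold: float = 0.15, seed: int = 0) -> ScreenResult:
    """Screen every transcript by |FAST| permutation p-value and local FDR."""
    if cohort.time is None:
        raise ValueError("cohort has no survival annotation")
    stats, pvals = permutation_pvalue(
        cohort.matrix.to_numpy(), cohort.time.to_numpy(),
        cohort.event.to_numpy(), n_perm=n_perm, seed=seed)
    lfdr = local_fdr(pvals)
    df = pd.DataFrame(
        {"statistic": stats, "p_value": pvals, "lfdr": lfdr,
         "selected": lfdr < lfdr_threshold},
        index=cohort.row_ids)
    return check_screen_result(df)


# ---------------------------------------------------------------------------
# PCA metagenes

def pca_metagenes(matrix: pd.DataFrame, n_components: int = 1):
    """Decompose (transcripts x samples) expression into PCA metagenes.

    Rows are mean-centered across samples before the decomposition.
    Returns (loadings, scores, explained_variance_ratio) with components
    ordered by explained variance; score_c = loadings_c . centered matrix.
    The raw SVD sign is made deterministic (largest-|loading| positive);
    the hazard-positive orientation is applied separately.
    """
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    if matrix.shape[0] < n_components:
        raise ValueError("more components than transcripts")
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if n_components > max(rank, 1):
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    u = u[:, :n_components]
    s = s[:n_components]
    # deterministic sign: the largest-magnitude loading is positive
    for c in range(n_components):
        k = np.argmax(np.abs(u[:, c]))
        if u[k, c] < 0:
            u[:, c] = -u[:, c]
    scores = u.T @ xc
    total_var = (xc ** 2).sum()
    evr = (s ** 2) / total_var if total_var > 0 else np.zeros_like(s)
    comp_ix = [f"PC{c + 1}" for c in range(n_components)]
    loadings = pd.DataFrame(u, index=matrix.index, columns=comp_ix)
    scores = pd.DataFrame(scores.T, index=matrix.columns, columns=comp_ix)
    return loadings, scores, evr


def orient_component(scores: np.ndarray, time: np.ndarray,
                     event: np.ndarray) -> int:
    """Hazard-positive orientation: +1 if the FAST statistic of the score
    vector is already non-negative, else -1."""
    s = fast_statistic(np.asarray(scores, float), time, event)
    return 1 if s >= 0 else -1


def split_signature(loadings: pd.Series, orientation: int,
                    component_index: int = 0,
                    cv_statistic: Optional[float] = None,
                    cv_pvalue: Optional[float] = None) -> SignatureModel:
    """Partition oriented loadings into hazardous and protective sets."""
    if orientation not in (-1, 1):
        raise ValueError("component must be oriented (+1/-1) first")
    oriented = loadings.to_numpy() * orientation
    ids = list(loadings.index)
    hazardous = {g for g, w in zip(ids, oriented) if w > 0}
    protective = {g for g, w in zip(ids, oriented) if w < 0}
    zeros = set(ids) - hazardous - protective
    if zeros:
        warnings.warn(f"{len(zeros)} zero loadings assigned to protective set")
        protective |= zeros
    return SignatureModel(
        transcript_ids=ids, loadings=loadings.to_numpy(),
        component_index=component_index, orientation=orientation,
        hazardous_set=frozenset(hazardous), protective_set=frozenset(protective),
        cv_statistic=cv_statistic, cv_pvalue=cv_pvalue)


# ---------------------------------------------------------------------------
# full pipeline

def _prepare(cohort: ExpressionCohort, keep_fraction: float) -> ExpressionCohort:
    out = variance_filter(cohort, keep_fraction)
    if out.probe_to_gene:
        out = collapse_probes(out)
    return out


def discover_signature(cohort: ExpressionCohort,
                       config: Optional[DiscoveryConfig] = None):
    """Run the full discovery pipeline on a cohort.

    Returns (SignatureModel, ScreenResult). Raises if no transcript
    survives the local-FDR selection.
    """
    config = config or DiscoveryConfig()
    prepared = _prepare(cohort, config.keep_fraction)
    screen = screen_transcripts(prepared, n_perm=config.n_perm,
                                lfdr_threshold=config.lfdr_threshold,
                                seed=config.seed)
    selected = screen.index[screen["selected"]]
    if len(selected) == 0:
        raise ValueError("no transcripts pass the local-FDR selection")
    n_comp = min(config.n_components, len(selected))
    loadings, scores, _ = pca_metagenes(prepared.matrix.loc[selected], n_comp)
    orientation = orient_component(scores.iloc[:, 0].to_numpy(),
                                   prepared.time.to_numpy(),
                                   prepared.event.to_numpy())
    model = split_signature(loadings.iloc[:, 0], orientation)
    return model, screen


@dataclass
class LoocvResult:
    """Out-of-fold component scores and their survival association."""

    scores: pd.DataFrame        # samples x components, NaN for skipped folds
    statistic: pd.Series        # FAST statistic per component
    p_value: pd.Series          # permutation p per component
    n_skipped: int


def evaluate_components_loocv(cohort: ExpressionCohort,
                              config: Optional[DiscoveryConfig] = None) -> LoocvResult:
    """Leave-one-out cross-validation of the whole discovery pipeline.

    For every held-out sample, the pipeline (filter, collapse, screen,
    select, PCA, orient) is re-run on the remaining samples and the
    held-out sample is scored with the fold's loadings (centering by the
    training row means). Screening inside folds uses the reduced
    ``cv_n_perm`` permutation count. The out-of-fold score vector of each
    component is then tested for survival association with the FAST
    statistic and its permutation p-value.
    """
    config = config or DiscoveryConfig()
    if cohort.n_samples < 10:
        raise ValueError("leave-one-out evaluation needs at least 10 samples")
    samples = list(cohort.sample_ids)
    comp_ix = [f"PC{c + 1}" for c in range(config.n_components)]
    oof = pd.DataFrame(np.nan, index=samples, columns=comp_ix)
    n_skipped = 0
    for i, held in enumerate(samples):
        train = cohort.subset_samples([s for s in samples if s != held])
        prepared = _prepare(train, config.keep_fraction)
        fold_seed = (config.seed * 100_003 + i) % (2 ** 31)
        screen = screen_transcripts(prepared, n_perm=config.cv_n_perm,
                                    lfdr_threshold=config.lfdr_threshold,
                                    seed=fold_seed)
        selected = screen.index[screen["selected"]]
        if len(selected) == 0:
            logger.warning("fold %d (%s): no transcripts selected; skipped",
                           i, held)
            n_skipped += 1
            continue
        n_comp = min(config.n_components, len(selected))
        sub = prepared.matrix.loc[selected]
        loadings, scores, _ = pca_metagenes(sub, n_comp)
        t = prepared.time.to_numpy()
        e = prepared.event.to_numpy()
        # held-out expression centered by training means; unseen rows are
        # guaranteed present because filtering is row-wise
        x_held = cohort.matrix.loc[selected, held].to_numpy()
        centered = x_held - sub.to_numpy().mean(axis=1)
        for c in range(n_comp):
            orientation = orient_component(scores.iloc[:, c].to_numpy(), t, e)
            oof.loc[held, comp_ix[c]] = orientation * float(
                loadings.iloc[:, c].to_numpy() @ centered)

    stat = {}
    pval = {}
    for c in comp_ix:
        mask = oof[c].notna()
        if mask.sum() < 3 or cohort.event[mask].sum() == 0:
            stat[c], pval[c] = np.nan, np.nan
            continue
        vec = oof.loc[mask, c].to_numpy()[None, :]
        s, p = permutation_pvalue(vec, cohort.time[mask].to_numpy(),
                                  cohort.event[mask].to_numpy(),
                                  n_perm=config.n_perm, seed=config.seed)
        stat[c], pval[c] = float(s[0]), float(p[0])
    return LoocvResult(scores=oof, statistic=pd.Series(stat),
                       p_value=pd.Series(pval), n_skipped=n_skipped)
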