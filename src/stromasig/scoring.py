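"""Applying signatures to cohorts: risk scores and the hypoxia meta-signature.

The risk score transfers a fitted principal-component signature to a new
cohort (including a second species via case-insensitive symbol matching):
each matched gene is mean-centered across samples and scaled to unit
variance, multiplied by its signature loading, and summed per sample.

The hypoxia meta-signature is the set of genes present in more than a
given fraction (default 20%) of the hypoxia-named sets of a gene-set
collection; cohorts are scored on it by the first principal axis of the
mean-centered meta-signature expression, with the sign anchored so that a
canonical hypoxia-induced transcript (VEGFA) carries a positive weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import ExpressionCohort, GeneSetCollection, ScoreTable, SignatureModel

__all__ = [
    "risk_score",
    "MetaSignature",
    "build_hypoxia_metasignature",
    "hypoxia_score",
    "stratify_scores",
]


def _as_matrix(cohort) -> pd.DataFrame:
    if isinstance(cohort, ExpressionCohort):
        return cohort.matrix
    return cohort


def _match_symbols(row_ids: Sequence[str], wanted: Sequence[str],
                   ortholog_map: Optional[Mapping[str, str]] = None) -> dict:
    """Map cohort row id -> signature transcript id, case-insensitively.

    ``ortholog_map`` (signature symbol -> cohort symbol) takes precedence
    when supplied. The first matching row wins for a given transcript.
    """
    if ortholog_map:
        wanted_by_key = {str(ortholog_map.get(t, t)).casefold(): t for t in wanted}
    else:
        wanted_by_key = {str(t).casefold(): t for t in wanted}
    out: dict = {}
    claimed: set = set()
    for rid in row_ids:
        t = wanted_by_key.get(str(rid).casefold())
        if t is not None and t not in claimed:
            out[rid] = t
            claimed.add(t)
    return out


def risk_score(cohort, signature: SignatureModel,
               ortholog_map: Optional[Mapping[str, str]] = None) -> ScoreTable:
    """Score a cohort on a fitted signature.

    Matched gene expression is z-scored across samples and weighted by the
    hazard-oriented loadings; the per-sample sum is the risk score, so a
    positive score marks a sample resembling the hazardous expression
    pattern. Unmatched signature genes are dropped and the matched
    fraction reported.
    """
    matrix = _as_matrix(cohort)
    if matrix.shape[1] < 2:
        raise ValueError("risk scoring needs at least 2 samples")
    match = _match_symbols(matrix.index, signature.transcript_ids, ortholog_map)
    if not match:
        raise ValueError("no signature genes match the cohort")
    w = pd.Series(signature.oriented_loadings,
                  index=signature.transcript_ids)
    rows = list(match)
    x = matrix.loc[rows].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance genes from scoring")
    if not keep.any():
        raise ValueError("all matched genes have zero variance")
    x = x[keep]
    rows = [r for r, k in zip(rows, keep) if k]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    weights = np.array([w[match[r]] for r in rows])
    scores = pd.Series(weights @ z, index=matrix.columns, name="score")
    frac = len(match) / len(signature.transcript_ids)
    return ScoreTable(scores=scores, matched_gene_fraction=frac)


@dataclass
class MetaSignature:
    """A consensus gene list distilled from token-matched gene sets."""

    genes: list
    n_matching_sets: int
    union_size: int


def build_hypoxia_metasignature(collection: GeneSetCollection,
                                name_token: str = "HYPOXIA",
                                min_fraction: float = 0.20) -> MetaSignature:
    """Genes present in strictly more than ``min_fraction`` of the sets
    whose name contains ``name_token`` (case-insensitive)."""
    token = name_token.casefold()
    matching = {name: members for name, members in collection.sets.items()
                if token in name.casefold()}
    if not matching:
        raise ValueError(f"no matching sets: no set name contains {name_token!r}")
    n = len(matching)
    counts: dict = {}
    for members in matching.values():
        for g in members:
            counts[g] = counts.get(g, 0) + 1
    genes = sorted(g for g, k in counts.items() if k / n > min_fraction)
    return MetaSignature(genes=genes, n_matching_sets=n,
                         union_size=len(counts))


def hypoxia_score(cohort, metasignature: Union[MetaSignature, Sequence[str]],
                  anchor_gene: str = "VEGFA") -> ScoreTable:
    """Score samples on the first principal axis of the meta-signature genes.

    Meta-signature gene rows are mean-centered across samples and
    decomposed by SVD; the per-sample score is the sample-side coordinate
    of the first component. The whole component is flipped if the anchor
    gene's gene-side weight is negative, so that higher scores track
    higher expression of the anchor (a hypoxia-induced transcript).
    """
    matrix = _as_matrix(cohort)
    genes = metasignature.genes if isinstance(metasignature, MetaSignature) \
        else list(metasignature)
    match = _match_symbols(matrix.index, genes)
    if len(match) < 2:
        raise ValueError("need at least 2 meta-signature genes in the cohort")
    anchor_rows = [r for r, t in match.items()
                   if str(t).casefold() == str(anchor_gene).casefold()]
    if not anchor_rows:
        raise ValueError(
            f"anchor gene {anchor_gene!r} absent from cohort or meta-signature; "
            "the sign rule cannot be applied")
    rows = list(match)
    x = matrix.loc[rows].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    weights = u[:, 0]
    scores = s[0] * vt[0]
    a = rows.index(anchor_rows[0])
    if weights[a] < 0:
        weights, scores = -weights, -scores
    frac = len(match) / len(genes)
    return ScoreTable(scores=pd.Series(scores, index=matrix.columns, name="score"),
                      matched_gene_fraction=frac)


def stratify_scores(table: ScoreTable, scheme="tertile",
                    q_low: float = 0.25, q_high: float = 0.75) -> ScoreTable:
    """Attach stratum labels by empirical quantiles (type-7 interpolation).

    Schemes: ``tertile`` (low/mid/high thirds), ``quartile_extremes``
    (low = bottom quartile, high = top quartile, rest mid),
    ``quantile_extremes`` (as quartile_extremes with custom q_low/q_high),
    ``median`` (low/high halves). In the extremes schemes the mid samples
    are intended to be excluded from two-group comparisons.
    """
    s = table.scores
    if s.nunique() == 1:
        raise ValueError("degenerate quantiles: all scores equal")
    labels = pd.Series("mid", index=s.index, name="stratum")
    if scheme == "tertile":
        if len(s) < 3:
            raise ValueError("fewer samples than groups")
        q1, q2 = np.quantile(s, [1 / 3, 2 / 3])
        labels[s <= q1] = "low"
        labels[s > q2] = "high"
    elif scheme in ("quartile_extremes", "quantile_extremes", "median"):
        if scheme == "quartile_extremes":
            q_low, q_high = 0.25, 0.75
        elif scheme == "median":
            q_low = q_high = 0.5
        if len(s) < 2:
            raise ValueError("fewer samples than groups")
        lo, hi = np.quantile(s, [q_low, q_high])
        labels[s <= lo] = "low"
        labels[s > hi] = "high"
    else:
        raise ValueError(f"unknown stratification scheme: {scheme!r}")
    return ScoreTable(scores=s, matched_gene_fraction=table.matched_gene_fraction,
                      stratum=labels)
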