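"""Survival and association statistics used throughout the analyses.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
rank statistics to scipy. The Yates-corrected chi-square on 2x2 tables is
computed from its closed form,

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)),

with the upper tail of a 1-df chi-square distribution as p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "KmCurve",
    "km_estimate",
    "logrank_test",
    "yates_chi2",
    "mann_whitney_u",
    "spearman_rho",
]


@dataclass
class ContingencyTable2x2:
    """Counts of a 2x2 table: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class KmCurve:
    """Product-limit survival curve on the observed event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float  # first time survival <= 0.5; NaN if never reached

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KmCurve:
    """Kaplan-Meier product-limit estimate with median survival.

    The median is the first time at which the survival probability drops
    to 0.5 or below, NaN if the curve never reaches 0.5.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty input")
    if (time <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    mask = tbl["observed"] > 0
    times = tbl.index.to_numpy(dtype=float)[mask.to_numpy()]
    surv = kmf.survival_function_at_times(times).to_numpy()
    at_risk = tbl["at_risk"].to_numpy()[mask.to_numpy()]
    med = float(kmf.median_survival_time_)
    if not np.isfinite(med):
        med = float("nan")
    return KmCurve(times=times, survival=surv, at_risk=at_risk, median=med)


def logrank_test(groups: Sequence[Tuple[Sequence[float], Sequence[int]]]
                 ) -> Tuple[float, float]:
    """Log-rank comparison of two or more survival curves.

    ``groups`` is a sequence of (time, event) pairs. Returns (chi-square
    statistic, p-value) with k-1 degrees of freedom for k groups. Tied
    event times are handled in one step with hypergeometric variance.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def yates_chi2(table: ContingencyTable2x2) -> Tuple[float, float]:
    """Chi-square test with Yates continuity correction on a 2x2 table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n < 1:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise ValueError("zero margin: corrected chi-square undefined")
    num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    chi2 = num / np.prod([float(m) for m in margins])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p-value when the smaller sample has at most 8 observations and
    there are no ties; otherwise a tie-corrected normal approximation.
    All values tied across both samples yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied across both samples: p = 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero rank variance")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
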