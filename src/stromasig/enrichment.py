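"""Gene-set over-representation analysis.

Each set is tested with the hypergeometric upper tail P(X >= k) for the
overlap k between the query and the set within a finite gene universe;
p-values are corrected with the Benjamini-Yekutieli step-up procedure,
which controls the false discovery rate under arbitrary dependence among
the (heavily overlapping) sets.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection

__all__ = ["hypergeom_ora", "by_adjust"]


def by_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values.

    Equivalent to Benjamini-Hochberg step-up inflated by the harmonic
    factor c(m) = sum_{i<=m} 1/i, with monotonicity enforcement and
    capping at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


def hypergeom_ora(query: Sequence[str], collection: GeneSetCollection,
                  universe: Optional[Sequence[str]] = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``query`` in every set of ``collection``.

    Sets are intersected with the universe before testing; sets that are
    empty after intersection are skipped. Returns one row per tested set
    with columns name, k (overlap), n (query size), K (set size), N
    (universe size), p_value, p_adjusted, significant (strict < alpha).
    """
    if universe is None:
        universe = collection.universe or (collection.union() | set(query))
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        missing = sorted(query - universe)[:3]
        raise ValueError(f"query genes outside the universe, e.g. {missing}")

    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        inset = members & universe
        K = len(inset)
        if K == 0:
            continue
        k = len(inset & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, n, K, N, min(p, 1.0)))
    if not rows:
        raise ValueError("no testable sets after universe intersection")
    df = pd.DataFrame(rows, columns=["name", "k", "n", "K", "N", "p_value"])
    df["p_adjusted"] = by_adjust(df["p_value"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
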