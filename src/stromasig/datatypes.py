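"""Core containers shared across the analysis stages.

The transcriptomic stages all operate on an :class:`ExpressionCohort`
(log-scale expression matrix plus right-censored survival annotations),
produce a :class:`SignatureModel` (the serializable artifact of signature
discovery) and exchange per-sample results as :class:`ScoreTable` objects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "SignatureModel",
    "GeneSetCollection",
    "ScoreTable",
    "ScreenResult",
]


@dataclass
class ExpressionCohort:
    """A normalized, log-scale expression matrix with clinical annotations.

    Parameters
    ----------
    matrix
        Expression values, rows are probes or genes, columns are samples.
    time
        Follow-up time in months per sample (positive). ``None`` for
        cohorts without survival annotation (e.g. a scored-only cohort).
    event
        Event indicator per sample, 1 = death observed, 0 = censored.
    probe_to_gene
        Optional probe id -> gene symbol map; present while rows are probes.
    batch
        Optional batch label per sample.
    """

    matrix: pd.DataFrame
    time: Optional[pd.Series] = None
    event: Optional[pd.Series] = None
    probe_to_gene: Optional[Mapping[str, str]] = None
    batch: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate row id: {dup!r}")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.time is None) != (self.event is None):
            raise ValueError("time and event must be given together")
        if self.time is not None:
            self.time = self.time.reindex(self.matrix.columns)
            self.event = self.event.reindex(self.matrix.columns)
            if self.time.isna().any() or self.event.isna().any():
                raise ValueError("clinical annotation missing for some samples")
            if (self.time <= 0).any():
                raise ValueError("survival times must be positive")
            if not self.event.isin([0, 1]).all():
                raise ValueError("event indicator must be 0/1")
            self.event = self.event.astype(int)
        if self.batch is not None:
            self.batch = self.batch.reindex(self.matrix.columns)

    @property
    def row_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionCohort":
        """Return a cohort restricted to (and ordered by) ``samples``."""
        samples = list(samples)
        return ExpressionCohort(
            matrix=self.matrix[samples],
            time=None if self.time is None else self.time[samples],
            event=None if self.event is None else self.event[samples],
            probe_to_gene=self.probe_to_gene,
            batch=None if self.batch is None else self.batch[samples],
        )

    def with_matrix(self, matrix: pd.DataFrame,
                    probe_to_gene: Optional[Mapping[str, str]] = "keep",
                    ) -> "ExpressionCohort":
        """Return a copy with ``matrix`` replaced (same samples)."""
        p2g = self.probe_to_gene if probe_to_gene == "keep" else probe_to_gene
        return ExpressionCohort(matrix=matrix, time=self.time,
                                event=self.event, probe_to_gene=p2g,
                                batch=self.batch)


@dataclass
class SignatureModel:
    """A fitted principal-component survival signature.

    ``orientation`` is chosen so that a higher component score corresponds
    to a higher hazard; transcripts whose oriented loading is positive form
    the hazardous set, the remainder the protective set.
    """

    transcript_ids: list
    loadings: np.ndarray
    component_index: int = 0
    orientation: int = 1
    hazardous_set: frozenset = field(default_factory=frozenset)
    protective_set: frozenset = field(default_factory=frozenset)
    cv_statistic: Optional[float] = None
    cv_pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (len(self.transcript_ids),):
            raise ValueError("one loading per transcript required")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")
        self.hazardous_set = frozenset(self.hazardous_set)
        self.protective_set = frozenset(self.protective_set)
        all_ids = set(self.transcript_ids)
        if self.hazardous_set | self.protective_set != all_ids:
            raise ValueError("hazardous/protective sets must cover all transcripts")
        if self.hazardous_set & self.protective_set:
            raise ValueError("hazardous/protective sets must be disjoint")
        oriented = self.loadings * self.orientation
        for tid, w in zip(self.transcript_ids, oriented):
            if w > 0 and tid not in self.hazardous_set:
                raise ValueError(f"positive oriented loading not hazardous: {tid}")
            if w < 0 and tid not in self.protective_set:
                raise ValueError(f"negative oriented loading not protective: {tid}")

    @property
    def oriented_loadings(self) -> np.ndarray:
        """Loadings with the hazard-positive sign applied."""
        return self.loadings * self.orientation

    def to_dict(self) -> dict:
        return {
            "transcript_ids": list(self.transcript_ids),
            # decimal strings keep the JSON artifact diffable and exact to
            # 10 significant digits
            "loadings": [format(x, ".10g") for x in self.loadings],
            "component_index": self.component_index,
            "orientation": self.orientation,
            "hazardous_set": sorted(self.hazardous_set),
            "protective_set": sorted(self.protective_set),
            "cv_statistic": self.cv_statistic,
            "cv_pvalue": self.cv_pvalue,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(
            transcript_ids=list(d["transcript_ids"]),
            loadings=np.array([float(x) for x in d["loadings"]]),
            component_index=int(d["component_index"]),
            orientation=int(d["orientation"]),
            hazardous_set=frozenset(d["hazardous_set"]),
            protective_set=frozenset(d["protective_set"]),
            cv_statistic=d.get("cv_statistic"),
            cv_pvalue=d.get("cv_pvalue"),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GeneSetCollection:
    """Named gene sets (a GMT file in memory)."""

    sets: dict
    universe: Optional[frozenset] = None

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            if name in clean:
                raise ValueError(f"duplicate set name: {name}")
            members = frozenset(members)
            if not members:
                raise ValueError(f"empty gene set: {name}")
            clean[name] = members
        self.sets = clean
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for members in self.sets.values():
            out |= members
        return out


@dataclass
class ScoreTable:
    """Per-sample scalar scores with optional stratum labels."""

    scores: pd.Series
    matched_gene_fraction: float = 1.0
    stratum: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if not (0 < self.matched_gene_fraction <= 1):
            raise ValueError("matched_gene_fraction must be in (0, 1]")
        if self.stratum is not None:
            self.stratum = self.stratum.reindex(self.scores.index)

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.scores.index,
                           "score": self.scores.values})
        if self.stratum is not None:
            df["stratum"] = self.stratum.values
        return df


#: per-transcript screening result: columns statistic, p_value, lfdr, selected
ScreenResult = pd.DataFrame


def check_screen_result(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the column contract of a screening result table."""
    required = {"statistic", "p_value", "lfdr", "selected"}
    if not required <= set(df.columns):
        raise ValueError(f"screen result missing columns {required - set(df.columns)}")
    if ((df["p_value"] <= 0) | (df["p_value"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if ((df["lfdr"] < 0) | (df["lfdr"] > 1)).any():
        raise ValueError("local FDR values must lie in [0, 1]")
    return df
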