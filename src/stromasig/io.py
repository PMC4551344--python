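"""Readers and writers for the pipeline's file formats.

Everything tabular is tab-separated UTF-8 with Unix newlines; numbers are
written with 10 significant digits so reruns diff cleanly. Gene sets use
the standard GMT dialect (set name, description, then members, one set per
line). Image stacks are single- or multi-page grayscale TIFF.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import tifffile

from .datatypes import ExpressionCohort, GeneSetCollection, ScoreTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_probe_map",
    "load_cohort",
    "write_cohort",
    "read_gmt",
    "write_gmt",
    "read_scores",
    "write_scores",
    "read_stack",
    "write_stack",
]

FLOAT_FORMAT = "%.10g"


def read_expression(path, missing_policy: Optional[str] = None) -> pd.DataFrame:
    """Read a genes-x-samples expression TSV (first column = row ids).

    Missing cells are rejected unless ``missing_policy='drop-row'``, which
    drops any row containing a missing value. Non-numeric cells and
    duplicate row ids are always rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate row id in {path}: {dup!r}")
    non_numeric = [c for c in df.columns
                   if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        bad = df[non_numeric[0]]
        coerced = pd.to_numeric(bad, errors="coerce")
        offender = bad[coerced.isna() & bad.notna()]
        cell = offender.iloc[0] if len(offender) else "?"
        raise ValueError(
            f"non-numeric cell in column {non_numeric[0]!r} of {path}: {cell!r}")
    if df.isna().any().any():
        if missing_policy == "drop-row":
            df = df.dropna(axis=0, how="any")
        else:
            raise ValueError(
                f"missing cells in {path}; pass missing_policy='drop-row' to drop them")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
              index_label="gene_id", lineterminator="\n")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, time_months, event
    (0/1) and optional batch; indexed by sample_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_months", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"clinical table missing columns "
                         f"{sorted(required - set(df.columns))}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    return df.set_index("sample_id")


def write_clinical(cohort: ExpressionCohort, path) -> None:
    df = pd.DataFrame({"sample_id": cohort.sample_ids,
                       "time_months": cohort.time.values,
                       "event": cohort.event.values})
    if cohort.batch is not None:
        df["batch"] = cohort.batch.values
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def read_probe_map(path) -> dict:
    """Read a probe_id -> gene_symbol TSV (two columns, with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs columns probe_id, gene_symbol")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_cohort(expression_path, clinical_path,
                probe_map_path=None,
                missing_policy: Optional[str] = None) -> ExpressionCohort:
    """Assemble an ExpressionCohort from its on-disk parts.

    Samples are intersected between matrix and clinical table; samples
    missing from either are dropped.
    """
    matrix = read_expression(expression_path, missing_policy=missing_policy)
    clinical = read_clinical(clinical_path)
    common = [s for s in matrix.columns if s in clinical.index]
    if not common:
        raise ValueError("no samples shared between matrix and clinical table")
    clinical = clinical.loc[common]
    p2g = read_probe_map(probe_map_path) if probe_map_path else None
    return ExpressionCohort(
        matrix=matrix[common],
        time=clinical["time_months"].astype(float),
        event=clinical["event"].astype(int),
        probe_to_gene=p2g,
        batch=clinical["batch"] if "batch" in clinical.columns else None,
    )


def write_cohort(cohort: ExpressionCohort, expression_path, clinical_path) -> None:
    write_expression(cohort.matrix, expression_path)
    write_clinical(cohort, clinical_path)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Each line: set name, description, then one or more member genes,
    tab-separated. Duplicate members are deduplicated; malformed lines
    (fewer than 3 columns) are reported with their line number.
    """
    sets: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(expected name, description, members)")
            name = parts[0]
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path,
              descriptions: Optional[Mapping[str, str]] = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_scores(path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t")
    stratum = df.set_index("sample_id")["stratum"] if "stratum" in df.columns else None
    return ScoreTable(scores=df.set_index("sample_id")["score"],
                      stratum=stratum)


def write_scores(table: ScoreTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False,
                            float_format=FLOAT_FORMAT, lineterminator="\n")


def read_stack(path) -> np.ndarray:
    """Read a single- or multi-page grayscale TIFF as (depth, h, w)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale stack, got shape {arr.shape}")
    return arr


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def require_files(*paths) -> None:
    """Fail fast (before any stage runs) if an input file is missing."""
    for p in paths:
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(f"input file not found: {p}")
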