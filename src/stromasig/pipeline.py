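"""End-to-end orchestration of the two analyses.

``run_pipeline`` chains the transcriptomic stages (simulate or load a
cohort, discover a signature, score it, stratify, compare survival) or the
imaging stages (simulate or load stacks, texture profile, decay fit),
writing every intermediate artifact plus a manifest that echoes the
configuration, seeds and package version. Re-running the same
configuration reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .datatypes import ExpressionCohort
from .discovery import DiscoveryConfig, discover_signature, evaluate_components_loocv
from .scoring import risk_score, stratify_scores
from .survival import km_estimate, logrank_test
from .synthetic import CohortSpec, TextureSpec, generate_shg_stack, generate_survival_cohort
from .texture import analyze_stack

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    subcommand: str = "signature"  # "signature" or "texture"
    out_dir: str = "results"
    seed: int = 0
    # inputs; when None for "signature", a synthetic cohort is generated
    expression: Optional[str] = None
    clinical: Optional[str] = None
    probe_map: Optional[str] = None
    stack: Optional[str] = None
    # stage parameters
    keep_fraction: float = 0.5
    n_perm: int = 10_000
    cv_n_perm: int = 1_000
    lfdr_threshold: float = 0.15
    run_loocv: bool = False
    stratify_scheme: str = "tertile"
    min_fraction: float = 0.20
    alpha: float = 0.05
    max_distance: int = 100
    levels: int = 64
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _stage(manifest: list, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = _time.perf_counter() - self.t0
            status = "failed" if exc_type else "ok"
            manifest.append({"stage": name, "status": status,
                             "seconds": round(dt, 3)})
            logger.info("stage %s: %s (%.2fs)", name, status, dt)
            return False
    return _Timer()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured analysis; returns the output directory.

    Any stage failure propagates with the stage recorded in the manifest;
    artifacts written by completed stages are preserved.
    """
    logging.basicConfig(level=config.log_level)
    io.require_files(config.expression, config.clinical, config.probe_map,
                     config.stack)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list = []
    try:
        if config.subcommand == "signature":
            _run_signature(config, out, manifest)
        elif config.subcommand == "texture":
            _run_texture(config, out, manifest)
        else:
            raise ValueError(f"unknown subcommand: {config.subcommand!r}")
    finally:
        meta = {
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "stages": manifest,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)
    return out


def _run_signature(config: RunConfig, out: Path, manifest: list) -> None:
    with _stage(manifest, "load_cohort"):
        if config.expression:
            cohort = io.load_cohort(config.expression, config.clinical,
                                    config.probe_map)
        else:
            cohort, truth = generate_survival_cohort(CohortSpec(seed=config.seed))
            io.write_cohort(cohort, out / "expression.tsv", out / "clinical.tsv")
            truth["loadings"].to_csv(out / "planted_loadings.tsv", sep="\t",
                                     header=["loading"])

    disc = DiscoveryConfig(keep_fraction=config.keep_fraction,
                           n_perm=config.n_perm, cv_n_perm=config.cv_n_perm,
                           lfdr_threshold=config.lfdr_threshold,
                           seed=config.seed)
    with _stage(manifest, "discover_signature"):
        model, screen = discover_signature(cohort, disc)
        screen.to_csv(out / "screen.tsv", sep="\t", index_label="transcript_id")
        model.to_json(out / "signature.json")

    if config.run_loocv:
        with _stage(manifest, "loocv"):
            cv = evaluate_components_loocv(cohort, disc)
            cv.scores.to_csv(out / "loocv_scores.tsv", sep="\t",
                             index_label="sample_id")
            pd.DataFrame({"statistic": cv.statistic,
                          "p_value": cv.p_value}).to_csv(
                out / "loocv_association.tsv", sep="\t",
                index_label="component")

    with _stage(manifest, "risk_score"):
        scores = risk_score(cohort, model)
        scores = stratify_scores(scores, config.stratify_scheme)
        io.write_scores(scores, out / "risk_scores.tsv")

    with _stage(manifest, "survival_comparison"):
        strata = scores.stratum
        groups, labels = [], []
        for label in ("low", "high"):
            sel = strata == label
            if sel.any():
                groups.append((cohort.time[sel].to_numpy(),
                               cohort.event[sel].to_numpy()))
                labels.append(label)
        result = {}
        for label, (t, e) in zip(labels, groups):
            result[f"median_survival_{label}"] = km_estimate(t, e).median
        if len(groups) >= 2:
            chi2, p = logrank_test(groups)
            result["logrank_chi2"] = chi2
            result["logrank_p"] = p
        with open(out / "survival_comparison.json", "w", encoding="utf-8") as fh:
            json.dump({k: (None if v != v else v) for k, v in result.items()},
                      fh, indent=1)


def _run_texture(config: RunConfig, out: Path, manifest: list) -> None:
    with _stage(manifest, "load_stack"):
        if config.stack:
            stack = io.read_stack(config.stack)
        else:
            stack = generate_shg_stack(TextureSpec(seed=config.seed))
            io.write_stack(stack, out / "stack.tif")

    with _stage(manifest, "texture_profile"):
        profile = analyze_stack(
            stack, distances=tuple(range(1, config.max_distance + 1)),
            levels=config.levels, seed=config.seed)
        profile.values.to_csv(out / "texture_profile.tsv", sep="\t",
                              index=False, float_format="%.10g")
        summary = {"area_fraction_percent": profile.area_fraction}
        for pname, fit in profile.fits.items():
            summary[pname] = {
                "A1": fit.a1, "lambda1": fit.lambda1,
                "A2": fit.a2, "lambda2": fit.lambda2,
                "offset": fit.offset, "inverted": fit.inverted,
                "weighted_mean_decay_distance":
                    fit.weighted_mean_decay_distance,
            }
        with open(out / "texture_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1)

    with _stage(manifest, "depth_profile"):
        from .texture import depth_profile
        prof = depth_profile(stack)
        pd.DataFrame({"slice": np.arange(len(prof.counts)),
                      "foreground_pixels": prof.counts,
                      "percent": prof.percents}).to_csv(
            out / "depth_profile.tsv", sep="\t", index=False,
            float_format="%.10g")
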