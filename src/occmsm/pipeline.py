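"""End-to-end pipeline: simulate or ingest → derive → weight → fit → report.

One call produces every artifact of the analysis in an output directory and
returns a manifest with the artifact paths and headline estimates.  All
randomness flows from the single master seed in the configuration, so a rerun
with the same configuration reproduces the manifest estimates exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import report as report_mod
from .msm import ModelSpec, compare_weighted_unweighted, fit_pooled_logistic, threshold_sensitivity
from .simulate import SimConfig, generate_cohort
from .weights import (
    compute_stabilized_weights,
    fit_exposure_models,
    truncate_weights,
    weight_diagnostics,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration: exactly one input mode (simulate or a CSV path)."""

    output_dir: str | Path = "results/run"
    simulate: SimConfig | None = None
    episodes_csv: str | Path | None = None
    year_start: str | None = None        # ISO date of study day 1, for date CSVs
    year_length: int = 365
    weekday_of_day1: int = 1
    percentile: float = 85.0
    exposure: str = "cumulative"         # cumulative | short_term
    cluster_level: str = "hospital"
    truncation: tuple[float, float] | None = None
    sensitivity_percentiles: tuple[float, ...] = (75, 80, 85, 90, 95)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            if "hospital_sizes" in sim:
                sim["hospital_sizes"] = tuple(sim["hospital_sizes"])
            if "hospital_types" in sim:
                sim["hospital_types"] = tuple(sim["hospital_types"])
            raw["simulate"] = SimConfig(**sim).validate()
        if "truncation" in raw and raw["truncation"] is not None:
            raw["truncation"] = tuple(raw["truncation"])
        if "sensitivity_percentiles" in raw:
            raw["sensitivity_percentiles"] = tuple(raw["sensitivity_percentiles"])
        return cls(**raw)

    def validate(self) -> "PipelineConfig":
        if (self.simulate is None) == (self.episodes_csv is None):
            raise PipelineError("config", "exactly one of simulate / episodes_csv must be set")
        return self


def _result_payload(result) -> dict:
    return {
        "terms": result.terms.reset_index().rename(columns={"index": "term"}).to_dict(orient="records"),
        "n_person_days": result.n_person_days,
        "n_clusters": result.n_clusters,
        "cluster_level": result.cluster_level,
        "weighted": result.weighted,
        "weight_meta": result.weight_meta,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    cfg = config.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "estimates": {}}

    # --- input stage
    if cfg.simulate is not None:
        sim = cfg.simulate.validate()
        year_length, weekday1 = sim.year_length, sim.weekday_of_day1
        episodes, truth = generate_cohort(sim)
        truth.to_json(out / "sim_truth.json")
        manifest["artifacts"]["sim_truth"] = str(out / "sim_truth.json")
        manifest["seed"] = sim.seed
    else:
        year_length, weekday1 = cfg.year_length, cfg.weekday_of_day1
        try:
            episodes = cohort_mod.read_episodes(cfg.episodes_csv, cfg.year_start)
        except Exception as exc:
            raise PipelineError("ingest", str(exc)) from exc
        episodes = cohort_mod.attach_weekend_admission(episodes, weekday1)
    episodes.to_csv(out / "episodes.csv", index=False)
    manifest["artifacts"]["episodes"] = str(out / "episodes.csv")

    # --- cohort derivation
    try:
        kept = cohort_mod.apply_inclusion_filters(episodes, year_length)
        manifest["n_episodes_input"] = int(len(episodes))
        manifest["n_episodes_analysed"] = int(len(kept))
        hospital_days = cohort_mod.build_daily_series(kept, year_length, weekday1)
        thresholds = cohort_mod.derive_threshold(hospital_days, cfg.percentile)
        persondays = cohort_mod.expand_person_days(kept, hospital_days, thresholds)
    except Exception as exc:
        raise PipelineError("cohort", str(exc)) from exc
    hospital_days.to_csv(out / "hospital_days.csv", index=False)
    thresholds.to_csv(out / "thresholds.csv", index=False)
    persondays.to_csv(out / "persondays.csv", index=False)
    for name in ("hospital_days", "thresholds", "persondays"):
        manifest["artifacts"][name] = str(out / f"{name}.csv")

    # --- weights
    try:
        models = fit_exposure_models(persondays)
        weights = compute_stabilized_weights(models, persondays)
    except Exception as exc:
        raise PipelineError("weights", str(exc)) from exc
    weights.table.to_csv(out / "weights.csv", index=False)
    diag = weight_diagnostics(weights, plot_path=out / "weight_density.png")
    with open(out / "weight_diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    manifest["artifacts"]["weights"] = str(out / "weights.csv")
    manifest["artifacts"]["weight_diagnostics"] = str(out / "weight_diagnostics.json")
    manifest["estimates"]["weight_mean"] = diag["mean"]

    # --- MSM fits
    spec = ModelSpec(exposure_term=cfg.exposure, cluster_level=cfg.cluster_level)
    try:
        comparison = compare_weighted_unweighted(persondays, weights, spec)
        results = {
            "unweighted": fit_pooled_logistic(persondays, spec),
            "weighted": fit_pooled_logistic(persondays, spec, weights=weights),
            "weighted_truncated": fit_pooled_logistic(
                persondays, spec, weights=truncate_weights(weights, *(cfg.truncation or (1, 99)))
            ),
            "short_term_weighted": fit_pooled_logistic(
                persondays, ModelSpec(exposure_term="short_term", cluster_level=cfg.cluster_level),
                weights=weights,
            ),
        }
    except Exception as exc:
        raise PipelineError("msm", str(exc)) from exc
    with open(out / "msm_results.json", "w") as fh:
        json.dump({k: _result_payload(v) for k, v in results.items()}, fh, indent=2)
    comparison.reset_index().to_csv(out / "msm_comparison.csv", index=False)
    manifest["artifacts"]["msm_results"] = str(out / "msm_results.json")
    manifest["artifacts"]["msm_comparison"] = str(out / "msm_comparison.csv")
    exp = results["weighted"].exposure_row
    manifest["estimates"]["weighted_or_per_exposure_day"] = float(exp["odds_ratio"])
    manifest["estimates"]["weighted_ci"] = [float(exp["ci_low"]), float(exp["ci_high"])]
    manifest["estimates"]["unweighted_or_per_exposure_day"] = float(
        results["unweighted"].exposure_row["odds_ratio"]
    )

    # --- sensitivity & descriptives
    try:
        sens = threshold_sensitivity(kept, hospital_days, cfg.sensitivity_percentiles, spec)
        sens.to_csv(out / "threshold_sensitivity.csv", index=False)
        t1 = report_mod.table_one(kept)
        t1.to_csv(out / "table_one.csv", index=False)
        summary = report_mod.covariate_distribution_summary(
            hospital_days, thresholds, plot_path=out / "cu_violin.png"
        )
        summary.to_csv(out / "covariate_summary.csv", index=False)
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc
    for name in ("threshold_sensitivity", "table_one", "covariate_summary"):
        manifest["artifacts"][name] = str(out / f"{name}.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["artifacts"]["manifest"] = str(out / "manifest.json")
    return manifest
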