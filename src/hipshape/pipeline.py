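"""End-to-end pipeline: simulate -> build-ssm -> measure -> grade -> associate -> composite.

Each stage writes its artifact (points files, CSV tables, model JSON,
figures) into the output directory together with a ``metadata.json``
recording the seed and stage row counts, so a run is reproducible and
its exclusion accounting (input n = analysed n + excluded n) auditable.
All randomness flows through the single seed in the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .schema import DEFAULT_SCHEMA, PointSchema, write_cohort, write_points_dir
from .simulate import GenerativeShapeSpec, OutcomeModelSpec, sample_cohort
from .ssm import fit_shape_model
from .geometry import measure_cohort
from .grading import GradingConfig, grade_cohort
from .association import (bonferroni_flag, describe_cohort, fit_cox_per_hsm,
                          fit_logistic_per_hsm, results_to_frame)
from .composite import build_composite, composite_to_frame, render_outlines

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "fit_all_associations", "OUTCOMES"]

OUTCOMES = ("rhoa_grade2_only", "rhoa_ge3", "hoa_hospital", "thr")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its input."""


@dataclass
class PipelineConfig:
    """One-file configuration of the whole pipeline."""

    n: int = 2000
    seed: int = 0
    out_dir: str = "hipshape_run"
    k_modes: int = 10               # modes carried into the association stage
    bonferroni_k: int | None = None  # defaults to k_modes
    factor: float = 5.0             # composite visual multiplier
    point_noise_sd: float = 0.35
    score_sd: tuple[float, ...] | None = None
    schema_path: str | None = None
    grading_path: str | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.k_modes < 1:
            raise ValueError("k_modes must be >= 1")
        if self.bonferroni_k is None:
            self.bonferroni_k = self.k_modes
        for p in (self.schema_path, self.grading_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "score_sd" in d and d["score_sd"] is not None:
            d["score_sd"] = tuple(d["score_sd"])
        return cls(**d)

    def schema(self) -> PointSchema:
        return PointSchema.from_yaml(self.schema_path) if self.schema_path else DEFAULT_SCHEMA

    def grading(self) -> GradingConfig:
        return GradingConfig.from_yaml(self.grading_path) if self.grading_path else GradingConfig()


def fit_all_associations(
    scores: pd.DataFrame,
    cohort: pd.DataFrame,
    grades: pd.DataFrame,
    measures: pd.DataFrame,
    n_tests: int = 10,
) -> pd.DataFrame:
    """Per-mode models for all four OA outcomes under all adjustment models.

    Adjustment models: ``unadjusted``, ``model2`` (age, sex, height,
    weight, white/other ethnicity), ``model2_aa`` and ``model2_lcea``.
    Rows with an undefined AA/LCEA are dropped from the corresponding
    adjusted models (complete-case).
    """
    df = scores.merge(cohort, on="subject_id").merge(
        grades, on="subject_id").merge(
        measures[["subject_id", "alpha_angle", "lcea"]], on="subject_id")
    hsm_cols = [c for c in scores.columns if c != "subject_id"]
    cov = df[["age", "sex", "height", "weight", "ethnicity_white"]]

    out = []
    for outcome in OUTCOMES:
        if outcome == "thr":
            def fit(sub, extra, model_name, covariates):
                return fit_cox_per_hsm(
                    sub[hsm_cols], sub["thr_time"], sub["thr_event"],
                    covariates=covariates, extra=extra,
                    outcome_name="thr", model_name=model_name)
        else:
            def fit(sub, extra, model_name, covariates, _o=outcome):
                return fit_logistic_per_hsm(
                    sub[hsm_cols], sub[_o], covariates=covariates, extra=extra,
                    outcome_name=_o, model_name=model_name)
        out += fit(df, None, "unadjusted", None)
        out += fit(df, None, "model2", cov)
        for col, mname in (("alpha_angle", "model2_aa"), ("lcea", "model2_lcea")):
            sub = df[np.isfinite(df[col])]
            extra = sub[col]
            out += fit(sub, extra, mname,
                       sub[["age", "sex", "height", "weight", "ethnicity_white"]])
    frame = results_to_frame(out)
    return bonferroni_flag(frame, n_tests=n_tests)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = config.schema()
    grading_cfg = config.grading()
    meta: dict = {"seed": config.seed, "n": config.n, "version": __version__,
                  "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("simulate")
        shape_spec = GenerativeShapeSpec.default(point_noise_sd=config.point_noise_sd) \
            if config.score_sd is None else GenerativeShapeSpec.default(
                score_sd=config.score_sd, point_noise_sd=config.point_noise_sd)
        outcome_spec = OutcomeModelSpec.default()
        configs, cohort, true_scores = sample_cohort(
            shape_spec, outcome_spec, n=config.n, seed=config.seed)
        pts_dir = out / "points"
        write_points_dir(configs, pts_dir)
        write_cohort(cohort, out / "cohort.csv")
        true_scores.to_csv(out / "true_scores.csv", index=False)
        outcome_spec.to_json(out / "true_parameters.json")
        meta["stages"][name] = {"n": len(configs)}

        name = stage("build-ssm")
        model = fit_shape_model(configs)
        model.to_json(out / "model.json")
        k = min(config.k_modes, model.n_modes)
        scores = model.transform(configs)
        scores = scores[["subject_id"] + [f"hsm{i+1}" for i in range(k)]]
        scores.to_csv(out / "scores.csv", index=False)
        meta["stages"][name] = {
            "n": len(scores), "k_modes": k,
            "cumulative_var_top_k": model.cumulative_variance(k),
        }

        name = stage("measure")
        measures = measure_cohort(configs, schema)
        measures.to_csv(out / "measures.csv", index=False)
        n_aa = int(np.isfinite(measures["alpha_angle"]).sum())
        meta["stages"][name] = {"n": len(measures), "n_alpha_defined": n_aa,
                                "n_alpha_undefined": len(measures) - n_aa}

        name = stage("grade")
        grades = grade_cohort(measures, cohort.df, grading_cfg)
        grades.to_csv(out / "grades.csv", index=False)
        meta["stages"][name] = {
            "n": len(grades),
            "n_grade2_only": int(grades["rhoa_grade2_only"].sum()),
            "n_ge3": int(grades["rhoa_ge3"].sum()),
        }

        name = stage("describe")
        describe_cohort(cohort.df, grades).to_csv(out / "describe.csv", index=False)

        name = stage("associate")
        results = fit_all_associations(scores, cohort.df, grades, measures,
                                       n_tests=config.bonferroni_k)
        results.to_csv(out / "results.csv", index=False)
        meta["stages"][name] = {"n_models": len(results),
                                "n_significant": int(results["significant"].sum())}

        name = stage("composite")
        model2 = results[results["model"] == "model2"]
        composites = {}
        for outcome in OUTCOMES:
            comp = build_composite(model, model2, outcome, factor=config.factor,
                                   p_threshold=0.05 / config.bonferroni_k)
            composite_to_frame(comp).to_csv(out / f"composite_{outcome}.csv", index=False)
            composites[outcome] = comp.composite_points
            meta["stages"].setdefault(name, {})[outcome] = {
                "included_hsms": list(comp.included_hsms), "factor": config.factor}
        render_outlines(build_composite(model, model2, OUTCOMES[0],
                                        factor=config.factor).mean_points,
                        composites, out / "composites.svg", schema=schema)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    (out / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return out
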