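"""End-to-end analysis orchestration.

One config drives: generate (or load) the cohort, compute CVR scores,
build the standardised model matrix, fit the full structural model plus
the two variable-constrained nested comparisons, derive executive-
function factor scores, compute sliding-window blood-pressure curves
(overall and per stratum), the risk-factor multiple regression, and the
grey-matter -> white-matter -> executive-function mediation.  Every
stage writes a TSV/JSON artifact and the run ends with a manifest
recording stage status and input hashes.  Reruns with the same inputs,
config and seed are byte-identical (no timestamps in any artifact).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._version import __version__ as _version
from .association import fit_regression
from .cohort import default_params, generate_cohort
from .effects import mediate
from .preprocess import build_model_matrix
from .risk import score_cohort
from .schema import ALL_COLUMNS
from .sem import (
    build_structural_spec,
    chi_square_difference,
    constrain_variable_paths,
    factor_scores,
    fit_sem,
    SemModelSpec,
)
from .windows import gaussian_smooth, sliding_window_curve

logger = logging.getLogger("neurocvr")

DEFAULT_STAGES = ("cohort", "score", "preprocess", "sem", "windows", "regression", "mediation")

#: Table-1-style covariate set (8 predictors).
REGRESSION_COVARIATES = (
    "whr",
    "smoking_code",
    "on_cholesterol_medication",
    "on_bp_medication",
    "diabetic",
    "apoe_points",
    "age",
    "townsend",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`; JSON/YAML loadable."""

    output_dir: str = "neurocvr_run"
    seed: Optional[int] = None
    input_path: Optional[str] = None  # cohort CSV/TSV; None -> simulate
    n: int = 2000  # generator size when simulating
    stages: Sequence[str] = DEFAULT_STAGES
    estimator: str = "ML"
    sem_spec_path: Optional[str] = None  # JSON/YAML model spec override
    window_frac: float = 0.10
    window_step: float = 0.01
    smooth_kernel: float = 10.0
    strata: Sequence[str] = ("on_bp_medication", "age_group")
    age_group_cut: float = 70.0  # mid-life 44-69 vs late-life >= 70
    n_boot: int = 10000
    log_level: str = "INFO"

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return PipelineConfig(**d)

    def validate(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        stochastic = {"cohort", "mediation"} & set(self.stages)
        if self.seed is None and (self.input_path is None or stochastic):
            raise ValueError("a seed is required when any stochastic stage is enabled")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_cohort(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input cohort lacks required columns: {missing}")
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest dictionary.

    The input table is never mutated in place; each stage writes its own
    artifact and a failure aborts with a stage-named diagnostic while
    retaining partial outputs and a failure marker in the manifest.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    logger.addHandler(fh)

    manifest: dict = {
        "package_version": _version,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
        "inputs": {},
    }
    state: dict = {}

    def run_stage(name: str, fn) -> None:
        if name not in config.stages:
            manifest["stages"][name] = {"status": "skipped"}
            return
        logger.info("stage %s", name)
        try:
            artifacts = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_json(manifest, out / "manifest.json")
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {"status": "ok", "artifacts": artifacts}

    # -- cohort --------------------------------------------------------------
    def stage_cohort():
        if config.input_path:
            df = _load_cohort(config.input_path)
            manifest["inputs"]["cohort"] = _sha256(Path(config.input_path))
        else:
            df = generate_cohort(default_params(config.n), seed=config.seed)
            prov = out / "cohort_provenance.json"
            _write_json({"n": config.n, "seed": config.seed}, prov)
        state["cohort"] = df
        path = out / "cohort.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["inputs"]["cohort_table"] = _sha256(path)
        return ["cohort.tsv"]

    run_stage("cohort", stage_cohort)
    if "cohort" not in state:
        raise ValueError("the cohort stage is required")
    df = state["cohort"]

    # fail fast on unknown columns before any downstream compute
    referenced = [s for s in config.strata if s != "age_group"]
    missing_cols = [c for c in referenced if c not in df.columns]
    if missing_cols:
        manifest["stages"]["validate"] = {
            "status": "failed",
            "error": f"missing columns: {missing_cols}",
        }
        _write_json(manifest, out / "manifest.json")
        raise ValueError(
            f"config references columns absent from the cohort: {missing_cols}"
        )

    # -- score ---------------------------------------------------------------
    def stage_score():
        breakdown = score_cohort(df)
        breakdown.to_csv(out / "cvr_breakdown.tsv", sep="\t", index=False)
        state["breakdown"] = breakdown
        return ["cvr_breakdown.tsv"]

    run_stage("score", stage_score)

    # -- preprocess ------------------------------------------------------------
    def stage_preprocess():
        cvr = state.get("breakdown")
        mat, norm = build_model_matrix(
            df, cvr_total=None if cvr is None else cvr["cvr_total"]
        )
        mat.to_csv(out / "model_matrix.tsv", sep="\t", index=False)
        norm.to_json(out / "normalization.json")
        state["matrix"] = mat
        return ["model_matrix.tsv", "normalization.json"]

    run_stage("preprocess", stage_preprocess)

    # -- sem -------------------------------------------------------------------
    def stage_sem():
        mat = state["matrix"]
        spec = (
            SemModelSpec.from_file(config.sem_spec_path)
            if config.sem_spec_path
            else build_structural_spec()
        )
        fit = fit_sem(mat, spec, estimator=config.estimator)
        _write_json(fit.to_dict(), out / "sem_fit.json")
        fit.params_table().to_csv(out / "sem_params.tsv", sep="\t", index=False)
        comparisons = {}
        for var in ("gm", "wm"):
            if var not in spec.variables:
                continue
            nested = fit_sem(
                mat, constrain_variable_paths(spec, var), estimator=config.estimator
            )
            diff = chi_square_difference(fit, nested)
            comparisons[var] = {
                "delta_chisq": diff.delta_chisq,
                "delta_df": diff.delta_df,
                "p": diff.p_value,
                "nested_fit_indices": nested.fit_indices,
            }
        _write_json(comparisons, out / "nested_comparison.json")
        scores = factor_scores(fit, mat)
        scores.to_csv(out / "factor_scores.tsv", sep="\t", index=False)
        state["fit"] = fit
        state["scores"] = scores
        return [
            "sem_fit.json",
            "sem_params.tsv",
            "nested_comparison.json",
            "factor_scores.tsv",
        ]

    run_stage("sem", stage_sem)

    def _ef_score() -> pd.Series:
        if "scores" in state:
            return state["scores"]["ef"]
        mat = state["matrix"]
        # loading-free fallback: mean of the standardised cognitive columns
        return mat[["rt", "pairs"]].mean(axis=1)

    # -- windows ---------------------------------------------------------------
    def stage_windows():
        ef = _ef_score()
        sbp = df[["sbp_1", "sbp_2"]].mean(axis=1)
        keep = sbp.notna() & ef.notna()
        artifacts = []

        def emit(tag: str, sel) -> None:
            if sel.sum() < 1 / config.window_frac:
                return
            curve = sliding_window_curve(
                sbp[sel], ef[sel], config.window_frac, config.window_step
            )
            frame = curve.to_frame()
            frame["smoothed"] = gaussian_smooth(curve.means, config.smooth_kernel)
            name = f"window_{tag}.tsv"
            frame.to_csv(out / name, sep="\t", index=False)
            artifacts.append(name)

        emit("all", keep)
        for stratum in config.strata:
            if stratum == "age_group":
                mid = keep & (df["age"] < config.age_group_cut)
                emit("midlife", mid)
                emit("latelife", keep & ~ (df["age"] < config.age_group_cut))
            elif stratum in df.columns:
                flag = df[stratum].astype(bool)
                emit(f"{stratum}_yes", keep & flag)
                emit(f"{stratum}_no", keep & ~flag)
            else:
                raise ValueError(f"stratification column {stratum!r} not in cohort")
        return artifacts

    run_stage("windows", stage_windows)

    # -- regression --------------------------------------------------------------
    def stage_regression():
        ef = _ef_score()
        X = pd.DataFrame(index=df.index)
        X["whr"] = df["waist_cm"] / df["hip_cm"]
        X["smoking_code"] = df["smoking_status"].map({"never": 0, "ex": 1, "current": 2})
        X["on_cholesterol_medication"] = df["on_cholesterol_medication"].astype(float)
        X["on_bp_medication"] = df["on_bp_medication"].astype(float)
        X["diabetic"] = df["diabetic"].astype(float)
        X["apoe_points"] = df["apoe_genotype"].fillna("").str.count("4")
        X["age"] = df["age"]
        X["townsend"] = df["townsend"]
        result = fit_regression(ef, X[list(REGRESSION_COVARIATES)])
        result.table.reset_index().to_csv(out / "regression.tsv", sep="\t", index=False)
        _write_json(
            {
                "F": result.f_stat,
                "df_num": result.df_num,
                "df_den": result.df_den,
                "r_squared": result.r_squared,
                "n_used": result.n_used,
            },
            out / "regression.json",
        )
        return ["regression.tsv", "regression.json"]

    run_stage("regression", stage_regression)

    # -- mediation ----------------------------------------------------------------
    def stage_mediation():
        scores = state.get("scores")
        if scores is None:
            raise ValueError("mediation requires the sem stage (factor scores)")
        keep = scores.notna().all(axis=1)
        res = mediate(
            scores.loc[keep, "gm"],
            scores.loc[keep, "wm"],
            scores.loc[keep, "ef"],
            n_boot=config.n_boot,
            seed=config.seed,
        )
        _write_json(
            {
                "a_gm_to_wm": res.a,
                "b_wm_to_ef": res.b,
                "c_total": res.c_total,
                "c_direct": res.c_direct,
                "indirect": res.indirect,
                "boot_ci": list(res.boot_ci),
                "n_boot": res.n_boot,
                "seed": res.seed,
            },
            out / "mediation.json",
        )
        return ["mediation.json"]

    run_stage("mediation", stage_mediation)

    _write_json(manifest, out / "manifest.json")
    logger.removeHandler(fh)
    fh.close()
    return manifest
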