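"""Typed CSV loading, pipeline configuration and orchestration.

``load_table`` validates a CSV against one of the named schemas before any
analysis runs; ``run_pipeline`` chains design fitting, desirability
optimization, calibration/QC validation, release fitting and NCA from a
single declarative :class:`PipelineConfig`, writing all outputs plus a
provenance manifest to the output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import rsm, validation, release
from .nca import ConcTimeProfile, nca as run_nca, summarize_group

logger = logging.getLogger("doepk")

__all__ = [
    "SchemaError",
    "load_table",
    "design_factor_columns",
    "PipelineConfig",
    "run_pipeline",
]

# required columns per schema; design/response tables additionally accept
# arbitrary coded-factor and response columns.
SCHEMAS: dict[str, list[str]] = {
    "design": ["exp_no", "run_order", "point_type"],
    "calibration": ["concentration_ug_ml", "signal"],
    "qc": ["session", "nominal_ug_ml"],
    "release": ["time", "value"],
    "conctime": ["subject", "group", "time_h", "conc_ug_ml"],
    "peaks": ["tr", "w", "w05", "f", "w_half", "t0"],
    "factors": ["name", "symbol", "low", "centre", "high", "units"],
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` naming any missing column; non-numeric cells
    in numeric columns raise a parse error carrying the offending row number.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise SchemaError(f"{path}: empty file") from err
    missing = [c for c in SCHEMAS[schema] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    non_numeric = {"design": ["point_type"], "qc": ["session"],
                   "conctime": ["subject", "group"], "factors": ["name", "symbol", "units"]}
    for col in frame.columns:
        if col in non_numeric.get(schema, []):
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}"
            )
        frame[col] = coerced
    logger.info("loaded %s: %d rows (%s schema)", path.name, len(frame), schema)
    return frame


def design_factor_columns(frame: pd.DataFrame) -> list[str]:
    """Coded-factor columns of a design CSV.

    The design dialect is ``exp_no, run_order, <factors...>, point_type,
    <responses...>``, so the factor columns are exactly those between
    ``run_order`` and ``point_type``.
    """
    cols = list(frame.columns)
    try:
        start, stop = cols.index("run_order") + 1, cols.index("point_type")
    except ValueError as err:
        raise SchemaError("design table lacks run_order/point_type columns") from err
    if stop <= start:
        raise SchemaError("design table has no factor columns")
    return cols[start:stop]


class GoalSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    response: str
    direction: str
    low: float
    high: float
    target: float | None = None
    weight: float = 1.0


class PipelineConfig(BaseModel):
    """Declarative pipeline run: inputs, goals and numeric settings.

    Unknown keys are rejected at validation time so typos fail before any
    stage executes.
    """

    model_config = ConfigDict(extra="forbid")

    design_path: str
    response_names: list[str] = Field(default_factory=lambda: ["Y1", "Y2", "Y3"])
    goals: list[GoalSpec] = Field(default_factory=list)
    grid_resolution: int = 201
    calibration_path: str | None = None
    qc_path: str | None = None
    release_path: str | None = None
    release_model: str = "zero"
    conctime_path: str | None = None
    terminal_rule: str = "best-fit"
    seed: int = 0
    output_dir: str = "doepk_out"


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write results + manifest to disk.

    Returns the manifest dict.  Reruns with an identical config reproduce
    the numeric outputs (all randomness flows from ``config.seed``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.model_dump(), "outputs": {}, "stages": []}

    design = _stage("load-design")(load_table)(config.design_path, "design")
    factor_cols = design_factor_columns(design)
    manifest["stages"].append({"stage": "load-design", "rows": len(design)})

    models = []
    coef_rows = []
    for name in config.response_names:
        model = _stage(f"fit-{name}")(rsm.fit_quadratic)(
            design[["exp_no", "run_order", "point_type"] + factor_cols],
            design[name],
            name,
        )
        models.append(model)
        row = dict(zip(model.coef_names_, model.coef_))
        row.update(response=name, r_squared=model.r_squared_,
                   resid_std=model.resid_std_)
        anova = rsm.anova_lack_of_fit(model)
        anova.to_csv(out / f"anova_{name}.csv")
        coef_rows.append(row)
    coefs = pd.DataFrame(coef_rows).set_index("response")
    coefs.to_csv(out / "rsm_coefficients.csv")
    manifest["outputs"]["rsm_coefficients"] = "rsm_coefficients.csv"

    if config.goals:
        goals = [
            rsm.DesirabilityGoal(
                response_name=g.response, direction=g.direction,
                low=g.low, high=g.high, target=g.target, weight=g.weight,
            )
            for g in config.goals
        ]
        opt = _stage("optimize")(rsm.optimize_desirability)(
            models, goals, resolution=config.grid_resolution
        )
        optimum = {
            "coded": dict(zip(factor_cols, opt.coded.tolist())),
            "desirability": opt.desirability,
            "predictions": opt.predictions,
            "all_zero": opt.all_zero,
        }
        (out / "optimum.json").write_text(json.dumps(optimum, indent=2))
        manifest["outputs"]["optimum"] = "optimum.json"

    if config.calibration_path:
        cal = _stage("load-calibration")(load_table)(
            config.calibration_path, "calibration"
        )
        curve = _stage("fit-calibration")(validation.fit_calibration)(
            cal["concentration_ug_ml"], cal["signal"]
        )
        lod, loq = validation.lod_loq(curve.resid_std_, curve.slope_)
        report = {
            "slope": curve.slope_, "intercept": curve.intercept_,
            "r_squared": curve.r_squared_, "resid_std": curve.resid_std_,
            "lod_ug_ml": lod, "loq_ug_ml": loq,
        }
        (out / "validation.json").write_text(json.dumps(report, indent=2))
        manifest["outputs"]["validation"] = "validation.json"

    if config.release_path:
        rel = _stage("load-release")(load_table)(config.release_path, "release")
        fit = _stage("fit-release")(release.fit_release_model)(
            times=rel["time"], cumulative_pct=rel["value"],
            model=config.release_model,
        )
        (out / "release_fit.json").write_text(json.dumps({
            "model": config.release_model, "rate": fit.rate_,
            "intercept": fit.intercept_, "r_squared": fit.r_squared_,
        }, indent=2))
        manifest["outputs"]["release_fit"] = "release_fit.json"

    if config.conctime_path:
        ct = _stage("load-conctime")(load_table)(config.conctime_path, "conctime")
        results = []
        for (subj, grp), sub in ct.groupby(["subject", "group"]):
            profile = ConcTimeProfile(
                times=sub["time_h"].to_numpy(),
                concentrations=sub["conc_ug_ml"].to_numpy(),
                subject=str(subj), group=str(grp),
            )
            results.append(_stage("nca")(run_nca)(profile))
        frame = pd.DataFrame([r.to_dict() for r in results])
        frame.to_csv(out / "nca_results.csv", index=False)
        summaries = {}
        for grp, sub in frame.groupby("group"):
            if len(sub) >= 2:
                res = [r for r in results if r.group == grp]
                summaries[grp] = summarize_group(res).to_dict()
        (out / "nca_summary.json").write_text(json.dumps(summaries, indent=2))
        manifest["outputs"]["nca"] = "nca_results.csv"

    manifest["seed"] = config.seed
    from . import __version__
    manifest["version"] = __version__
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
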