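"""File round-tripping and experiment configuration.

Exchange formats are deliberately plain:

* ratings — CSV with header ``examinee,task,rater,score``, 1-based ids;
  missing triples are absent rows, and a score of ``-1`` on read is
  accepted as an explicit missing marker and dropped;
* parameters — JSON with keys ``theta, beta, gamma, d, K``; the d
  identification constraints are enforced on read;
* designs — CSV with header ``examinee,task,rater``;
* grid reports — CSV with columns
  ``C_R, C_I, index, mean_error, delta, pass, n_reps`` (per-replication
  errors are not part of the exchange format);
* experiment configs — YAML, unknown keys rejected.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MFRMParameters, RatingDataset
from .design import AssignmentDesign
from .errors import ConfigError, FacetLinkError, ParseError
from .estimation import McmcConfig
from .evaluate import CellResult, ExperimentConfig, GridReport
from .truth import DistributionSpec, NormalSpec

__all__ = [
    "write_ratings_csv",
    "read_ratings_csv",
    "write_parameters_json",
    "read_parameters_json",
    "write_design_csv",
    "write_grid_report_csv",
    "read_grid_report_csv",
    "load_config",
]

RATING_COLUMNS = ["examinee", "task", "rater", "score"]


def write_ratings_csv(data: RatingDataset, path) -> None:
    data.to_dataframe().to_csv(path, index=False)


def read_ratings_csv(
    path,
    J: int | None = None,
    I: int | None = None,  # noqa: E741
    R: int | None = None,
    K: int | None = None,
) -> RatingDataset:
    """Read a long-format ratings CSV.

    Ids are 1-based in the file.  Rows with score ``-1`` (the conventional
    missing marker) are dropped.  Dimensions default to the largest index
    observed; pass them explicitly when trailing examinees/tasks/raters
    have no ratings.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns) != RATING_COLUMNS:
        raise ParseError(f"expected header {','.join(RATING_COLUMNS)}, got {','.join(df.columns)}")
    for col in RATING_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else None
            raise ParseError(f"non-integer value in column {col!r}", line=line)
    df = df[df["score"] != -1]
    for col in ("examinee", "task", "rater"):
        bad = df.index[df[col] < 1]
        if len(bad):
            raise ParseError(f"{col} id < 1", line=int(bad[0]) + 2)
    J = J if J is not None else int(df["examinee"].max())
    I = I if I is not None else int(df["task"].max())  # noqa: E741
    R = R if R is not None else int(df["rater"].max())
    K = K if K is not None else int(df["score"].max())
    bad = df.index[(df["score"] < 1) | (df["score"] > K)]
    if len(bad):
        raise ParseError(f"score outside 1..{K}", line=int(bad[0]) + 2)
    try:
        return RatingDataset(
            examinee=df["examinee"].to_numpy() - 1,
            task=df["task"].to_numpy() - 1,
            rater=df["rater"].to_numpy() - 1,
            score=df["score"].to_numpy(),
            J=J,
            I=I,
            R=R,
            K=K,
        )
    except FacetLinkError as exc:
        raise ParseError(f"invalid ratings in {path}: {exc}") from exc


def write_parameters_json(params: MFRMParameters, path) -> None:
    payload = {
        "theta": params.theta.tolist(),
        "beta": params.beta.tolist(),
        "gamma": params.gamma.tolist(),
        "d": params.d.tolist(),
        "K": params.K,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_parameters_json(path) -> MFRMParameters:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse {path}: {exc}", line=exc.lineno) from exc
    missing = {"theta", "beta", "gamma", "d", "K"} - set(payload)
    if missing:
        raise ParseError(f"parameter file missing keys: {sorted(missing)}")
    try:
        return MFRMParameters(
            theta=np.asarray(payload["theta"], dtype=float),
            beta=np.asarray(payload["beta"], dtype=float),
            gamma=np.asarray(payload["gamma"], dtype=float),
            d=np.asarray(payload["d"], dtype=float),
            K=int(payload["K"]),
        )
    except FacetLinkError as exc:
        raise ParseError(f"invalid parameters in {path}: {exc}") from exc


def write_design_csv(design: AssignmentDesign, path) -> None:
    design.to_dataframe().to_csv(path, index=False)


def write_grid_report_csv(report: GridReport, path) -> None:
    df = report.to_dataframe()
    df.insert(0, "master_seed", report.master_seed)
    for name, value in (("K", report.K), ("R", report.R), ("I", report.I), ("J", report.J)):
        df.insert(0, name, value)
    df.insert(len(df.columns), "scope", report.scope)
    df.insert(len(df.columns), "replications", report.replications)
    df.to_csv(path, index=False, float_format="%.17g")


def read_grid_report_csv(path) -> GridReport:
    """Rebuild a GridReport from CSV (summary fields only, no raw errors)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    required = {"J", "I", "R", "K", "master_seed", "C_R", "C_I", "index",
                "mean_error", "delta", "pass", "n_reps", "scope", "replications"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"grid report missing columns: {sorted(missing)}")
    if df.empty:
        raise ParseError("grid report has no cells")
    cells = tuple(
        CellResult(
            C_R=int(row.C_R),
            C_I=int(row.C_I),
            errors=(),
            mean_error=float(row.mean_error),
            delta=float(row.delta),
            passed=bool(row["pass"]),
            n_reps=int(row.n_reps),
        )
        for _, row in df.iterrows()
    )
    first = df.iloc[0]
    return GridReport(
        cells=cells,
        index=str(first["index"]),
        scope=str(first["scope"]),
        J=int(first["J"]),
        I=int(first["I"]),
        R=int(first["R"]),
        K=int(first["K"]),
        replications=int(first["replications"]),
        master_seed=int(first["master_seed"]),
    )


# --------------------------------------------------------------------------
# YAML experiment configuration
# --------------------------------------------------------------------------

_CLASS_NAMES = ("theta", "beta", "gamma", "d")


def _reject_unknown(block: dict, allowed, where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {where}")


def _parse_normal(block, where: str) -> NormalSpec:
    if not isinstance(block, dict):
        raise ConfigError(f"{where} must be a mapping with mean/sd")
    _reject_unknown(block, ("mean", "sd"), where)
    try:
        return NormalSpec(mean=float(block.get("mean", 0.0)), sd=float(block.get("sd", 1.0)))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid number in {where}: {exc}") from exc


def _parse_spec(block, where: str) -> DistributionSpec:
    if block is None:
        return DistributionSpec.standard()
    if isinstance(block, str):
        name = block.strip().lower().replace(" ", "_")
        if name.startswith("distribution_"):
            try:
                return DistributionSpec.scenario(int(name.removeprefix("distribution_")))
            except ValueError as exc:
                raise ConfigError(f"bad scenario name {block!r} in {where}") from exc
        if name == "standard":
            return DistributionSpec.standard()
        raise ConfigError(f"unknown distribution name {block!r} in {where}")
    if not isinstance(block, dict):
        raise ConfigError(f"{where} must be a mapping or scenario name")
    _reject_unknown(block, _CLASS_NAMES, where)
    kwargs = {
        cls: _parse_normal(block[cls], f"{where}.{cls}") for cls in _CLASS_NAMES if cls in block
    }
    return DistributionSpec(**kwargs)


_TOP_KEYS = (
    "J", "I", "R", "K", "replications", "seed", "base", "new", "grid",
    "design", "drift", "error", "mcmc",
)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config, filling defaults.

    Defaults: K = 5, 30 replications, standard normal base and new
    distributions, complete data, no drift, RMSE over all free
    parameters, the default sampler, master seed 0.  Unknown keys are
    rejected with the offending key named.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        raise ParseError(
            f"cannot parse {path}: {exc}", line=None if mark is None else mark.line + 1
        ) from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    for req in ("J", "I", "R"):
        if req not in raw:
            raise ConfigError(f"config missing required key {req!r}")

    kwargs: dict = {
        "J": int(raw["J"]),
        "I": int(raw["I"]),
        "R": int(raw["R"]),
        "K": int(raw.get("K", 5)),
        "replications": int(raw.get("replications", 30)),
        "master_seed": int(raw.get("seed", 0)),
        "base_spec": _parse_spec(raw.get("base"), "base"),
        "new_spec": _parse_spec(raw.get("new"), "new"),
    }

    grid = raw.get("grid", {})
    if grid:
        _reject_unknown(grid, ("c_r", "c_i"), "grid")
        if "c_r" in grid:
            kwargs["c_r_grid"] = tuple(int(v) for v in grid["c_r"])
        if "c_i" in grid:
            kwargs["c_i_grid"] = tuple(int(v) for v in grid["c_i"])

    design = raw.get("design", "complete")
    if design in (None, "complete"):
        kwargs["n_r"] = None
    elif isinstance(design, dict):
        _reject_unknown(design, ("n_r",), "design")
        kwargs["n_r"] = int(design["n_r"])
    else:
        raise ConfigError(f"design must be 'complete' or a mapping with n_r, got {design!r}")

    drift = raw.get("drift", False)
    if isinstance(drift, bool):
        kwargs["drift"] = drift
    elif isinstance(drift, dict):
        _reject_unknown(drift, ("enabled", "sd_task", "sd_rater"), "drift")
        kwargs["drift"] = bool(drift.get("enabled", True))
        if "sd_task" in drift:
            kwargs["drift_sd_task"] = float(drift["sd_task"])
        if "sd_rater" in drift:
            kwargs["drift_sd_rater"] = float(drift["sd_rater"])
    else:
        raise ConfigError("drift must be a boolean or a mapping")

    error = raw.get("error", {})
    if error:
        _reject_unknown(error, ("index", "scope"), "error")
        if "index" in error:
            kwargs["error_index"] = str(error["index"])
        if "scope" in error:
            kwargs["error_scope"] = str(error["scope"])

    mcmc = raw.get("mcmc", {})
    if mcmc:
        _reject_unknown(
            mcmc, ("iterations", "burn_in", "thinning", "chains", "proposal_sd", "adapt", "seed"),
            "mcmc",
        )
        kwargs["mcmc"] = McmcConfig(**mcmc)

    return ExperimentConfig(**kwargs)
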