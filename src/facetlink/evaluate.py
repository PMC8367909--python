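"""The linking-accuracy simulation pipeline.

One *replication* runs the full six-step procedure: generate base-test
truth from standard normals -> generate new-test truth from the configured
(shifted) distributions -> embed C_R common raters and C_I common tasks ->
optionally build a rater-set design and/or drift the anchors -> sample the
new test's ratings -> estimate the new test by anchored EAP-MCMC -> score
the estimates against truth with an error index (RMSE by default).

Whether a given (C_R, C_I) supports accurate linking is decided against
the threshold delta = mu_e + 2 sigma_e, where mu_e and sigma_e are the
mean and sample SD of replication errors from a matched run in which the
new test's distributions equal the base test's — i.e. the error level when
the tests are trivially on one scale, so only data size (and design)
drives it.  A cell passes when its mean error falls below delta.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from .core import MFRMParameters
from .design import build_design
from .errors import ConfigError, ScopeError
from .estimation import FixedMask, McmcConfig, estimate_eap
from .seeds import SeedPlan, Stage
from .truth import (
    DRIFT_SD_RATER,
    DRIFT_SD_TASK,
    DistributionSpec,
    embed_common,
    generate_parameters,
    inject_drift,
    sample_dataset,
)

__all__ = [
    "ExperimentConfig",
    "CellResult",
    "GridReport",
    "compute_error",
    "threshold_from_errors",
    "run_replication",
    "compute_threshold",
    "run_grid",
]

logger = logging.getLogger(__name__)

ERROR_INDICES = ("rmse", "mae", "abs_mean_bias")
ERROR_SCOPES = ("all_free", "ability", "task", "rater", "category")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a grid experiment needs; see the module docstring."""

    J: int
    I: int  # noqa: E741
    R: int
    K: int = 5
    base_spec: DistributionSpec = field(default_factory=DistributionSpec.standard)
    new_spec: DistributionSpec = field(default_factory=DistributionSpec.standard)
    c_r_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    c_i_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    replications: int = 30
    n_r: int | None = None  # None -> complete data; else rater-set design N_R
    drift: bool = False
    drift_sd_task: float = DRIFT_SD_TASK
    drift_sd_rater: float = DRIFT_SD_RATER
    error_index: str = "rmse"
    error_scope: str = "all_free"
    extra_errors: tuple[tuple[str, str], ...] = ()
    include_anchored: bool = False  # score anchored entries too (sensitivity flag)
    anchor_at_estimates: bool = False  # fix anchors at base-test estimates, not truth
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    master_seed: int = 0

    def __post_init__(self):
        if min(self.J, self.I, self.R) < 1:
            raise ConfigError("J, I, R must all be >= 1")
        if self.K < 2:
            raise ConfigError(f"K must be >= 2, got {self.K}")
        if self.replications < 2:
            raise ConfigError(
                f"replications must be >= 2 (the threshold needs a sample SD), "
                f"got {self.replications}"
            )
        if self.n_r is not None and not (2 <= self.n_r <= self.R):
            from .errors import DesignError

            raise DesignError(
                f"N_R must satisfy 2 <= N_R <= R, got N_R={self.n_r}, R={self.R}"
            )
        for c in self.c_r_grid:
            if not (0 <= c <= self.R):
                raise ConfigError(f"C_R = {c} outside [0, R = {self.R}]")
        for c in self.c_i_grid:
            if not (0 <= c <= self.I):
                raise ConfigError(f"C_I = {c} outside [0, I = {self.I}]")
        for index, scope in ((self.error_index, self.error_scope), *self.extra_errors):
            if index not in ERROR_INDICES:
                raise ConfigError(f"unknown error index {index!r}; choose {ERROR_INDICES}")
            if scope not in ERROR_SCOPES:
                raise ConfigError(f"unknown error scope {scope!r}; choose {ERROR_SCOPES}")

    @property
    def primary_key(self) -> str:
        return f"{self.error_index}:{self.error_scope}"


def compute_error(
    est: MFRMParameters,
    truth: MFRMParameters,
    index: str = "rmse",
    scope: str = "all_free",
    mask: FixedMask | None = None,
) -> float:
    """Error index over the scope's free parameters.

    ``mask`` identifies anchored beta/gamma entries, which are excluded
    (their deviation is identically zero and would deflate the index);
    pass ``mask=None`` to score every parameter.  The category scope is
    d_2..d_K (d_1 is structurally zero for both est and truth).
    """
    if (est.J, est.I, est.R, est.K) != (truth.J, truth.I, truth.R, truth.K):
        raise ScopeError("estimate and truth dimensions differ")
    if index not in ERROR_INDICES:
        raise ScopeError(f"unknown error index {index!r}")
    fixed_b = np.asarray(mask.beta_indices if mask else (), dtype=int)
    fixed_g = np.asarray(mask.gamma_indices if mask else (), dtype=int)
    free_b = np.setdiff1d(np.arange(est.I), fixed_b)
    free_g = np.setdiff1d(np.arange(est.R), fixed_g)
    parts = {
        "ability": [est.theta - truth.theta],
        "task": [est.beta[free_b] - truth.beta[free_b]],
        "rater": [est.gamma[free_g] - truth.gamma[free_g]],
        "category": [est.d[1:] - truth.d[1:]],
    }
    parts["all_free"] = parts["ability"] + parts["task"] + parts["rater"] + parts["category"]
    if scope not in parts:
        raise ScopeError(f"unknown error scope {scope!r}")
    dev = np.concatenate(parts[scope]) if parts[scope] else np.empty(0)
    if dev.size == 0:
        raise ScopeError(f"scope {scope!r} selects no free parameters")
    if index == "rmse":
        return float(np.sqrt(np.mean(dev * dev)))
    if index == "mae":
        return float(np.mean(np.abs(dev)))
    return float(abs(np.mean(dev)))  # abs_mean_bias


def threshold_from_errors(errors) -> float:
    """delta = mu_e + 2 sigma_e with the n-1 sample SD."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise ConfigError("threshold needs at least 2 replication errors")
    return float(errors.mean() + 2.0 * errors.std(ddof=1))


def run_replication(
    config: ExperimentConfig,
    C_R: int,
    C_I: int,
    rep_seed,
) -> dict[str, float]:
    """One full six-step replication; returns errors keyed "index:scope".

    ``rep_seed`` may be an int or a ``numpy.random.SeedSequence``; all
    stage streams (base/new generation, embedding, drift, sampling, MCMC)
    are spawned from it, so the result is a pure function of
    (config, C_R, C_I, rep_seed).
    """
    ss = rep_seed if isinstance(rep_seed, np.random.SeedSequence) else np.random.SeedSequence(rep_seed)
    s_base, s_new, s_embed, s_drift, s_sample, s_mcmc, s_anchor = ss.spawn(7)

    base = generate_parameters(
        config.J, config.I, config.R, config.K, config.base_spec, np.random.default_rng(s_base)
    )
    new = generate_parameters(
        config.J, config.I, config.R, config.K, config.new_spec, np.random.default_rng(s_new)
    )
    new, layout = embed_common(base, new, C_R, C_I, np.random.default_rng(s_embed))

    if config.anchor_at_estimates:
        layout = _reanchor_at_estimates(config, base, layout, s_anchor)

    sampling_params = new
    if config.drift:
        sampling_params = inject_drift(
            new,
            layout,
            sd_task=config.drift_sd_task,
            sd_rater=config.drift_sd_rater,
            rng=np.random.default_rng(s_drift),
        )
    design = build_design(config.J, config.I, config.R, config.n_r) if config.n_r else None
    data = sample_dataset(sampling_params, design, np.random.default_rng(s_sample))

    mask = FixedMask.from_layout(layout)
    mcmc_seed = int(s_mcmc.generate_state(1)[0] % (2**31))
    est, diag = estimate_eap(data, mask, replace(config.mcmc, seed=mcmc_seed))

    score_mask = None if config.include_anchored else mask
    errors = {}
    for index, scope in ((config.error_index, config.error_scope), *config.extra_errors):
        errors[f"{index}:{scope}"] = compute_error(est, new, index, scope, mask=score_mask)
    logger.info(
        "replication C_R=%d C_I=%d seed=%s mcmc_seed=%d n_records=%d errors=%s",
        C_R, C_I, ss.spawn_key or ss.entropy, mcmc_seed, data.n_records, errors,
    )
    if not all(np.isfinite(v) for v in errors.values()):
        raise ConfigError(f"non-finite replication error: {errors}")
    return errors


def _reanchor_at_estimates(config, base, layout, seed_seq):
    """Replace anchor values by base-test EAP estimates (off by default).

    The base test is sampled under the same design and estimated
    stand-alone (gamma_1 pinned); the anchors then carry the base test's
    estimation error, as they would when the base calibration is real.
    """
    s_sample, s_mcmc = seed_seq.spawn(2)
    design = build_design(config.J, config.I, config.R, config.n_r) if config.n_r else None
    base_data = sample_dataset(base, design, np.random.default_rng(s_sample))
    mcmc_seed = int(s_mcmc.generate_state(1)[0] % (2**31))
    base_est, _ = estimate_eap(base_data, FixedMask.empty(), replace(config.mcmc, seed=mcmc_seed))
    return replace(
        layout,
        anchor_gamma=tuple(float(base_est.gamma[b]) for b, _ in layout.common_rater_pairs),
        anchor_beta=tuple(float(base_est.beta[b]) for b, _ in layout.common_task_pairs),
    )


@dataclass(frozen=True)
class CellResult:
    """Replication errors, mean, threshold and pass flag for one grid cell."""

    C_R: int
    C_I: int
    errors: tuple[float, ...]
    mean_error: float
    delta: float
    passed: bool
    n_reps: int

    def __post_init__(self):
        if self.passed != (self.mean_error < self.delta):
            raise ConfigError("pass flag inconsistent with mean_error < delta")

    @classmethod
    def from_errors(cls, C_R, C_I, errors, delta) -> "CellResult":
        errors = tuple(float(e) for e in errors)
        mean = float(np.mean(errors))
        return cls(
            C_R=C_R,
            C_I=C_I,
            errors=errors,
            mean_error=mean,
            delta=float(delta),
            passed=bool(mean < delta),
            n_reps=len(errors),
        )


@dataclass(frozen=True)
class GridReport:
    """Per-cell linking accuracy over a (C_R, C_I) grid."""

    cells: tuple[CellResult, ...]
    index: str
    scope: str
    J: int
    I: int  # noqa: E741
    R: int
    K: int
    replications: int
    master_seed: int

    def cell(self, C_R: int, C_I: int) -> CellResult:
        for c in self.cells:
            if (c.C_R, c.C_I) == (C_R, C_I):
                return c
        raise KeyError(f"no cell ({C_R}, {C_I})")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "C_R": [c.C_R for c in self.cells],
                "C_I": [c.C_I for c in self.cells],
                "index": [self.index for _ in self.cells],
                "mean_error": [c.mean_error for c in self.cells],
                "delta": [c.delta for c in self.cells],
                "pass": [c.passed for c in self.cells],
                "n_reps": [c.n_reps for c in self.cells],
            }
        )

    def format_table(self) -> str:
        """Text table: rows C_R, columns C_I, "mean (delta)", '*' marks a pass."""

        def fmt(x: float) -> str:
            return f"{x:.4f}".lstrip("0")

        c_r_values = sorted({c.C_R for c in self.cells})
        c_i_values = sorted({c.C_I for c in self.cells})
        header = ["C_R"] + [f"C_I={ci}" for ci in c_i_values]
        rows = [header]
        for cr in c_r_values:
            row = [str(cr)]
            for ci in c_i_values:
                try:
                    c = self.cell(cr, ci)
                except KeyError:
                    row.append("-")
                    continue
                mark = "*" if c.passed else " "
                row.append(f"{mark}{fmt(c.mean_error)} ({fmt(c.delta)})")
            rows.append(row)
        widths = [max(len(r[k]) for r in rows) for k in range(len(header))]
        lines = ["  ".join(r[k].ljust(widths[k]) for k in range(len(r))) for r in rows]
        title = (
            f"{self.index} ({self.scope}), J={self.J} I={self.I} R={self.R} K={self.K}, "
            f"{self.replications} replications; '*' = mean below threshold delta"
        )
        return title + "\n" + "\n".join(lines)


def _replication_with_retry(config, C_R, C_I, rep, stage, plan) -> float | None:
    """Run one replication; retry once on failure with a fresh derived seed."""
    for attempt, stage_code in enumerate((int(stage), int(stage) + 2)):
        seq = plan.sequence(C_R, C_I, rep, stage_code)
        try:
            return run_replication(config, C_R, C_I, seq)[config.primary_key]
        except ConfigError as exc:
            logger.warning(
                "replication failed (C_R=%d C_I=%d rep=%d stage=%d attempt=%d): %s",
                C_R, C_I, rep, int(stage), attempt, exc,
            )
    logger.warning(
        "replication excluded after retry: C_R=%d C_I=%d rep=%d stage=%d",
        C_R, C_I, rep, int(stage),
    )
    return None


def _cell_errors(config, C_R, C_I, stage) -> list[float]:
    plan = SeedPlan(config.master_seed)
    errors = []
    for rep in range(config.replications):
        e = _replication_with_retry(config, C_R, C_I, rep, stage, plan)
        if e is not None:
            errors.append(e)
    if len(errors) < 2:
        raise ConfigError(f"fewer than 2 successful replications in cell ({C_R}, {C_I})")
    return errors


def compute_threshold(config: ExperimentConfig, C_R: int, C_I: int, rep_seeds=None) -> float:
    """Threshold delta for one cell.

    Reruns the replications with the new test's distributions replaced by
    the base test's, so the only remaining error is estimation noise at
    this data size and design; delta = mu_e + 2 sigma_e of those errors.
    With ``rep_seeds=None`` the seeds come from the config's master seed
    (threshold stage), so delta is shared across configs that differ only
    in the new-test distributions — matching how a single delta serves all
    distribution scenarios of equal data size.
    """
    null_config = replace(config, new_spec=config.base_spec, drift=False)
    if rep_seeds is None:
        return threshold_from_errors(_cell_errors(null_config, C_R, C_I, Stage.THRESHOLD))
    errors = [run_replication(null_config, C_R, C_I, s)[config.primary_key] for s in rep_seeds]
    return threshold_from_errors(errors)


def run_grid(config: ExperimentConfig) -> GridReport:
    """Mean error, threshold and pass flag for every (C_R, C_I) cell.

    Per-replication seeds derive from the master seed via :class:`SeedPlan`,
    so cells are independent and rerunnable in any order.
    """
    cells = []
    for C_R, C_I in product(config.c_r_grid, config.c_i_grid):
        errors = _cell_errors(config, C_R, C_I, Stage.EVALUATION)
        delta = compute_threshold(config, C_R, C_I)
        cells.append(CellResult.from_errors(C_R, C_I, errors, delta))
        logger.info(
            "cell C_R=%d C_I=%d mean=%.4f delta=%.4f pass=%s",
            C_R, C_I, cells[-1].mean_error, delta, cells[-1].passed,
        )
    return GridReport(
        cells=tuple(cells),
        index=config.error_index,
        scope=config.error_scope,
        J=config.J,
        I=config.I,
        R=config.R,
        K=config.K,
        replications=config.replications,
        master_seed=config.master_seed,
    )
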