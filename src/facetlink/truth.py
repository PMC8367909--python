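"""True-parameter generation for base and new tests.

A linking simulation needs two tests with known truth: a *base* test whose
parameters define the scale, and a *new* test whose parameters are drawn
from (possibly shifted) normal distributions and must be recovered on the
base scale.  C_R raters and C_I tasks of the base test are embedded into
the new test as common anchors; optionally the anchors drift (small
zero-mean normal fluctuations) between administrations, affecting the data
actually sampled but not the anchor values fixed during estimation.

All randomness flows through explicit numpy Generators, so every draw is
reproducible from a seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import MFRMParameters, RatingDataset, category_probabilities
from .design import AssignmentDesign
from .errors import ConfigError, DataError, LayoutError

__all__ = [
    "NormalSpec",
    "DistributionSpec",
    "LinkingLayout",
    "generate_parameters",
    "embed_common",
    "inject_drift",
    "sample_dataset",
    "n_drifted_tasks",
    "n_drifted_raters",
    "standard_error_of_mean",
    "ability_shift_halfwidth",
]

#: Drift fluctuation SDs (logits) for common tasks and raters, matching
#: empirical item-drift and rater-drift magnitudes.
DRIFT_SD_TASK = 0.05
DRIFT_SD_RATER = 0.10


@dataclass(frozen=True)
class NormalSpec:
    """Mean and SD of a normal generating distribution."""

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if not (self.sd > 0):
            raise ConfigError(f"sd must be > 0, got {self.sd}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)


@dataclass(frozen=True)
class DistributionSpec:
    """Generating distributions per parameter class (theta, beta, gamma, d)."""

    theta: NormalSpec = field(default_factory=NormalSpec)
    beta: NormalSpec = field(default_factory=NormalSpec)
    gamma: NormalSpec = field(default_factory=NormalSpec)
    d: NormalSpec = field(default_factory=NormalSpec)

    @classmethod
    def standard(cls) -> "DistributionSpec":
        """All classes standard normal — the base-test (and prior) distributions."""
        return cls()

    @classmethod
    def scenario(cls, number: int) -> "DistributionSpec":
        """The four new-test shift scenarios studied for linking accuracy.

        1: theta ~ N(-0.5, 1)                      (baseline ability shift)
        2: theta ~ N(-0.2, 1)                      (small ability shift)
        3: theta ~ N(-0.5, 1), beta ~ N(0.5, 1)    (ability + task shift)
        4: theta ~ N(-0.5, 1), gamma ~ N(0.5, 1)   (ability + rater shift)
        """
        table = {
            1: cls(theta=NormalSpec(-0.5, 1.0)),
            2: cls(theta=NormalSpec(-0.2, 1.0)),
            3: cls(theta=NormalSpec(-0.5, 1.0), beta=NormalSpec(0.5, 1.0)),
            4: cls(theta=NormalSpec(-0.5, 1.0), gamma=NormalSpec(0.5, 1.0)),
        }
        if number not in table:
            raise ConfigError(f"unknown distribution scenario {number}; choose 1-4")
        return table[number]


@dataclass(frozen=True)
class LinkingLayout:
    """Identity and anchor values of the common raters/tasks.

    ``common_rater_pairs``/``common_task_pairs`` hold (base_index,
    new_index) pairs, 0-based.  ``anchor_gamma``/``anchor_beta`` are the
    base-test values installed at the new-test slots; they are what gets
    fixed during anchored estimation, regardless of any drift applied to
    the sampling copy of the parameters.
    """

    C_R: int
    C_I: int
    common_rater_pairs: tuple[tuple[int, int], ...]
    common_task_pairs: tuple[tuple[int, int], ...]
    anchor_gamma: tuple[float, ...]
    anchor_beta: tuple[float, ...]

    def __post_init__(self):
        if self.C_R != len(self.common_rater_pairs) or self.C_R != len(self.anchor_gamma):
            raise LayoutError("C_R inconsistent with rater pairs / anchor values")
        if self.C_I != len(self.common_task_pairs) or self.C_I != len(self.anchor_beta):
            raise LayoutError("C_I inconsistent with task pairs / anchor values")
        for pairs, what in ((self.common_rater_pairs, "rater"), (self.common_task_pairs, "task")):
            for side in (0, 1):
                idx = [p[side] for p in pairs]
                if len(set(idx)) != len(idx):
                    raise LayoutError(f"duplicate {what} index on side {side}")

    @property
    def new_rater_indices(self) -> tuple[int, ...]:
        return tuple(p[1] for p in self.common_rater_pairs)

    @property
    def new_task_indices(self) -> tuple[int, ...]:
        return tuple(p[1] for p in self.common_task_pairs)


def generate_parameters(
    J: int,
    I: int,  # noqa: E741
    R: int,
    K: int,
    spec: DistributionSpec,
    rng: np.random.Generator,
) -> MFRMParameters:
    """Draw one test's true parameters from ``spec``.

    theta, beta, gamma are i.i.d. normal draws.  For the category
    parameters, K-1 values are drawn from the d distribution, sorted
    ascending (transitions get harder with the category in practice) and
    mean-centred so they total zero; d_1 = 0 structurally.
    """
    if K < 2:
        raise ConfigError(f"K must be >= 2, got {K}")
    theta = spec.theta.draw(J, rng)
    beta = spec.beta.draw(I, rng)
    gamma = spec.gamma.draw(R, rng)
    upper = np.sort(spec.d.draw(K - 1, rng))
    upper -= upper.mean()
    d = np.concatenate([[0.0], upper])
    return MFRMParameters(theta=theta, beta=beta, gamma=gamma, d=d, K=K)


def embed_common(
    base: MFRMParameters,
    new: MFRMParameters,
    C_R: int,
    C_I: int,
    rng: np.random.Generator,
) -> tuple[MFRMParameters, LinkingLayout]:
    """Embed C_R base raters and C_I base tasks into the new test.

    Base raters/tasks and the new-test slots they replace are both drawn
    uniformly at random without replacement (slot identity is exchangeable
    under i.i.d. generation).  Returns the modified new-test parameters and
    the layout recording the mapping and anchor values.
    """
    if not (0 <= C_R <= min(base.R, new.R)):
        raise LayoutError(f"C_R = {C_R} outside [0, {min(base.R, new.R)}]")
    if not (0 <= C_I <= min(base.I, new.I)):
        raise LayoutError(f"C_I = {C_I} outside [0, {min(base.I, new.I)}]")
    base_r = rng.choice(base.R, size=C_R, replace=False)
    new_r = rng.choice(new.R, size=C_R, replace=False)
    base_i = rng.choice(base.I, size=C_I, replace=False)
    new_i = rng.choice(new.I, size=C_I, replace=False)
    gamma = new.gamma.copy()
    beta = new.beta.copy()
    gamma[new_r] = base.gamma[base_r]
    beta[new_i] = base.beta[base_i]
    layout = LinkingLayout(
        C_R=C_R,
        C_I=C_I,
        common_rater_pairs=tuple((int(b), int(n)) for b, n in zip(base_r, new_r)),
        common_task_pairs=tuple((int(b), int(n)) for b, n in zip(base_i, new_i)),
        anchor_gamma=tuple(float(v) for v in base.gamma[base_r]),
        anchor_beta=tuple(float(v) for v in base.beta[base_i]),
    )
    return new.replace(gamma=gamma, beta=beta), layout


def n_drifted_tasks(C_I: int) -> int:
    """floor(C_I/2) + (C_I mod 2) — about half the common tasks drift."""
    return C_I // 2 + C_I % 2


def n_drifted_raters(C_R: int) -> int:
    """floor((C_R-1)/2) + ((C_R-1) mod 2) — about half the common raters drift."""
    return (C_R - 1) // 2 + (C_R - 1) % 2


def inject_drift(
    new: MFRMParameters,
    layout: LinkingLayout,
    sd_task: float = DRIFT_SD_TASK,
    sd_rater: float = DRIFT_SD_RATER,
    rng: np.random.Generator | None = None,
) -> MFRMParameters:
    """Sampling-only copy of ``new`` with drifted common raters/tasks.

    A subset of the common tasks and raters (counts per
    :func:`n_drifted_tasks` / :func:`n_drifted_raters`, chosen uniformly
    among the commons) receives an additive zero-mean normal fluctuation.
    The returned copy is used only for sampling rating data; anchored
    estimation keeps the original values recorded in the layout.  theta
    and d are returned bit-identical.
    """
    if rng is None:
        rng = np.random.default_rng()
    for idx, n, what in (
        (layout.new_task_indices, new.I, "task"),
        (layout.new_rater_indices, new.R, "rater"),
    ):
        if any(i >= n for i in idx):
            raise LayoutError(f"layout {what} index outside the new test's dimensions")
    beta = new.beta.copy()
    gamma = new.gamma.copy()
    nt = n_drifted_tasks(layout.C_I)
    nr = n_drifted_raters(layout.C_R)
    if nt:
        pick = rng.choice(layout.C_I, size=nt, replace=False)
        tasks = np.asarray(layout.new_task_indices)[pick]
        beta[tasks] += rng.normal(0.0, sd_task, size=nt)
    if nr:
        pick = rng.choice(layout.C_R, size=nr, replace=False)
        raters = np.asarray(layout.new_rater_indices)[pick]
        gamma[raters] += rng.normal(0.0, sd_rater, size=nr)
    return new.replace(beta=beta, gamma=gamma)


def sample_dataset(
    params: MFRMParameters,
    design: AssignmentDesign | None = None,
    rng: np.random.Generator | None = None,
) -> RatingDataset:
    """Sample one score per assigned (examinee, task, rater) triple.

    ``design=None`` means the complete design: every rater grades every
    (examinee, task) target.  Scores are drawn by inverting the model CDF
    against a single uniform per record, so runs sharing a generator state
    are paired record-by-record (common random numbers) even when the
    parameters differ slightly, e.g. with and without drift.
    """
    if rng is None:
        rng = np.random.default_rng()
    J, I, R = params.J, params.I, params.R
    if design is None:
        jj, ii, rr = np.meshgrid(np.arange(J), np.arange(I), np.arange(R), indexing="ij")
        jj, ii, rr = jj.ravel(), ii.ravel(), rr.ravel()
    else:
        if (design.J, design.I) != (J, I) or design.R != R:
            raise DataError(
                f"design dimensions {(design.J, design.I, design.R)} do not match "
                f"parameters {(J, I, R)}"
            )
        jj, ii, _ = np.meshgrid(
            np.arange(J), np.arange(I), np.arange(design.N_R), indexing="ij"
        )
        jj, ii = jj.ravel(), ii.ravel()
        rr = design.assignment.ravel()
    eta = params.theta[jj] - params.beta[ii] - params.gamma[rr]
    probs = category_probabilities(eta, params.d, params.K)
    cdf = np.cumsum(probs, axis=-1)
    u = rng.random(len(eta))
    scores = (cdf < u[:, None]).sum(axis=-1) + 1
    np.minimum(scores, params.K, out=scores)
    return RatingDataset(
        examinee=jj, task=ii, rater=rr, score=scores, J=J, I=I, R=R, K=params.K
    )


def standard_error_of_mean(n: int) -> float:
    """SEM of the mean of n draws from a unit-variance population: 1/sqrt(n).

    Motivates the baseline ability shift of 0.5: with n = 100 examinees the
    SEM is 0.1, so observed between-test mean differences rarely exceed the
    ±2.5 SEM band (:func:`ability_shift_halfwidth`).
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    return 1.0 / math.sqrt(n)


def ability_shift_halfwidth(n: int, z: float = 2.5) -> float:
    """Half-width z * SEM of the plausible between-test mean-shift band."""
    return z * standard_error_of_mean(n)
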