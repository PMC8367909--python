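"""Many-facet Rasch model (MFRM) core.

The MFRM is an adjacent-categories Rasch model for polytomous ratings
x_ijr in {1..K} assigned by rater r to examinee j's performance on task i:

    P(x_ijr = k) = exp( sum_{m<=k} [theta_j - beta_i - gamma_r - d_m] )
                   / sum_{l=1}^K exp( sum_{m<=l} [theta_j - beta_i - gamma_r - d_m] )

with theta_j the examinee ability, beta_i the task difficulty, gamma_r the
rater severity and d_k the category-transition parameter, all on the logit
scale.  Identification fixes d_1 = 0 and sum_{k>=2} d_k = 0 structurally;
gamma_1 = 0 is an estimation-time constraint (see
:mod:`facetlink.estimation`), not a field invariant of the parameter
container.

The model is invariant to the translations
(theta, beta, gamma) -> (theta + a + b, beta + a, gamma + b), which is
exactly why separately calibrated tests need linking.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import record_loglik
from .errors import DataError, DimensionError, ModelInputError

__all__ = [
    "D_SUM_TOL",
    "MFRMParameters",
    "RatingDataset",
    "category_probabilities",
    "log_likelihood",
    "sample_response",
]

#: Tolerance for the sum-to-zero constraint on d_2..d_K.
D_SUM_TOL = 1e-12


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ModelInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class MFRMParameters:
    """One test's full MFRM parameter set.

    Attributes
    ----------
    theta : (J,) examinee abilities (logits).
    beta : (I,) task difficulties (logits).
    gamma : (R,) rater severities (logits).
    d : (K,) category-transition parameters; d[0] == 0 exactly and
        d[1:] sums to zero within :data:`D_SUM_TOL`.
    K : number of rating categories (>= 2).
    """

    theta: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    d: np.ndarray
    K: int

    def __post_init__(self):
        object.__setattr__(self, "theta", _as_float_vector(self.theta, "theta"))
        object.__setattr__(self, "beta", _as_float_vector(self.beta, "beta"))
        object.__setattr__(self, "gamma", _as_float_vector(self.gamma, "gamma"))
        object.__setattr__(self, "d", _as_float_vector(self.d, "d"))
        if self.K < 2:
            raise DimensionError(f"K must be >= 2, got {self.K}")
        if len(self.d) != self.K:
            raise DimensionError(f"len(d) = {len(self.d)} does not match K = {self.K}")
        if self.d[0] != 0.0:
            raise ModelInputError(f"d[0] must be exactly 0, got {self.d[0]!r}")
        s = float(self.d[1:].sum())
        if abs(s) > D_SUM_TOL:
            raise ModelInputError(f"sum of d[1:] must be 0 within {D_SUM_TOL}, got {s!r}")

    @property
    def J(self) -> int:
        return len(self.theta)

    @property
    def I(self) -> int:  # noqa: E743 - field name from the measurement literature
        return len(self.beta)

    @property
    def R(self) -> int:
        return len(self.gamma)

    def replace(self, **kwargs) -> "MFRMParameters":
        """Return a copy with the given fields replaced."""
        fields = dict(theta=self.theta, beta=self.beta, gamma=self.gamma, d=self.d, K=self.K)
        fields.update(kwargs)
        return MFRMParameters(**fields)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MFRMParameters):
            return NotImplemented
        return (
            self.K == other.K
            and np.array_equal(self.theta, other.theta)
            and np.array_equal(self.beta, other.beta)
            and np.array_equal(self.gamma, other.gamma)
            and np.array_equal(self.d, other.d)
        )


@dataclass(frozen=True)
class RatingDataset:
    """Long-format observed ratings with missing-by-design entries.

    Each record is a (examinee, task, rater, score) tuple with 0-based
    indices and score in {1..K}.  Missing (examinee, task, rater) triples
    are simply absent; the ``-1`` score sentinel used in flat-file exchange
    is handled at I/O time (:mod:`facetlink.io`), never stored here.
    """

    examinee: np.ndarray
    task: np.ndarray
    rater: np.ndarray
    score: np.ndarray
    J: int
    I: int  # noqa: E741
    R: int
    K: int

    def __post_init__(self):
        for name in ("examinee", "task", "rater", "score"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.ndim != 1:
                raise DimensionError(f"{name} must be 1-D")
            object.__setattr__(self, name, arr)
        n = len(self.score)
        if not (len(self.examinee) == len(self.task) == len(self.rater) == n):
            raise DimensionError("record columns have unequal lengths")
        for name, bound in (("examinee", self.J), ("task", self.I), ("rater", self.R)):
            arr = getattr(self, name)
            if n and (arr.min() < 0 or arr.max() >= bound):
                raise DataError(f"{name} index outside [0, {bound})")
        if n and (self.score.min() < 1 or self.score.max() > self.K):
            raise DataError(f"scores must lie in 1..{self.K}")
        flat = (self.examinee * self.I + self.task) * self.R + self.rater
        if n and len(np.unique(flat)) != n:
            raise DataError("duplicate (examinee, task, rater) triples")

    @property
    def n_records(self) -> int:
        return len(self.score)

    def to_dataframe(self):
        """Long-format DataFrame with 1-based ids, as used in files/reports."""
        import pandas as pd

        return pd.DataFrame(
            {
                "examinee": self.examinee + 1,
                "task": self.task + 1,
                "rater": self.rater + 1,
                "score": self.score,
            }
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, RatingDataset):
            return NotImplemented
        return (
            (self.J, self.I, self.R, self.K) == (other.J, other.I, other.R, other.K)
            and np.array_equal(self.examinee, other.examinee)
            and np.array_equal(self.task, other.task)
            and np.array_equal(self.rater, other.rater)
            and np.array_equal(self.score, other.score)
        )


def _check_eta_d(eta, d, K):
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ModelInputError("d contains non-finite values")
    if K is None:
        K = len(d)
    if len(d) != K:
        raise DimensionError(f"len(d) = {len(d)} does not match K = {K}")
    if K < 2:
        raise DimensionError(f"K must be >= 2, got {K}")
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ModelInputError("eta is not finite")
    return eta, d, K


def category_probabilities(eta, d, K: int | None = None) -> np.ndarray:
    """Category probabilities (P_1..P_K) of the adjacent-categories model.

    ``eta`` is the linear predictor theta_j - beta_i - gamma_r.  Accepts a
    scalar or an array of etas; the category axis is last.  Computed with
    max-subtraction so large |eta| cannot overflow.
    """
    eta, d, K = _check_eta_d(eta, d, K)
    cum_d = np.cumsum(d)
    lvec = np.arange(1, K + 1, dtype=float)
    psi = np.multiply.outer(eta, lvec) - cum_d  # cumulative logits
    psi -= psi.max(axis=-1, keepdims=True)
    np.exp(psi, out=psi)
    psi /= psi.sum(axis=-1, keepdims=True)
    return psi


def log_likelihood(params: MFRMParameters, data: RatingDataset) -> float:
    """Log-likelihood of the observed records; missing triples contribute 0."""
    if (data.J, data.I, data.R, data.K) != (params.J, params.I, params.R, params.K):
        raise DimensionError(
            f"data dimensions {(data.J, data.I, data.R, data.K)} do not match "
            f"parameters {(params.J, params.I, params.R, params.K)}"
        )
    if data.n_records == 0:
        return 0.0
    eta = params.theta[data.examinee] - params.beta[data.task] - params.gamma[data.rater]
    ll, _ = record_loglik(eta, data.score - 1, np.cumsum(params.d), data.examinee, params.J)
    return float(ll.sum())


def sample_response(eta, d, K: int | None = None, rng: np.random.Generator | None = None):
    """Draw a score in 1..K from the model at ``eta``.

    Vectorized over ``eta``; returns an int for scalar input.  Reproducible
    given the generator's state.
    """
    if rng is None:
        rng = np.random.default_rng()
    probs = category_probabilities(eta, d, K)
    scalar = probs.ndim == 1
    probs = np.atleast_2d(probs)
    cdf = np.cumsum(probs, axis=-1)
    u = rng.random(probs.shape[0])
    scores = (cdf < u[:, None]).sum(axis=-1) + 1
    np.minimum(scores, probs.shape[-1], out=scores)  # guard float round-off in cdf[-1]
    return int(scores[0]) if scalar else scores
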