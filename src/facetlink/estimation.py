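"""Bayesian EAP estimation of MFRM parameters with fixed anchors.

Estimation follows the fixed-common-parameters linking method: the new
test's parameters are sampled from their joint posterior under standard
normal priors while the gamma/beta entries of common raters/tasks stay
clamped at their base-test values.  Point estimates are posterior means
(EAP) over post-burn-in, thinned draws.

The sampler is Metropolis-within-Gibbs with Gaussian random-walk
proposals, one block per parameter class per iteration:

* theta: all J components proposed and accepted independently (they are
  conditionally independent given the other classes), vectorized;
* beta, gamma: same, over the free (non-anchored) components only;
* d: one joint proposal on the K-2 free components, with d_1 = 0 and
  d_K = -(d_2 + ... + d_{K-1}) determined, so every draw satisfies the
  identification constraints exactly.

When no anchors are fixed the model location/scale is unidentified, so a
stand-alone fit pins gamma_1 = 0; with anchors present the fixed values
resolve identification and gamma_1 is free.

Proposal SDs are tuned during burn-in toward 20-50% acceptance.  All
randomness comes from the config seed; runs are exactly reproducible.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import record_loglik
from .core import MFRMParameters, RatingDataset, log_likelihood
from .errors import ConfigError, ContractError, ModelInputError
from .truth import LinkingLayout

__all__ = ["McmcConfig", "FixedMask", "log_posterior", "estimate_eap"]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)

#: Per-class random-walk proposal SDs (starting values; adapted in burn-in).
DEFAULT_PROPOSAL_SD = {"theta": 0.3, "beta": 0.15, "gamma": 0.15, "d": 0.08}

_ADAPT_WINDOW = 100  # iterations per burn-in adaptation window
_TARGET_ACCEPT = {"theta": 0.4, "beta": 0.4, "gamma": 0.4, "d": 0.3}


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Defaults (5000 iterations, 2000 burn-in, thinning 2, one chain) suit
    the small/mid test settings where the posterior has at most a few
    hundred parameters and is unimodal in practice.
    """

    iterations: int = 5000
    burn_in: int = 2000
    thinning: int = 2
    chains: int = 1
    proposal_sd: dict = field(default_factory=lambda: dict(DEFAULT_PROPOSAL_SD))
    adapt: bool = True
    seed: int | None = None

    def __post_init__(self):
        if not (0 <= self.burn_in < self.iterations):
            raise ConfigError(
                f"burn_in must satisfy 0 <= burn_in < iterations, got "
                f"{self.burn_in} / {self.iterations}"
            )
        if self.chains < 1:
            raise ConfigError(f"chains must be >= 1, got {self.chains}")
        if self.thinning < 1:
            raise ConfigError(f"thinning must be >= 1, got {self.thinning}")
        sd = dict(DEFAULT_PROPOSAL_SD)
        sd.update(self.proposal_sd)
        unknown = set(sd) - set(DEFAULT_PROPOSAL_SD)
        if unknown:
            raise ConfigError(f"unknown proposal_sd classes: {sorted(unknown)}")
        if any(not (v > 0) for v in sd.values()):
            raise ConfigError("proposal SDs must be > 0")
        object.__setattr__(self, "proposal_sd", sd)


@dataclass(frozen=True)
class FixedMask:
    """Anchored gamma/beta entries held fixed during estimation."""

    gamma_indices: tuple[int, ...] = ()
    gamma_values: tuple[float, ...] = ()
    beta_indices: tuple[int, ...] = ()
    beta_values: tuple[float, ...] = ()

    def __post_init__(self):
        for idx, val, what in (
            (self.gamma_indices, self.gamma_values, "gamma"),
            (self.beta_indices, self.beta_values, "beta"),
        ):
            if len(idx) != len(val):
                raise ModelInputError(f"{what} indices/values length mismatch")
            if len(set(idx)) != len(idx):
                raise ModelInputError(f"duplicate fixed {what} indices")
            if any(i < 0 for i in idx):
                raise ModelInputError(f"negative fixed {what} index")
            if not all(math.isfinite(v) for v in val):
                raise ModelInputError(f"non-finite fixed {what} value")

    @classmethod
    def empty(cls) -> "FixedMask":
        return cls()

    @classmethod
    def from_layout(cls, layout: LinkingLayout) -> "FixedMask":
        """Anchor the new-test slots of the common raters/tasks."""
        return cls(
            gamma_indices=layout.new_rater_indices,
            gamma_values=layout.anchor_gamma,
            beta_indices=layout.new_task_indices,
            beta_values=layout.anchor_beta,
        )

    @property
    def is_empty(self) -> bool:
        return not (self.gamma_indices or self.beta_indices)


def _log_phi(x) -> float:
    """Sum of standard normal log-densities."""
    x = np.asarray(x, dtype=float)
    return float(-0.5 * np.sum(x * x) - 0.5 * _LOG_2PI * x.size)


def log_posterior(params: MFRMParameters, data: RatingDataset, mask: FixedMask) -> float:
    """Log-likelihood plus standard normal log-priors over free parameters.

    Free parameters are all theta, the non-anchored beta and gamma entries,
    and the K-2 free d components d_2..d_{K-1} (d_1 and d_K are determined
    by the identification constraints and carry no prior term).  Anchored
    entries must equal their fixed values and contribute no prior.
    """
    for idx, val, arr, what in (
        (mask.gamma_indices, mask.gamma_values, params.gamma, "gamma"),
        (mask.beta_indices, mask.beta_values, params.beta, "beta"),
    ):
        for i, v in zip(idx, val):
            if arr[i] != v:
                raise ContractError(
                    f"masked {what}[{i}] = {arr[i]!r} deviates from fixed value {v!r}"
                )
    free_b = np.setdiff1d(np.arange(params.I), np.asarray(mask.beta_indices, dtype=int))
    free_g = np.setdiff1d(np.arange(params.R), np.asarray(mask.gamma_indices, dtype=int))
    lp = log_likelihood(params, data)
    lp += _log_phi(params.theta)
    lp += _log_phi(params.beta[free_b])
    lp += _log_phi(params.gamma[free_g])
    lp += _log_phi(params.d[1 : params.K - 1])
    return lp


def _d_from_z(z: np.ndarray, K: int) -> np.ndarray:
    """Full d vector from its K-2 free components."""
    d = np.zeros(K)
    if K > 2:
        d[1 : K - 1] = z
        d[K - 1] = -z.sum()
    return d


def estimate_eap(
    data: RatingDataset, mask: FixedMask, config: McmcConfig
) -> tuple[MFRMParameters, dict]:
    """EAP estimates and diagnostics for one rating dataset.

    Returns the posterior-mean parameter set (anchored entries exactly at
    their fixed values; d satisfying d_1 = 0 and sum d_2..d_K = 0 exactly)
    and a diagnostics dict with per-class acceptance rates, split-chain
    R-hat, batch-means Monte Carlo standard errors, and the retained draws.
    """
    J, I, R, K = data.J, data.I, data.R, data.K
    fixed_b = np.asarray(mask.beta_indices, dtype=int)
    fixed_g = np.asarray(mask.gamma_indices, dtype=int)
    if len(fixed_b) and fixed_b.max() >= I:
        raise ModelInputError("fixed beta index outside the data's task range")
    if len(fixed_g) and fixed_g.max() >= R:
        raise ModelInputError("fixed gamma index outside the data's rater range")

    _warn_unobserved(data, fixed_b, fixed_g)

    master = np.random.SeedSequence(config.seed)
    chain_seeds = master.spawn(config.chains)
    chains = [
        _run_chain(data, mask, config, np.random.default_rng(s), jitter=(c > 0))
        for c, s in enumerate(chain_seeds)
    ]

    draws = {
        name: np.concatenate([ch["draws"][name] for ch in chains], axis=0)
        for name in ("theta", "beta", "gamma", "d")
    }
    theta = draws["theta"].mean(axis=0)
    beta = draws["beta"].mean(axis=0)
    gamma = draws["gamma"].mean(axis=0)
    d = draws["d"].mean(axis=0)
    # anchored entries and the d constraints hold in every draw; re-impose
    # exactly to remove float accumulation from the averaging
    if len(fixed_b):
        beta[fixed_b] = np.asarray(mask.beta_values)
    if len(fixed_g):
        gamma[fixed_g] = np.asarray(mask.gamma_values)
    d[0] = 0.0
    if K > 2:
        d[K - 1] = -d[1 : K - 1].sum()
    else:
        d[:] = 0.0
    estimates = MFRMParameters(theta=theta, beta=beta, gamma=gamma, d=d, K=K)

    acceptance = {
        cls: float(np.mean([ch["acceptance"][cls] for ch in chains]))
        for cls in ("theta", "beta", "gamma", "d")
        if not math.isnan(chains[0]["acceptance"][cls])
    }
    per_chain = {
        name: np.stack([ch["draws"][name] for ch in chains]) for name in draws
    }
    rhat = _split_rhat(per_chain)
    mcse = {name: _batch_mcse(draws[name]) for name in draws}
    diagnostics = {
        "acceptance": acceptance,
        "rhat": rhat,
        "rhat_max": max(rhat.values()) if rhat else float("nan"),
        "converged": all(v < 1.1 for v in rhat.values()) if rhat else True,
        "mcse": mcse,
        "draws": draws,
        "n_draws": draws["theta"].shape[0],
        "proposal_sd": {cls: float(np.mean([ch["sd"][cls] for ch in chains]))
                        for cls in ("theta", "beta", "gamma", "d")},
        "seed": config.seed,
    }
    return estimates, diagnostics


def _warn_unobserved(data, fixed_b, fixed_g):
    """Warn when a free parameter has no observations (prior-dominated)."""
    missing = []
    counts = np.bincount(data.examinee, minlength=data.J)
    if np.any(counts == 0):
        missing.append(f"theta{np.flatnonzero(counts == 0).tolist()}")
    counts = np.bincount(data.task, minlength=data.I)
    unobs = np.setdiff1d(np.flatnonzero(counts == 0), fixed_b)
    if unobs.size:
        missing.append(f"beta{unobs.tolist()}")
    counts = np.bincount(data.rater, minlength=data.R)
    unobs = np.setdiff1d(np.flatnonzero(counts == 0), fixed_g)
    if unobs.size:
        missing.append(f"gamma{unobs.tolist()}")
    if missing and data.n_records > 0:
        warnings.warn(
            "parameters with no observations will be prior-dominated: "
            + ", ".join(missing),
            stacklevel=3,
        )


def _run_chain(data, mask, config, rng, jitter=False):
    J, I, R, K = data.J, data.I, data.R, data.K
    jj, ii, rr = data.examinee, data.task, data.rater
    s0 = data.score - 1
    n = data.n_records

    fixed_b = np.asarray(mask.beta_indices, dtype=int)
    fixed_g = np.asarray(mask.gamma_indices, dtype=int)
    free_b = np.setdiff1d(np.arange(I), fixed_b)
    free_g = np.setdiff1d(np.arange(R), fixed_g)
    if mask.is_empty:
        free_g = free_g[free_g != 0]  # stand-alone fit: pin gamma_1 = 0

    theta = np.zeros(J)
    beta = np.zeros(I)
    gamma = np.zeros(R)
    if len(fixed_b):
        beta[fixed_b] = np.asarray(mask.beta_values)
    if len(fixed_g):
        gamma[fixed_g] = np.asarray(mask.gamma_values)
    nz = K - 2
    z = np.zeros(nz)
    if jitter:  # over-dispersed starts for extra chains
        theta += 0.5 * rng.standard_normal(J)
        beta[free_b] += 0.5 * rng.standard_normal(free_b.size)
        gamma[free_g] += 0.5 * rng.standard_normal(free_g.size)
        z += 0.2 * rng.standard_normal(nz)
    d = _d_from_z(z, K)
    cum_d = np.cumsum(d)

    eta = theta[jj] - beta[ii] - gamma[rr]
    ll_rec, _ = record_loglik(eta, s0, cum_d, jj, J)
    zero_group = np.zeros(n, dtype=np.int64)

    sd = dict(config.proposal_sd)
    n_keep = (config.iterations - config.burn_in + config.thinning - 1) // config.thinning
    out = {
        "theta": np.empty((n_keep, J)),
        "beta": np.empty((n_keep, I)),
        "gamma": np.empty((n_keep, R)),
        "d": np.empty((n_keep, K)),
    }
    win = {c: 0 for c in sd}  # acceptances in the current adaptation window
    win_n = {c: 0 for c in sd}
    post = {c: 0 for c in sd}  # post-burn-in acceptances
    post_n = {c: 0 for c in sd}
    kept = 0

    for it in range(config.iterations):
        burn = it < config.burn_in
        # --- theta block -------------------------------------------------
        prop = theta + sd["theta"] * rng.standard_normal(J)
        eta_p = eta + (prop - theta)[jj]
        ll_p, g_p = record_loglik(eta_p, s0, cum_d, jj, J)
        g_c = np.bincount(jj, ll_rec, J)
        logr = (g_p - g_c) + 0.5 * (theta * theta - prop * prop)
        acc = np.log(rng.random(J)) < logr
        if acc.any():
            theta = np.where(acc, prop, theta)
            m = acc[jj]
            eta[m] = eta_p[m]
            ll_rec[m] = ll_p[m]
        _tally(acc.sum(), J, "theta", burn, win, win_n, post, post_n)

        # --- beta block --------------------------------------------------
        if free_b.size:
            prop = beta.copy()
            prop[free_b] += sd["beta"] * rng.standard_normal(free_b.size)
            eta_p = eta - (prop - beta)[ii]
            ll_p, g_p = record_loglik(eta_p, s0, cum_d, ii, I)
            g_c = np.bincount(ii, ll_rec, I)
            logr = (g_p - g_c) + 0.5 * (beta * beta - prop * prop)
            acc = np.zeros(I, dtype=bool)
            acc[free_b] = np.log(rng.random(free_b.size)) < logr[free_b]
            if acc.any():
                beta = np.where(acc, prop, beta)
                m = acc[ii]
                eta[m] = eta_p[m]
                ll_rec[m] = ll_p[m]
            _tally(acc.sum(), free_b.size, "beta", burn, win, win_n, post, post_n)

        # --- gamma block -------------------------------------------------
        if free_g.size:
            prop = gamma.copy()
            prop[free_g] += sd["gamma"] * rng.standard_normal(free_g.size)
            eta_p = eta - (prop - gamma)[rr]
            ll_p, g_p = record_loglik(eta_p, s0, cum_d, rr, R)
            g_c = np.bincount(rr, ll_rec, R)
            logr = (g_p - g_c) + 0.5 * (gamma * gamma - prop * prop)
            acc = np.zeros(R, dtype=bool)
            acc[free_g] = np.log(rng.random(free_g.size)) < logr[free_g]
            if acc.any():
                gamma = np.where(acc, prop, gamma)
                m = acc[rr]
                eta[m] = eta_p[m]
                ll_rec[m] = ll_p[m]
            _tally(acc.sum(), free_g.size, "gamma", burn, win, win_n, post, post_n)

        # --- d block (joint over the K-2 free components) ----------------
        if nz > 0:
            z_p = z + sd["d"] * rng.standard_normal(nz)
            d_p = _d_from_z(z_p, K)
            cum_p = np.cumsum(d_p)
            ll_p, g_p = record_loglik(eta, s0, cum_p, zero_group, 1)
            logr = (g_p[0] - ll_rec.sum()) + 0.5 * (z @ z - z_p @ z_p)
            if np.log(rng.random()) < logr:
                z, d, cum_d = z_p, d_p, cum_p
                ll_rec = ll_p
                _tally(1, 1, "d", burn, win, win_n, post, post_n)
            else:
                _tally(0, 1, "d", burn, win, win_n, post, post_n)

        # --- burn-in adaptation ------------------------------------------
        if config.adapt and burn and (it + 1) % _ADAPT_WINDOW == 0:
            for cls in sd:
                if win_n[cls]:
                    rate = win[cls] / win_n[cls]
                    sd[cls] = float(
                        np.clip(sd[cls] * math.exp(rate - _TARGET_ACCEPT[cls]), 1e-3, 10.0)
                    )
                win[cls] = 0
                win_n[cls] = 0

        # --- retain ------------------------------------------------------
        if not burn and (it - config.burn_in) % config.thinning == 0:
            out["theta"][kept] = theta
            out["beta"][kept] = beta
            out["gamma"][kept] = gamma
            out["d"][kept] = d
            kept += 1

    for name in out:
        out[name] = out[name][:kept]
    acceptance = {
        cls: (post[cls] / post_n[cls]) if post_n[cls] else float("nan") for cls in sd
    }
    return {"draws": out, "acceptance": acceptance, "sd": sd}


def _tally(n_acc, n_prop, cls, burn, win, win_n, post, post_n):
    if burn:
        win[cls] += int(n_acc)
        win_n[cls] += int(n_prop)
    else:
        post[cls] += int(n_acc)
        post_n[cls] += int(n_prop)


def _split_rhat(per_chain: dict) -> dict:
    """Max split-chain R-hat per parameter class.

    Each chain is split in half, giving 2 * chains segments; R-hat is the
    usual between/within variance ratio per scalar parameter; the maximum
    over a class's parameters is reported.  Parameters with zero variance
    (anchored entries, pinned gamma_1, d_1) are skipped.
    """
    result = {}
    for name, draws in per_chain.items():  # draws: (chains, n, P)
        c, nkeep, p = draws.shape
        half = nkeep // 2
        if half < 2:
            continue
        segs = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
        seg_mean = segs.mean(axis=1)  # (2c, P)
        seg_var = segs.var(axis=1, ddof=1)  # (2c, P)
        w = seg_var.mean(axis=0)
        b = half * seg_mean.var(axis=0, ddof=1)
        live = w > 0
        if not live.any():
            continue
        var_plus = (half - 1) / half * w[live] + b[live] / half
        result[name] = float(np.max(np.sqrt(var_plus / w[live])))
    return result


def _batch_mcse(draws: np.ndarray, n_batches: int = 25) -> np.ndarray:
    """Batch-means Monte Carlo standard error of the posterior mean, per column."""
    n = draws.shape[0]
    b = max(2, min(n_batches, n // 2))
    size = n // b
    if size < 1:
        return np.full(draws.shape[1], np.nan)
    trimmed = draws[: b * size]
    means = trimmed.reshape(b, size, -1).mean(axis=1)
    return means.std(axis=0, ddof=1) / math.sqrt(b)
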