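"""Numba kernels for the adjacent-categories likelihood.

The sampler spends essentially all of its time evaluating per-record
log-probabilities log P(x_ijr = k | eta, d), so this single pass is JIT
compiled.  Everything else in the package is plain numpy.
"""
import numba
import numpy as np

__all__ = ["record_loglik", "total_loglik"]


@numba.njit(cache=True)
def record_loglik(eta, s0, cum_d, group, n_groups):
    """Per-record log-likelihood and per-group sums in one pass.

    Parameters
    ----------
    eta : float64[n]
        Linear predictor theta_j - beta_i - gamma_r per record.
    s0 : int64[n]
        Zero-based observed category per record.
    cum_d : float64[K]
        Cumulative sums of the category parameters d_1..d_K.
    group : int64[n]
        Grouping index per record (examinee, task, or rater index).
    n_groups : int
        Number of groups.

    Returns
    -------
    (float64[n], float64[n_groups])
        Per-record log-likelihood terms and their per-group sums.

    Notes
    -----
    The log-probability of category k (1-based) is

        k*eta - D_k - logsumexp_l (l*eta - D_l),   D_l = sum_{m<=l} d_m,

    evaluated with max-subtraction so that |eta| up to ~8 (drifted or
    extreme parameters) stays finite.
    """
    n = eta.shape[0]
    K = cum_d.shape[0]
    ll = np.empty(n)
    gsum = np.zeros(n_groups)
    for t in range(n):
        e = eta[t]
        m = -np.inf
        for l in range(K):
            psi = (l + 1) * e - cum_d[l]
            if psi > m:
                m = psi
        acc = 0.0
        for l in range(K):
            acc += np.exp((l + 1) * e - cum_d[l] - m)
        v = (s0[t] + 1) * e - cum_d[s0[t]] - m - np.log(acc)
        ll[t] = v
        gsum[group[t]] += v
    return ll, gsum


@numba.njit(cache=True)
def total_loglik(eta, s0, cum_d):
    """Sum of per-record log-likelihood terms (single group)."""
    n = eta.shape[0]
    K = cum_d.shape[0]
    total = 0.0
    for t in range(n):
        e = eta[t]
        m = -np.inf
        for l in range(K):
            psi = (l + 1) * e - cum_d[l]
            if psi > m:
                m = psi
        acc = 0.0
        for l in range(K):
            acc += np.exp((l + 1) * e - cum_d[l] - m)
        total += (s0[t] + 1) * e - cum_d[s0[t]] - m - np.log(acc)
    return total
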