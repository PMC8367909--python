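import numpy as np
import pytest

import facetlink as fl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A hand-sized parameter set with valid d constraints (K=5)."""
    return fl.MFRMParameters(
        theta=[0.3, -0.8, 1.1],
        beta=[0.2, -0.4],
        gamma=[0.0, 0.5],
        d=[0.0, -0.9, -0.1, 0.3, 0.7],
        K=5,
    )


@pytest.fixture
def tiny_mcmc():
    """Short sampler config for tests that only need a working chain."""
    return fl.McmcConfig(iterations=1200, burn_in=500, thinning=2, seed=7)


def naive_category_probs(eta, d):
    """Independent oracle: direct evaluation of the adjacent-categories form."""
    import math

    K = len(d)
    cum = [sum(eta - d[m] for m in range(k + 1)) for k in range(K)]
    ex = [math.exp(c) for c in cum]
    total = sum(ex)
    return [e / total for e in ex]


def naive_log_likelihood(params, data):
    """Independent oracle: per-record loop, no shared code with the package."""
    import math

    total = 0.0
    for j, i, r, x in zip(data.examinee, data.task, data.rater, data.score):
        eta = params.theta[j] - params.beta[i] - params.gamma[r]
        probs = naive_category_probs(eta, list(params.d))
        total += math.log(probs[x - 1])
    return total
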