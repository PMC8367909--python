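"""Anchored EAP-by-MCMC estimation: posterior, sampler invariants, recovery."""
import math

import numpy as np
import pytest

import facetlink as fl
from facetlink.errors import ContractError

from conftest import naive_log_likelihood


def naive_log_posterior(params, data, mask):
    """Independent oracle: naive likelihood loop + explicit normal priors."""
    from scipy.stats import norm

    free_b = [i for i in range(params.I) if i not in set(mask.beta_indices)]
    free_g = [r for r in range(params.R) if r not in set(mask.gamma_indices)]
    lp = naive_log_likelihood(params, data)
    lp += norm.logpdf(params.theta).sum()
    lp += norm.logpdf(params.beta[free_b]).sum()
    lp += norm.logpdf(params.gamma[free_g]).sum()
    lp += norm.logpdf(params.d[1 : params.K - 1]).sum()
    return lp


class TestLogPosterior:
    def test_closed_form_at_origin_with_empty_data(self):
        params = fl.MFRMParameters(
            theta=np.zeros(4), beta=np.zeros(3), gamma=np.zeros(2), d=np.zeros(5), K=5
        )
        empty = fl.RatingDataset(examinee=[], task=[], rater=[], score=[], J=4, I=3, R=2, K=5)
        n_free = 4 + 3 + 2 + (5 - 2)
        expected = n_free * (-0.5 * math.log(2 * math.pi))
        assert fl.log_posterior(params, empty, fl.FixedMask.empty()) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_naive_oracle(self, small_params, rng):
        data = fl.RatingDataset(
            examinee=[0, 0, 1, 1, 2, 2, 0, 1, 2, 2],
            task=[0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
            rater=[0, 0, 1, 1, 0, 0, 1, 0, 1, 1],
            score=[1, 3, 2, 5, 4, 2, 3, 1, 5, 2],
            J=3, I=2, R=2, K=5,
        )
        mask = fl.FixedMask(
            gamma_indices=(1,), gamma_values=(float(small_params.gamma[1]),),
            beta_indices=(0,), beta_values=(float(small_params.beta[0]),),
        )
        assert fl.log_posterior(small_params, data, mask) == pytest.approx(
            naive_log_posterior(small_params, data, mask), abs=1e-10
        )

    def test_additivity_in_records(self, small_params):
        mask = fl.FixedMask.empty()
        d1 = fl.RatingDataset(examinee=[0], task=[0], rater=[0], score=[2], J=3, I=2, R=2, K=5)
        d2 = fl.RatingDataset(
            examinee=[0, 1], task=[0, 1], rater=[0, 1], score=[2, 4], J=3, I=2, R=2, K=5
        )
        extra = fl.RatingDataset(examinee=[1], task=[1], rater=[1], score=[4], J=3, I=2, R=2, K=5)
        delta = fl.log_posterior(small_params, d2, mask) - fl.log_posterior(small_params, d1, mask)
        assert delta == pytest.approx(fl.log_likelihood(small_params, extra), abs=1e-10)

    def test_masked_entry_deviation_rejected(self, small_params):
        empty = fl.RatingDataset(examinee=[], task=[], rater=[], score=[], J=3, I=2, R=2, K=5)
        mask = fl.FixedMask(gamma_indices=(0,), gamma_values=(99.0,))
        with pytest.raises(ContractError):
            fl.log_posterior(small_params, empty, mask)


class TestSamplerInvariants:
    def test_d_constraints_hold_in_every_retained_draw(self, rng, tiny_mcmc):
        truth = fl.generate_parameters(15, 3, 3, 5, fl.DistributionSpec.standard(), rng)
        data = fl.sample_dataset(truth, rng=rng)
        _, diag = fl.estimate_eap(data, fl.FixedMask.empty(), tiny_mcmc)
        d = diag["draws"]["d"]
        assert np.all(d[:, 0] == 0.0)
        assert np.abs(d[:, 1:].sum(axis=1)).max() < 1e-12

    def test_gamma1_pinned_only_without_anchors(self, rng, tiny_mcmc):
        truth = fl.generate_parameters(15, 3, 3, 5, fl.DistributionSpec.standard(), rng)
        data = fl.sample_dataset(truth, rng=rng)
        _, diag = fl.estimate_eap(data, fl.FixedMask.empty(), tiny_mcmc)
        assert np.all(diag["draws"]["gamma"][:, 0] == 0.0)
        mask = fl.FixedMask(gamma_indices=(2,), gamma_values=(float(truth.gamma[2]),))
        est, diag = fl.estimate_eap(data, mask, tiny_mcmc)
        assert diag["draws"]["gamma"][:, 0].std() > 0  # gamma_1 free when anchored
        assert np.all(diag["draws"]["gamma"][:, 2] == truth.gamma[2])
        assert est.gamma[2] == truth.gamma[2]

    def test_seeded_estimation_reproducible(self, rng, tiny_mcmc):
        truth = fl.generate_parameters(10, 3, 3, 5, fl.DistributionSpec.standard(), rng)
        data = fl.sample_dataset(truth, rng=rng)
        a, _ = fl.estimate_eap(data, fl.FixedMask.empty(), tiny_mcmc)
        b, _ = fl.estimate_eap(data, fl.FixedMask.empty(), tiny_mcmc)
        assert a == b

    def test_empty_data_posterior_equals_prior(self):
        """With no records the posterior is the N(0,1) prior: every free
        EAP estimate should sit within 3 Monte-Carlo SEs of 0."""
        empty = fl.RatingDataset(examinee=[], task=[], rater=[], score=[], J=3, I=2, R=2, K=5)
        config = fl.McmcConfig(iterations=6000, burn_in=1000, thinning=2, seed=42)
        est, diag = fl.estimate_eap(empty, fl.FixedMask.empty(), config)
        for name, values in (("theta", est.theta), ("beta", est.beta)):
            mcse = diag["mcse"][name]
            assert np.all(np.abs(values) < 3 * mcse + 1e-9), name

    def test_single_theta_matches_quadrature(self):
        """1 examinee, 1 task, 1 rater, K=2, beta/gamma anchored at 0: the
        posterior is 1-D and the EAP has a quadrature oracle."""
        from scipy.integrate import quad
        from scipy.stats import norm

        data = fl.RatingDataset(examinee=[0], task=[0], rater=[0], score=[2], J=1, I=1, R=1, K=2)
        mask = fl.FixedMask(
            gamma_indices=(0,), gamma_values=(0.0,), beta_indices=(0,), beta_values=(0.0,)
        )

        def like(t):  # P(x=2 | theta=t) with d=(0,0): logistic in t
            return 1.0 / (1.0 + np.exp(-t))

        num = quad(lambda t: t * norm.pdf(t) * like(t), -10, 10)[0]
        den = quad(lambda t: norm.pdf(t) * like(t), -10, 10)[0]
        config = fl.McmcConfig(iterations=8000, burn_in=2000, thinning=2, seed=5)
        est, _ = fl.estimate_eap(data, mask, config)
        assert est.theta[0] == pytest.approx(num / den, abs=0.05)

    def test_unobserved_parameter_warns(self, rng, tiny_mcmc):
        data = fl.RatingDataset(
            examinee=[0, 0], task=[0, 0], rater=[0, 1], score=[2, 3], J=2, I=1, R=2, K=5
        )
        with pytest.warns(UserWarning, match="prior-dominated"):
            fl.estimate_eap(data, fl.FixedMask.empty(), tiny_mcmc)


class TestRecovery:
    def test_recovery_beats_prior_mean_estimator(self, rng):
        """Fully crossed data carries real information: EAP theta must beat
        the all-zeros estimator (the prior mean) on RMSE."""
        truth = fl.generate_parameters(30, 5, 5, 5, fl.DistributionSpec.standard(), rng)
        data = fl.sample_dataset(truth, rng=rng)
        config = fl.McmcConfig(iterations=2500, burn_in=1000, thinning=2, seed=17)
        est, _ = fl.estimate_eap(data, fl.FixedMask.empty(), config)
        rmse_est = np.sqrt(np.mean((est.theta - truth.theta) ** 2))
        rmse_zero = np.sqrt(np.mean(truth.theta**2))
        assert rmse_est < rmse_zero

    def test_rmse_decreases_with_data_volume(self):
        """With anchors at truth, every added examinee adds ratings on each
        task and rater, so the task/rater error shrinks as J grows (the
        per-examinee theta error stays flat at fixed I, R, so the facet
        parameters are where data volume shows)."""
        config = fl.McmcConfig(iterations=2500, burn_in=1000, thinning=2, seed=3)
        means = []
        for J in (25, 50, 100):
            sq = []
            for seed in (101, 202, 303):
                rng = np.random.default_rng(seed)
                truth = fl.generate_parameters(J, 4, 4, 5, fl.DistributionSpec.standard(), rng)
                mask = fl.FixedMask(
                    gamma_indices=(0,), gamma_values=(float(truth.gamma[0]),),
                    beta_indices=(0,), beta_values=(float(truth.beta[0]),),
                )
                data = fl.sample_dataset(truth, rng=rng)
                est, _ = fl.estimate_eap(data, mask, config)
                dev = np.concatenate(
                    [(est.beta - truth.beta)[1:], (est.gamma - truth.gamma)[1:]]
                )
                sq.extend(dev**2)
            means.append(np.sqrt(np.mean(sq)))
        assert means[2] < means[0]  # clear end-to-end decrease from J=25 to J=100
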