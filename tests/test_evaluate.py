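"""Linking pipeline: error indices, threshold, replication, grid."""
import numpy as np
import pytest

import facetlink as fl
from facetlink.errors import ConfigError, DesignError, ScopeError
from facetlink.seeds import SeedPlan, Stage


def _params(theta, beta, gamma, d):
    return fl.MFRMParameters(theta=theta, beta=beta, gamma=gamma, d=d, K=len(d))


TRUTH = _params([0.4, -0.2, 0.9, -1.1], [0.1, -0.3, 0.6], [0.0, 0.5], [0.0, -0.6, -0.1, 0.2, 0.5])


class TestComputeError:
    def test_perfect_estimate_gives_zero(self):
        for index in ("rmse", "mae", "abs_mean_bias"):
            for scope in ("all_free", "ability", "task", "rater", "category"):
                assert fl.compute_error(TRUTH, TRUTH, index, scope) == 0.0

    @pytest.mark.parametrize("scope,field", [("ability", "theta"), ("task", "beta"), ("rater", "gamma")])
    def test_uniform_shift_recovered_by_every_index(self, scope, field):
        est = TRUTH.replace(**{field: getattr(TRUTH, field) + 0.1})
        for index in ("rmse", "mae", "abs_mean_bias"):
            assert fl.compute_error(est, TRUTH, index, scope) == pytest.approx(0.1)

    def test_alternating_deviations_cancel_bias_not_rmse(self):
        est = TRUTH.replace(theta=TRUTH.theta + [0.1, -0.1, 0.1, -0.1])
        assert fl.compute_error(est, TRUTH, "abs_mean_bias", "ability") == pytest.approx(0.0, abs=1e-15)
        assert fl.compute_error(est, TRUTH, "rmse", "ability") == pytest.approx(0.1)
        assert fl.compute_error(est, TRUTH, "mae", "ability") == pytest.approx(0.1)

    def test_category_scope_uses_estimable_d(self):
        est = TRUTH.replace(d=TRUTH.d + [0.0, 0.1, -0.1, 0.1, -0.1])
        assert fl.compute_error(est, TRUTH, "rmse", "category") == pytest.approx(0.1)
        assert fl.compute_error(est, TRUTH, "abs_mean_bias", "category") == pytest.approx(0.0, abs=1e-15)

    def test_anchored_entries_excluded_with_mask(self):
        est = TRUTH.replace(beta=TRUTH.beta + [0.0, 0.2, 0.2])
        mask = fl.FixedMask(beta_indices=(1,), beta_values=(float(TRUTH.beta[1]),))
        # without mask the (wrongly moved) anchored slot dilutes nothing here,
        # with mask only the free slots count
        assert fl.compute_error(est, TRUTH, "rmse", "task", mask=mask) == pytest.approx(
            np.sqrt((0.0**2 + 0.2**2) / 2)
        )
        assert fl.compute_error(est, TRUTH, "rmse", "task") == pytest.approx(
            np.sqrt((0.0**2 + 0.2**2 + 0.2**2) / 3)
        )

    def test_empty_scope_rejected(self):
        mask = fl.FixedMask(
            beta_indices=(0, 1, 2),
            beta_values=tuple(map(float, TRUTH.beta)),
        )
        with pytest.raises(ScopeError):
            fl.compute_error(TRUTH, TRUTH, "rmse", "task", mask=mask)


class TestThreshold:
    def test_equal_errors_give_delta_equal_error(self):
        assert fl.threshold_from_errors([0.2, 0.2, 0.2]) == pytest.approx(0.2)

    def test_hand_computed_sample_sd(self):
        # mean 0.2, sample SD 0.1 -> delta = 0.4
        assert fl.threshold_from_errors([0.1, 0.2, 0.3]) == pytest.approx(0.4)

    def test_needs_at_least_two(self):
        with pytest.raises(ConfigError):
            fl.threshold_from_errors([0.1])


TINY = dict(J=12, I=3, R=3, K=3, replications=2, c_r_grid=(1,), c_i_grid=(1,),
            mcmc=fl.McmcConfig(iterations=600, burn_in=250, thinning=2))


class TestRunReplication:
    def test_deterministic_given_seed(self):
        config = fl.ExperimentConfig(new_spec=fl.DistributionSpec.scenario(1), **TINY)
        a = fl.run_replication(config, 1, 1, 42)
        b = fl.run_replication(config, 1, 1, 42)
        assert a == b
        assert a != fl.run_replication(config, 1, 1, 43)

    def test_reports_all_requested_indices(self):
        config = fl.ExperimentConfig(
            new_spec=fl.DistributionSpec.scenario(1),
            extra_errors=(("mae", "ability"), ("abs_mean_bias", "ability")),
            **TINY,
        )
        out = fl.run_replication(config, 1, 1, 0)
        assert set(out) == {"rmse:all_free", "mae:ability", "abs_mean_bias:ability"}
        assert all(np.isfinite(v) and v >= 0 for v in out.values())

    def test_anchoring_beats_unanchored_shifted_prior(self):
        """Anchors at truth pull the scale to the right place: the anchored
        fit must beat a stand-alone fit of the same shifted data."""
        rng = np.random.default_rng(8)
        base = fl.generate_parameters(40, 4, 4, 5, fl.DistributionSpec.standard(), rng)
        new = fl.generate_parameters(40, 4, 4, 5, fl.DistributionSpec.scenario(1), rng)
        new, layout = fl.embed_common(base, new, 2, 2, rng)
        data = fl.sample_dataset(new, rng=rng)
        config = fl.McmcConfig(iterations=2000, burn_in=800, thinning=2, seed=4)
        mask = fl.FixedMask.from_layout(layout)
        est_anchored, _ = fl.estimate_eap(data, mask, config)
        est_free, _ = fl.estimate_eap(data, fl.FixedMask.empty(), config)
        err_anchored = fl.compute_error(est_anchored, new, "rmse", "ability")
        err_free = fl.compute_error(est_free, new, "rmse", "ability")
        assert err_anchored < err_free


class TestGrid:
    def test_cell_result_pass_flag_invariant(self):
        cell = fl.CellResult.from_errors(1, 1, (0.10, 0.12), delta=0.15)
        assert cell.passed and cell.mean_error == pytest.approx(0.11)
        with pytest.raises(ConfigError):
            fl.CellResult(C_R=1, C_I=1, errors=(0.2,), mean_error=0.2,
                          delta=0.1, passed=True, n_reps=1)

    def test_single_cell_grid_composes_replication_and_threshold(self):
        config = fl.ExperimentConfig(
            new_spec=fl.DistributionSpec.scenario(1), master_seed=5, **TINY,
        )
        report = fl.run_grid(config)
        assert len(report.cells) == 1
        cell = report.cell(1, 1)
        plan = SeedPlan(5)
        expected = [
            fl.run_replication(config, 1, 1, plan.sequence(1, 1, rep, Stage.EVALUATION))["rmse:all_free"]
            for rep in range(2)
        ]
        assert cell.errors == pytest.approx(expected)
        assert cell.delta == pytest.approx(fl.compute_threshold(config, 1, 1))
        assert cell.passed == (cell.mean_error < cell.delta)

    def test_report_reproducible_from_master_seed(self):
        config = fl.ExperimentConfig(
            new_spec=fl.DistributionSpec.scenario(2), master_seed=9, **TINY,
        )
        assert fl.run_grid(config) == fl.run_grid(config)

    def test_format_table_marks_threshold_and_pass(self):
        cell = fl.CellResult.from_errors(1, 2, (0.10, 0.12), delta=0.15)
        report = fl.GridReport(cells=(cell,), index="rmse", scope="all_free",
                               J=10, I=3, R=3, K=5, replications=2, master_seed=0)
        text = report.format_table()
        assert "C_I=2" in text and "(.1500)" in text and "*.1100" in text


class TestConfigValidation:
    GRID = dict(c_r_grid=(1,), c_i_grid=(1,))

    def test_replication_floor(self):
        with pytest.raises(ConfigError, match="replications"):
            fl.ExperimentConfig(J=5, I=2, R=2, replications=1, **self.GRID)

    def test_grid_bounds(self):
        with pytest.raises(ConfigError):
            fl.ExperimentConfig(J=5, I=2, R=2, c_r_grid=(3,), c_i_grid=(1,))

    def test_rater_set_size_bounds(self):
        with pytest.raises(DesignError):
            fl.ExperimentConfig(J=5, I=2, R=2, n_r=5, **self.GRID)

    def test_unknown_index_rejected(self):
        with pytest.raises(ConfigError):
            fl.ExperimentConfig(J=5, I=2, R=2, error_index="mse", **self.GRID)
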