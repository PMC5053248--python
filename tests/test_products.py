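import numpy as np
import pandas as pd
import pytest

from odast import (
    CombinedFlowDraws,
    ConfigError,
    McmcConfig,
    ModelAssemblyError,
    ODMarginalDraws,
    age_profile_summary,
    combine_with_od_marginals,
    female_share_summary,
    gof_differences,
    posterior_predictive_proportions,
    run_chain,
)
from odast.data import ReportedFlowData
from odast.dims import SENDING
from odast.products import PredictiveProportions


@pytest.fixture(scope="module")
def small_fit(tiny_study_module):
    cfg, truth, data, od = tiny_study_module
    draws = run_chain(data, McmcConfig(n_iterations=100, burn_in=60, thinning=2, seed=8))
    return truth, data, od, draws


@pytest.fixture(scope="module")
def tiny_study_module():
    from odast import ScenarioConfig, StudyDimensions, simulate_scenario

    dims = StudyDimensions(countries=("AA", "BB"), n_ages=3, years=(2007,))
    cfg = ScenarioConfig(seed=5, missing_fraction_send=0.3, missing_fraction_recv=0.3,
                         sexonly_fraction=0.3, base_flow=40.0)
    truth, data, od = simulate_scenario(dims, cfg, n_od_draws=20, od_dispersion=0.02)
    return cfg, truth, data, od


class TestCombine:
    def test_uniform_composition_spreads_marginal_evenly(self, tiny_dims):
        from odast.mcmc import PosteriorDraws

        F, T, A = tiny_dims.n_flows, 1, tiny_dims.n_ages
        n_cells = A * 2
        pi = np.full((4, F, T, A, 2), 1.0 / n_cells)
        draws = PosteriorDraws(
            dims=tiny_dims, pi=pi, age_effect=np.zeros((4, A)),
            sex_effect=np.zeros((4, 2)), scalars={}, report_mask=np.zeros((2, F, T), bool),
            config=McmcConfig(), seed=0,
        )
        od = ODMarginalDraws(dims=tiny_dims, values=np.full((4, F, T), 60.0))
        combined = combine_with_od_marginals(draws, od)
        np.testing.assert_allclose(combined.values, 60.0 / n_cells)

    def test_conservation_per_draw(self, small_fit):
        _, _, od, draws = small_fit
        combined = combine_with_od_marginals(draws, od)
        sums = combined.values.sum(axis=(3, 4))
        np.testing.assert_allclose(sums, od.values, rtol=1e-10)

    def test_matches_per_draw_multiplication_oracle(self, small_fit):
        _, _, od, draws = small_fit
        combined = combine_with_od_marginals(draws, od)
        for i in (0, draws.n_draws - 1):
            for f in (0, 3):
                np.testing.assert_allclose(
                    combined.values[i, f, 0],
                    draws.pi[i, f, 0] * od.values[i, f, 0],
                    rtol=1e-12,
                )

    def test_mismatched_draw_counts_rejected(self, small_fit):
        _, _, od, draws = small_fit
        bad = ODMarginalDraws(dims=od.dims, values=od.values[:3])
        with pytest.raises(ModelAssemblyError):
            combine_with_od_marginals(draws, bad)


class TestPosteriorPredictive:
    def test_blocks_sum_to_one_where_defined(self, small_fit):
        _, data, _, draws = small_fit
        pred = posterior_predictive_proportions(draws, data, np.random.default_rng(1))
        sums = np.nansum(pred.agesex, axis=(4, 5))
        defined = ~np.isnan(pred.agesex).all(axis=(4, 5))
        np.testing.assert_allclose(sums[defined], 1.0, atol=1e-12)

    def test_noiseless_predictive_mean_recovers_composition(self, tiny_dims):
        # one draw replicated, enormous precision, zero interaction: the
        # predictive mean proportion converges to the draw's composition
        from odast.mcmc import PosteriorDraws

        F, A = tiny_dims.n_flows, tiny_dims.n_ages
        rng = np.random.default_rng(2)
        pi_block = rng.dirichlet(np.ones(A * 2)).reshape(A, 2)
        log_m = np.log(np.broadcast_to(pi_block * 2e5, (F, 1, A, 2)))
        n = 400
        data = ReportedFlowData.empty(tiny_dims)
        f = tiny_dims.flow_index("AA", "BB")
        data.mask_agesex[SENDING, f, 0] = True
        draws = PosteriorDraws(
            dims=tiny_dims,
            pi=np.broadcast_to(np.exp(log_m) / 2e5, (n, F, 1, A, 2)).copy(),
            age_effect=np.zeros((n, A)), sex_effect=np.zeros((n, 2)),
            scalars={k: np.full(n, 1e8) for k in (
                "tau_send", "tau_recv", "tau_send_sexonly", "tau_recv_sexonly")},
            report_mask=data.report_mask.copy(), config=McmcConfig(), seed=0,
            log_m=np.broadcast_to(log_m, (n, F, 1, A, 2)).copy(),
            report_effect=np.zeros((n, 2, F, 1)),
        )
        pred = posterior_predictive_proportions(draws, data, np.random.default_rng(3))
        mean = pred.mean_agesex()[SENDING, f, 0]
        assert np.max(np.abs(mean - pi_block)) < 0.005

    def test_missing_monitored_quantities_rejected(self, small_fit):
        _, data, _, draws = small_fit
        import dataclasses

        stripped = dataclasses.replace(draws, log_m=None)
        with pytest.raises(ConfigError):
            posterior_predictive_proportions(stripped, data)


class TestGof:
    def _self_consistent_predictive(self, data):
        """Predictive proportions equal to the observed ones (single draw)."""
        d = data.dims
        F, T, A = d.n_flows, d.n_years, d.n_ages
        ag = np.full((1, 2, F, T, A, 2), np.nan)
        sx = np.full((1, 2, F, T, 2), np.nan)
        for k in range(2):
            for f, t in zip(*np.where(data.mask_agesex[k])):
                z = data.z_agesex[k, f, t]
                if z.sum():
                    ag[0, k, f, t] = z / z.sum()
            for f, t in zip(*np.where(data.mask_sexonly[k])):
                z = data.z_sexonly[k, f, t]
                if z.sum():
                    sx[0, k, f, t] = z / z.sum()
        return PredictiveProportions(agesex=ag, sexonly=sx)

    def test_self_consistent_input_gives_zero_differences(self, small_fit):
        _, data, _, _ = small_fit
        report = gof_differences(data, self._self_consistent_predictive(data))
        assert report.n_cells > 0
        assert (report.table["difference"] == 0.0).all()
        assert report.rms == 0.0

    def test_tenfold_discrepancy_is_difference_of_one(self, small_fit):
        _, data, _, _ = small_fit
        pred = self._self_consistent_predictive(data)
        # scale every predictive mean down tenfold: difference becomes 1
        pred = PredictiveProportions(agesex=pred.agesex / 10.0, sexonly=pred.sexonly / 10.0)
        report = gof_differences(data, pred)
        np.testing.assert_allclose(report.table["difference"], 1.0, rtol=1e-12)

    def test_rms_invariant_to_cell_ordering(self, small_fit):
        _, data, _, draws = small_fit
        pred = posterior_predictive_proportions(draws, data, np.random.default_rng(4))
        report = gof_differences(data, pred)
        shuffled = report.table.sample(frac=1.0, random_state=0)
        assert np.sqrt((shuffled["difference"] ** 2).mean()) == pytest.approx(report.rms)


class TestFemaleShare:
    def _constant_combined(self, dims, values):
        return CombinedFlowDraws(dims=dims, values=values)

    def test_zero_female_reports_give_zero_percent(self, tiny_dims):
        data = ReportedFlowData.empty(tiny_dims)
        f = tiny_dims.flow_index("AA", "BB")
        data.mask_agesex[SENDING, f, 0] = True
        data.z_agesex[SENDING, f, 0, :, 1] = 5  # males only
        table = female_share_summary(data)
        row = table[(table["country"] == "AA") & (table["direction"] == "emigration")]
        assert row["share"].iloc[0] == 0.0

    def test_equal_sexes_give_fifty_percent(self, tiny_dims, rng):
        A = tiny_dims.n_ages
        vals = rng.gamma(2.0, 10.0, size=(5, tiny_dims.n_flows, 1, A, 1))
        vals = np.concatenate([vals, vals], axis=4)  # females == males
        table = female_share_summary(self._constant_combined(tiny_dims, vals))
        np.testing.assert_allclose(table["mean"], 50.0, atol=1e-9)

    def test_matches_ratio_then_average_oracle(self, small_fit):
        truth, _, od, draws = small_fit
        combined = combine_with_od_marginals(draws, od)
        dims = combined.dims
        table = female_share_summary(combined)
        o_idx, _ = dims.flow_arrays()
        u = dims.unit_index("AA")
        sel = o_idx == u
        shares = np.array([
            100.0 * combined.values[i][sel][:, :, :, 0].sum()
            / combined.values[i][sel].sum()
            for i in range(combined.n_draws)
        ])
        row = table[(table["country"] == "AA") & (table["direction"] == "emigration")]
        assert row["mean"].iloc[0] == pytest.approx(shares.mean(), rel=1e-10)

    def test_bounds_and_coverage_of_countries(self, small_fit):
        _, _, od, draws = small_fit
        combined = combine_with_od_marginals(draws, od)
        table = female_share_summary(combined, periods=[(2007,)])
        assert ((table["mean"] >= 0) & (table["mean"] <= 100)).all()
        for direction in ("emigration", "immigration"):
            sub = table[table["direction"] == direction]
            assert sorted(sub["country"]) == sorted(combined.dims.units)

    def test_empty_period_rejected(self, small_fit):
        _, _, od, draws = small_fit
        combined = combine_with_od_marginals(draws, od)
        with pytest.raises(ConfigError):
            female_share_summary(combined, periods=[()])


class TestAgeProfiles:
    def test_constant_draws_collapse_quantiles(self, tiny_dims):
        vals = np.full((9, tiny_dims.n_flows, 1, tiny_dims.n_ages, 2), 7.5)
        table = age_profile_summary(CombinedFlowDraws(dims=tiny_dims, values=vals))
        for col in ("q0.1", "q0.5", "q0.9"):
            np.testing.assert_allclose(table[col], 7.5)

    def test_median_of_1_to_99_is_50(self, tiny_dims):
        vals = np.ones((99, tiny_dims.n_flows, 1, tiny_dims.n_ages, 2))
        vals *= np.arange(1, 100)[:, None, None, None, None]
        table = age_profile_summary(
            CombinedFlowDraws(dims=tiny_dims, values=vals), quantiles=(0.5,)
        )
        np.testing.assert_allclose(table["q0.5"], 50.0)

    def test_matches_sort_based_oracle(self, small_fit, rng):
        _, _, od, draws = small_fit
        combined = combine_with_od_marginals(draws, od)
        table = age_profile_summary(combined, quantiles=(0.1, 0.5, 0.9))
        dims = combined.dims
        f = dims.flow_index("AA", "BB")
        sub = table[(table["origin"] == "AA") & (table["destination"] == "BB")
                    & (table["sex"] == "F") & (table["age_group"] == 2)]
        cell = np.sort(combined.values[:, f, 0, 1, 0])
        for q, col in ((0.1, "q0.1"), (0.5, "q0.5"), (0.9, "q0.9")):
            assert sub[col].iloc[0] == pytest.approx(np.quantile(cell, q), rel=1e-10)

    def test_invalid_quantile_rejected(self, tiny_dims):
        vals = np.ones((3, tiny_dims.n_flows, 1, tiny_dims.n_ages, 2))
        with pytest.raises(ConfigError):
            age_profile_summary(CombinedFlowDraws(dims=tiny_dims, values=vals),
                                quantiles=(0.0,))
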