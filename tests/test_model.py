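import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from odast import (
    ConfigError,
    DataError,
    ModelAssemblyError,
    ReportedFlowData,
    log_level_model,
    log_measurement,
    log_poisson_obs,
    log_posterior,
    log_prior,
    pi_from_log_m,
    pi_from_m,
    rho_from_nu,
)
from odast.dims import SENDING
from odast.model import LOG_2PI
from support import oracle_log_prior, random_model_state


class TestPoissonTerm:
    def test_closed_forms(self):
        assert log_poisson_obs(0, 0.0) == pytest.approx(-1.0)
        assert log_poisson_obs(2, np.log(2.0)) == pytest.approx(np.log(2.0) - 2.0)

    def test_matches_scipy_on_grid(self, rng):
        z = rng.integers(0, 200, size=300)
        log_nu = rng.normal(1.0, 2.0, size=300)
        ours = log_poisson_obs(z, log_nu)
        ref = stats.poisson.logpmf(z, np.exp(log_nu))
        assert np.max(np.abs(ours - ref) / np.abs(ref)) < 1e-12

    def test_rejects_invalid_counts(self):
        with pytest.raises(DataError):
            log_poisson_obs(-1, 0.0)
        with pytest.raises(DataError):
            log_poisson_obs(1.5, 0.0)


class TestMeasurementTerm:
    def test_density_at_mode(self):
        assert log_measurement(1.3, 1.3, 0.0, 1.0) == pytest.approx(-0.5 * LOG_2PI)

    def test_location_family_shift_invariance(self, rng):
        x, m, a, tau = 0.7, -0.2, 0.4, 2.5
        for c in rng.normal(size=5) * 10:
            assert log_measurement(x + c, m + c, a, tau) == pytest.approx(
                log_measurement(x, m, a, tau), rel=1e-12
            )

    def test_matches_scipy_normal(self, rng):
        x = rng.normal(size=200)
        m = rng.normal(size=200)
        a = rng.normal(size=200)
        tau = rng.gamma(3.0, 1.0, size=200) + 0.1
        ours = log_measurement(x, m, a, tau)
        ref = stats.norm.logpdf(x, m + a, 1.0 / np.sqrt(tau))
        assert np.max(np.abs(ours - ref) / np.abs(ref)) < 1e-12

    def test_rejects_non_positive_precision(self):
        with pytest.raises(ConfigError):
            log_measurement(0.0, 0.0, 0.0, 0.0)


class TestLevelModel:
    def test_doubling_precision_at_mode_adds_half_log_two_per_cell(self, tiny_dims, rng):
        data = ReportedFlowData.empty(tiny_dims)
        latent, params = random_model_state(data, rng)
        from odast.model import predictor

        log_m = np.broadcast_to(
            predictor(params, tiny_dims),
            (tiny_dims.n_flows, 1, tiny_dims.n_ages, 2),
        ).copy()
        params.tau_level = 1.0
        v1 = log_level_model(log_m, params, tiny_dims)
        params.tau_level = 2.0
        v2 = log_level_model(log_m, params, tiny_dims)
        n_cells = log_m.size
        assert v2 - v1 == pytest.approx(0.5 * np.log(2.0) * n_cells)

    def test_matches_cellwise_brute_force(self, tiny_dims, rng):
        data = ReportedFlowData.empty(tiny_dims)
        latent, params = random_model_state(data, rng)
        o_idx, d_idx = tiny_dims.flow_arrays()
        expected = 0.0
        for f in range(tiny_dims.n_flows):
            for t in range(tiny_dims.n_years):
                for a in range(tiny_dims.n_ages):
                    for s in range(2):
                        mean = (
                            params.dest_age[d_idx[f], a]
                            + params.dest_sex[d_idx[f], s]
                            + params.orig_age[o_idx[f], a]
                            + params.orig_sex[o_idx[f], s]
                        )
                        expected += stats.norm.logpdf(
                            latent.log_m[f, t, a, s], mean,
                            1.0 / np.sqrt(params.tau_level),
                        )
        ours = log_level_model(latent.log_m, params, tiny_dims)
        assert ours == pytest.approx(expected, rel=1e-10)


class TestPrior:
    def test_matches_term_by_term_oracle(self, tiny_study, rng):
        _, _, data, _ = tiny_study
        latent, params = random_model_state(data, rng)
        ours = log_prior(params, latent)
        assert ours == pytest.approx(
            oracle_log_prior(latent, params, data.dims), rel=1e-10
        )

    def test_invariant_to_country_relabelling(self, tiny_dims, rng):
        data = ReportedFlowData.empty(tiny_dims)
        latent, params = random_model_state(data, rng)
        base = log_prior(params, latent)
        # swap the two non-RoW country rows in every effect family
        perm = [0, 2, 1]
        swapped = params.copy()
        for name in ("dest_age", "dest_sex", "orig_age", "orig_sex"):
            setattr(swapped, name, getattr(params, name)[perm])
        assert log_prior(swapped, latent) == pytest.approx(base, rel=1e-12)

    def test_constraint_violation_raises(self, tiny_dims, rng):
        data = ReportedFlowData.empty(tiny_dims)
        latent, params = random_model_state(data, rng)
        params.age_effect[0] = 0.3
        with pytest.raises(ModelAssemblyError):
            log_prior(params, latent)


class TestPosterior:
    def test_empty_data_reduces_to_prior_plus_level(self, tiny_dims, rng):
        data = ReportedFlowData.empty(tiny_dims)
        latent, params = random_model_state(data, rng)
        expected = log_prior(params, latent) + log_level_model(
            latent.log_m, params, tiny_dims
        )
        assert log_posterior(data, latent, params) == pytest.approx(expected, rel=1e-12)

    def test_decreases_as_an_observation_moves_from_its_mean(self, tiny_study, rng):
        _, _, data, _ = tiny_study
        latent, params = random_model_state(data, rng)
        k, f, t = map(int, (i[0] for i in np.where(data.mask_agesex)))
        base = data.z_agesex[k, f, t, 0, 0]
        nu = np.exp(latent.log_nu_agesex[k, f, t, 0, 0])
        values = []
        for z in (int(np.floor(nu)), int(np.floor(nu)) + 3, int(np.floor(nu)) + 9):
            data.z_agesex[k, f, t, 0, 0] = z
            values.append(log_posterior(data, latent, params))
        data.z_agesex[k, f, t, 0, 0] = base
        assert values[0] > values[1] > values[2]

    def test_removing_a_block_changes_exactly_its_terms(self, tiny_study, rng):
        _, _, data, _ = tiny_study
        latent, params = random_model_state(data, rng)
        full = log_posterior(data, latent, params)
        k, f, t = (int(i[0]) for i in np.where(data.mask_agesex))
        import copy

        reduced = copy.deepcopy(data)
        reduced.mask_agesex[k, f, t] = False
        latent2 = latent.copy()
        latent2.report_mask = reduced.report_mask.copy()
        removed_terms = 0.0
        alpha = latent.report_effect[k, f, t]
        tau = params.tau_send if k == SENDING else params.tau_recv
        for a in range(data.dims.n_ages):
            for s in range(2):
                ln = latent.log_nu_agesex[k, f, t, a, s]
                removed_terms += log_measurement(ln, latent.log_m[f, t, a, s], alpha, tau)
                removed_terms += log_poisson_obs(data.z_agesex[k, f, t, a, s], ln)
        removed_terms += stats.norm.logpdf(alpha, 0.0, 10.0)  # the block's interaction
        assert log_posterior(reduced, latent2, params) == pytest.approx(
            full - removed_terms, rel=1e-10
        )

    def test_mask_mismatch_raises(self, tiny_study, rng):
        _, _, data, _ = tiny_study
        latent, params = random_model_state(data, rng)
        latent.report_mask = ~latent.report_mask
        with pytest.raises(ModelAssemblyError):
            log_posterior(data, latent, params)


class TestCompositions:
    def test_examples(self):
        np.testing.assert_allclose(rho_from_nu(np.full(4, 2.0)), np.full(4, 0.25))
        np.testing.assert_allclose(rho_from_nu(np.array([1.0, 3.0])), [0.25, 0.75])
        block = np.full((6, 6), 1.0)
        np.testing.assert_allclose(pi_from_m(block), np.full((6, 6), 1 / 36))

    def test_identical_to_rho(self, rng):
        block = rng.gamma(2.0, 1.0, size=(3, 2)) + 0.01
        np.testing.assert_array_equal(pi_from_m(block), rho_from_nu(block))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 1e6), min_size=2, max_size=36),
        st.floats(1e-6, 1e6),
    )
    def test_scale_invariance_and_normalization(self, values, c):
        block = np.array(values)
        out = rho_from_nu(block)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(rho_from_nu(c * block), out, rtol=1e-9)

    def test_rejects_non_positive(self):
        with pytest.raises(DataError):
            rho_from_nu(np.array([1.0, 0.0]))

    def test_pi_from_log_m_matches_blockwise(self, rng):
        log_m = rng.normal(size=(4, 2, 3, 2))
        out = pi_from_log_m(log_m)
        for f in range(4):
            for t in range(2):
                np.testing.assert_allclose(
                    out[f, t], pi_from_m(np.exp(log_m[f, t])), rtol=1e-10
                )
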