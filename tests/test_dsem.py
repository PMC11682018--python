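"""The AR(1) latent state-trait model: covariance oracle, likelihood,
indices and parameter recovery."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lstema.dsem import (DSEMParams, build_joint_covariance, loglik,
                         loglik_direct, fit_dsem, compute_indices,
                         blocks_to_wide)
from lstema.synthetic import GeneratorConfig, generate_score_level


def random_params(rng, phi_range=(-0.9, 0.9)):
    return DSEMParams(mu_trait=rng.normal(), var_trait=rng.uniform(0.05, 2),
                      beta=rng.normal(0, 0.05),
                      phi=rng.uniform(*phi_range),
                      var_state=rng.uniform(0.05, 2),
                      var_error=rng.uniform(0.05, 2))


class TestJointCovariance:
    def test_phi_zero_block_structure(self):
        p = DSEMParams(var_trait=0.7, var_state=0.4, var_error=0.2, phi=0.0)
        _, cov = build_joint_covariance(p, T=3)
        # same occasion, different indicators: trait + state
        assert cov[0, 1] == pytest.approx(0.7 + 0.4)
        # different occasions: trait only
        assert cov[0, 2] == pytest.approx(0.7)
        assert cov[0, 0] == pytest.approx(0.7 + 0.4 + 0.2)

    def test_occasion_variance_approaches_stationary_limit(self):
        p = DSEMParams(var_trait=0.0, var_state=1.0, var_error=0.0, phi=0.5)
        _, cov = build_joint_covariance(p, T=40)
        assert cov[-1, -1] == pytest.approx(1 / (1 - 0.25), rel=1e-6)

    def test_pure_noise_limit_is_diagonal(self):
        p = DSEMParams(var_trait=0.0, var_state=0.0, var_error=1.3)
        _, cov = build_joint_covariance(p, T=4)
        assert np.allclose(cov, 1.3 * np.eye(8))

    def test_mean_includes_linear_trend(self):
        p = DSEMParams(mu_trait=2.0, beta=0.5)
        mean, _ = build_joint_covariance(p, T=3)
        assert np.allclose(mean, [2.0, 2.0, 2.5, 2.5, 3.0, 3.0])

    def test_nonstationary_phi_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            build_joint_covariance(DSEMParams(phi=1.0), T=3)

    def test_negative_variance_rejected_naming_field(self):
        with pytest.raises(ValueError, match="var_state"):
            DSEMParams(var_state=-0.1).validate()


class TestLoglik:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("stationary", [False, True])
    def test_kalman_matches_direct_oracle(self, seed, stationary):
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        N, T = int(rng.integers(1, 6)), int(rng.integers(1, 7))
        mean, cov = build_joint_covariance(p, T, stationary_init=stationary)
        y = rng.multivariate_normal(mean, cov, size=N).reshape(N, T, 2)
        y[rng.random((N, T, 2)) < 0.25] = np.nan
        y[:, 0, 0] = rng.normal(size=N)  # every subject observes something
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = loglik(p, y, stationary_init=stationary)
            b = loglik_direct(p, y, stationary_init=stationary)
        assert a == pytest.approx(b, abs=1e-8)

    def test_inflated_error_variance_lowers_loglik(self):
        rng = np.random.default_rng(3)
        p = DSEMParams(var_trait=1, var_state=0.5, var_error=0.5, phi=0.3)
        mean, cov = build_joint_covariance(p, 6)
        y = rng.multivariate_normal(mean, cov, size=10).reshape(10, 6, 2)
        big = DSEMParams(var_trait=1, var_state=0.5, var_error=50.0, phi=0.3)
        bigger = DSEMParams(var_trait=1, var_state=0.5, var_error=100.0,
                            phi=0.3)
        assert loglik(bigger, y) < loglik(big, y) < loglik(p, y)

    def test_average_loglik_matches_gaussian_entropy_rate(self):
        # law of large numbers: E[log density] = -(k log 2pi + logdet + k)/2
        rng = np.random.default_rng(5)
        p = DSEMParams(var_trait=0.8, var_state=0.6, var_error=0.4, phi=0.4)
        T, N = 5, 4000
        mean, cov = build_joint_covariance(p, T)
        y = rng.multivariate_normal(mean, cov, size=N).reshape(N, T, 2)
        k = 2 * T
        expected = -0.5 * (k * np.log(2 * np.pi)
                           + np.linalg.slogdet(cov)[1] + k)
        assert loglik(p, y) / N == pytest.approx(expected, rel=0.02)

    def test_empty_subject_contributes_zero_with_warning(self):
        p = DSEMParams()
        y = np.full((2, 3, 2), np.nan)
        y[0] = 0.5
        with pytest.warns(UserWarning, match="zero observed"):
            a = loglik(p, y)
        assert a == pytest.approx(loglik(p, y[:1]))


class TestIndices:
    def test_phi_zero_closed_form(self):
        ix = compute_indices(DSEMParams(var_trait=1, var_state=1,
                                        var_error=2, phi=0))
        assert ix.var_occ == pytest.approx(1)
        assert ix.var_total == pytest.approx(4)
        assert ix.rel == pytest.approx(0.5)
        assert ix.con == pytest.approx(0.25)
        assert ix.spe == pytest.approx(0.25)
        assert ix.rel_within == pytest.approx(1 / 3)

    def test_truncated_occasion_variance_geometric_sum(self):
        ix = compute_indices(DSEMParams(phi=0.5, var_state=1.0))
        assert ix.var_occ == pytest.approx((1 - 0.5 ** 10) / (1 - 0.25),
                                           abs=1e-12)
        assert ix.var_occ == pytest.approx(1.33203125, abs=1e-12)

    def test_error_free_limit(self):
        ix = compute_indices(DSEMParams(var_trait=1, var_state=0.5,
                                        var_error=0.0, phi=0.2))
        assert ix.rel == pytest.approx(1.0)
        assert ix.rel_within == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(phi=st.floats(-0.98, 0.98),
           vt=st.floats(0.01, 10), vs=st.floats(0.01, 10),
           ve=st.floats(0.01, 10))
    def test_index_invariants(self, phi, vt, vs, ve):
        ix = compute_indices(DSEMParams(var_trait=vt, var_state=vs,
                                        var_error=ve, phi=phi))
        assert 0 <= ix.con <= ix.rel <= 1
        assert 0 <= ix.spe <= 1
        assert 0 <= ix.rel_within <= 1
        # con + spe <= rel, equality iff phi == 0
        assert ix.con + ix.spe <= ix.rel + 1e-12
        if phi == 0:
            assert ix.con + ix.spe == pytest.approx(ix.rel)
        assert ix.var_total == pytest.approx(vt + ix.var_occ + ve)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50), phi=st.floats(-0.9, 0.9))
    def test_indices_invariant_to_measurement_unit(self, scale, phi):
        base = DSEMParams(mu_trait=1.0, var_trait=0.7, beta=0.01, phi=phi,
                          var_state=0.5, var_error=0.3)
        scaled = DSEMParams(mu_trait=base.mu_trait * scale,
                            var_trait=base.var_trait * scale ** 2,
                            beta=base.beta * scale, phi=phi,
                            var_state=base.var_state * scale ** 2,
                            var_error=base.var_error * scale ** 2)
        a, b = compute_indices(base), compute_indices(scaled)
        for attr in ("rel", "con", "spe", "rel_within"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))


class TestFit:
    def test_recovers_generating_parameters(self, recovery_params):
        cfg = GeneratorConfig(n_subjects=150, n_days=14, prompts_per_day=4,
                              compliance_rate=1.0, seed=10,
                              scores={"y": recovery_params})
        blocks, _ = generate_score_level(cfg)
        fit = fit_dsem(blocks_to_wide(blocks, "y"), compute_se=False)
        p, t = fit.params, recovery_params
        assert p.var_trait == pytest.approx(t.var_trait, rel=0.25)
        assert p.var_state == pytest.approx(t.var_state, rel=0.25)
        assert p.var_error == pytest.approx(t.var_error, rel=0.25)
        assert p.phi == pytest.approx(t.phi, abs=0.1)
        assert p.beta == pytest.approx(t.beta, abs=0.01)

    def test_zero_state_variance_gives_rel_equal_con(self):
        truth = DSEMParams(mu_trait=0, var_trait=1, beta=0, phi=0,
                           var_state=0, var_error=0.5)
        cfg = GeneratorConfig(n_subjects=120, n_days=10, prompts_per_day=2,
                              compliance_rate=1.0, seed=4,
                              scores={"y": truth})
        blocks, _ = generate_score_level(cfg)
        fit = fit_dsem(blocks_to_wide(blocks, "y"), compute_se=False)
        assert fit.indices.spe == pytest.approx(0.0, abs=0.02)
        assert fit.indices.rel == pytest.approx(fit.indices.con, abs=0.03)

    def test_standard_errors_scale_with_information(self, recovery_params):
        cfg = GeneratorConfig(n_subjects=60, n_days=7, prompts_per_day=2,
                              compliance_rate=1.0, seed=2,
                              scores={"y": recovery_params})
        blocks, _ = generate_score_level(cfg)
        fit = fit_dsem(blocks_to_wide(blocks, "y"))
        assert set(fit.se) == {"mu_trait", "var_trait", "beta", "phi",
                               "var_state", "var_error"}
        assert all(v > 0 for v in fit.se.values())
        assert np.isfinite(fit.loglik)

    def test_subjects_below_min_complete_are_dropped(self):
        cfg = GeneratorConfig(n_subjects=12, n_days=7, prompts_per_day=2,
                              compliance_rate=1.0, seed=9,
                              scores={"y": DSEMParams()})
        blocks, _ = generate_score_level(cfg)
        y = blocks_to_wide(blocks, "y")
        y[0, 2:, :] = np.nan  # subject 1 keeps only 2 complete occasions
        fit = fit_dsem(y, compute_se=False)
        assert fit.n_subjects == 11
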