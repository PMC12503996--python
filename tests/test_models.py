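"""Analysis models: OLS recovery, mixed-model likelihood, policy contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deltami import (GenConfig, MissConfig, apply_missingness, fit_lm,
                     fit_lmm, lmm_loglik, lmm_marginal_covariance,
                     policy_contrast, simulate_trial, wald_test)
from deltami.models import (ContrastResult, _LmmData, _profiled_crit,
                            lmm_design_matrix, _contrast_from,
                            lmm_fixed_effect_names)
from conftest import make_manual_table


class TestWaldTest:
    @pytest.mark.parametrize("z, reject, direction", [
        (0.0, False, 0), (2.0, True, 1), (-1.95, False, 0), (-2.5, True, -1),
    ])
    def test_decision_rule(self, z, reject, direction):
        r = wald_test(z * 10.0, 10.0)
        assert r.reject_two_sided is reject
        assert r.onesided_direction == direction

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


def _lm_table(n, coefs, rng=None, noise=0.0):
    """Trial table where weeks 21-24 equal the LM surface exactly."""
    alpha, b_age, b_r, b_a = coefs
    rng = rng or np.random.default_rng(0)
    rows = []
    for pid in range(n):
        age = 20 + 20 * pid / (n - 1)
        arm = pid % 2
        y0 = 4000 + 100 * ((pid * 7) % 11)
        yi = alpha + b_age * age + b_r * y0 + b_a * arm
        if noise:
            yi += rng.normal(0, noise)
        for w in range(0, 25):
            y = y0 if w == 0 else (yi if w >= 21 else 6000.0)
            rows.append((pid, w, age, arm, y, 1))
    return make_manual_table(rows)


class TestLinearModel:
    def test_exact_recovery_noise_free(self):
        coefs = (2000.0, -40.0, 0.8, 600.0)
        fit = fit_lm(_lm_table(12, coefs))
        assert np.allclose(fit.params_.to_numpy(), coefs, rtol=0, atol=1e-6)
        assert fit.contrast_.theta_hat == pytest.approx(600.0, abs=1e-6)

    def test_matches_normal_equations_oracle(self):
        table = _lm_table(10, (2000.0, -40.0, 0.8, 600.0),
                          rng=np.random.default_rng(3), noise=500.0)
        fit = fit_lm(table)
        # independent closed-form solve of the normal equations
        base = table[table["week"] == 0]
        resp = table[table["week"] == 21].set_index("pid")["y"]
        X = np.column_stack([np.ones(10), base["age"], base["y"], base["arm"]])
        y = resp.loc[base["pid"]].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (10 - 4)
        cov = s2 * np.linalg.inv(X.T @ X)
        assert np.allclose(fit.params_.to_numpy(), beta)
        assert np.allclose(fit.cov_params_.to_numpy(), cov)

    def test_response_uses_observed_subset(self):
        table = _lm_table(8, (2000.0, -40.0, 0.8, 600.0))
        # mask weeks 22-24 for pid 0: response falls back to week 21 alone
        m = (table["pid"] == 0) & table["week"].isin([22, 23, 24])
        table.loc[m, "observed"] = 0
        fit = fit_lm(table)
        assert fit.n_used_ == 8
        # mask all four primary weeks for pid 1: participant dropped
        m = (table["pid"] == 1) & table["week"].isin([21, 22, 23, 24])
        table.loc[m, "observed"] = 0
        assert fit_lm(table).n_used_ == 7

    def test_too_few_participants_rejected(self):
        table = _lm_table(8, (0.0, 0.0, 0.0, 0.0))
        table = table[table["pid"] < 3]
        with pytest.raises(ValueError):
            fit_lm(table)


class TestMarginalCovariance:
    def test_hand_built_three_by_three(self):
        V = lmm_marginal_covariance([0, 1, 2], 1.0, 1.0, 1.0, 0.5)
        expected = np.array([[2.0, 1.5, 1.25],
                             [1.5, 3.0, 3.5],
                             [1.25, 3.5, 6.0]])
        assert np.allclose(V, expected)

    def test_iid_limit(self):
        V = lmm_marginal_covariance(np.arange(5), 0.0, 0.0, 2.0, 0.0)
        assert np.allclose(V, 4.0 * np.eye(5))

    def test_translation_invariance_without_slope(self):
        V1 = lmm_marginal_covariance([0, 1, 3], 1.0, 0.0, 1.0, 0.6)
        V2 = lmm_marginal_covariance([10, 11, 13], 1.0, 0.0, 1.0, 0.6)
        assert np.allclose(V1, V2)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            lmm_marginal_covariance([0, 1], 1, 1, 1, 1.0)


def _toy_table(rng, n_pid=3, weeks=(0, 1, 2, 4, 7), mask=()):
    rows = []
    for pid in range(n_pid):
        age = 25.0 + 3 * pid
        arm = pid % 2
        for w in weeks:
            rows.append((pid, w, age, arm, float(rng.normal(5000, 1000)),
                         0 if (pid, w) in mask else 1))
    return make_manual_table(rows)


class TestObservedLoglik:
    def _params(self):
        beta = np.zeros(30)
        beta[0] = -50.0       # age
        beta[1] = 4500.0      # run-in level
        beta[2] = 8000.0      # post-baseline level
        beta[3] = 20.0        # linear time
        return beta, 60.0, 15.0, 900.0, 0.7

    def test_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(5)
        table = _toy_table(rng, mask={(1, 2), (2, 7)})
        beta, sb0, sb1, sres, rho = self._params()
        ours = lmm_loglik(beta, sb0, sb1, sres, rho, table)
        # independent oracle: scipy dense multivariate normal per participant
        oracle = 0.0
        for _, g in table[table["observed"] == 1].groupby("pid"):
            w = g["week"].to_numpy(float)
            X = lmm_design_matrix(w, g["age"].iloc[0], int(g["arm"].iloc[0]))
            V = (sb0**2 + sb1**2 * np.outer(w, w)
                 + sres**2 * rho ** np.abs(w[:, None] - w[None, :]))
            oracle += stats.multivariate_normal.logpdf(
                g["y"].to_numpy(), mean=X @ beta, cov=V)
        assert abs(ours - oracle) < 1e-8

    def test_masking_equals_dropping_rows(self):
        rng = np.random.default_rng(6)
        table = _toy_table(rng, mask={(0, 1)})
        dropped = table[~((table["pid"] == 0) & (table["week"] == 1))]
        beta, *vc = self._params()
        assert np.isclose(lmm_loglik(beta, *vc, table),
                          lmm_loglik(beta, *vc, dropped), atol=1e-10)

    def test_location_invariance(self):
        rng = np.random.default_rng(7)
        table = _toy_table(rng)
        beta, *vc = self._params()
        shifted = table.copy()
        shifted["y"] = shifted["y"] + 1234.5
        beta2 = beta.copy()
        beta2[1] += 1234.5   # run-in level
        beta2[2] += 1234.5   # post-baseline level
        assert np.isclose(lmm_loglik(beta, *vc, table),
                          lmm_loglik(beta2, *vc, shifted), atol=1e-8)


class TestMixedModelFit:
    def test_gls_equals_ols_in_iid_limit(self, trial_table):
        # at vanishing random effects and rho = 0 the GLS solution is OLS
        data = _LmmData(trial_table)
        _, parts = _profiled_crit(np.array([-30.0, -30.0, 0.0]), data, False)
        beta_gls = parts[0]
        rhs = data.rhs_c[data.valid]
        beta_ols, *_ = np.linalg.lstsq(rhs[:, 1:], rhs[:, 0], rcond=None)
        assert np.allclose(beta_gls, beta_ols, rtol=1e-8, atol=1e-8)

    def test_fitted_criterion_beats_true_parameters(self):
        cfg = GenConfig(n=80)
        for seed in (1, 2):
            table = simulate_trial(cfg, seed)
            fit = fit_lmm(table, method="ml")
            data = _LmmData(table)
            # true variance components of the generator, on the fit's scale
            g = cfg.sigma_c0 / cfg.sigma_e
            theta_true = np.array([np.log(g), np.log(g),
                                   np.arctanh(np.exp(-1 / 52))])
            crit_true = _profiled_crit(theta_true, data, False)[0]
            crit_fit = _profiled_crit(fit.theta_, data, False)[0]
            assert crit_fit <= crit_true + 1e-6

    def test_recovers_null_policy_effect_large_n(self):
        cfg = GenConfig(n=1000)
        fit = fit_lmm(simulate_trial(cfg, 31))
        c = fit.contrast_
        assert fit.converged_
        assert abs(c.theta_hat) < 3 * c.se
        assert fit.sigma_res_ == pytest.approx(2000, rel=0.1)
        assert fit.rho_ == pytest.approx(np.exp(-1 / 52), abs=0.02)

    def test_invariant_to_pid_relabeling_and_row_order(self, small_masked_table):
        fit1 = fit_lmm(small_masked_table)
        shuffled = small_masked_table.sample(frac=1.0, random_state=1)
        shuffled["pid"] = shuffled["pid"].map(
            {p: 1000 - p for p in shuffled["pid"].unique()})
        fit2 = fit_lmm(shuffled)
        # agreement to optimizer tolerance (summation order perturbs the
        # objective in the last floating-point digits)
        assert np.allclose(fit1.fixed_effects_, fit2.fixed_effects_,
                           rtol=1e-3, atol=0.05)
        assert fit1.contrast_.theta_hat == pytest.approx(
            fit2.contrast_.theta_hat, abs=0.05)

    def test_masked_fit_converges_and_reports_psd_covariance(self, masked_table):
        fit = fit_lmm(masked_table)
        assert fit.converged_
        eig = np.linalg.eigvalsh(fit.cov_fixed_.to_numpy())
        assert eig.min() > -1e-8
        assert fit.contrast_.se > 0
        report = fit.report()
        assert report["contrast"]["theta_hat"] == fit.contrast_.theta_hat
        assert report["arm_w21"]["se"] > 0
        assert report["variance_components"]["rho"] == fit.rho_


class TestPolicyContrast:
    def test_identity_covariance_block(self):
        names = lmm_fixed_effect_names()
        params = np.zeros(30)
        cov = np.zeros((30, 30))
        for w in (21, 22, 23, 24):
            i = names.index(f"arm_w{w}")
            cov[i, i] = 1.0
        r = _contrast_from(names, params, cov)
        assert r.se == pytest.approx(0.5)

    def test_constant_coefficients_zero_covariance_flagged(self):
        names = lmm_fixed_effect_names()
        params = np.zeros(30)
        for w in (21, 22, 23, 24):
            params[names.index(f"arm_w{w}")] = 300.0
        r = _contrast_from(names, params, np.zeros((30, 30)))
        assert r.theta_hat == pytest.approx(300.0)
        assert r.se == 0.0 and not r.reject_two_sided

    def test_matches_dot_product_oracle(self, small_masked_table):
        fit = fit_lmm(small_masked_table)
        r = policy_contrast(fit)
        c = np.zeros(30)
        names = fit.names_
        for w in (21, 22, 23, 24):
            c[names.index(f"arm_w{w}")] = 0.25
        assert r.theta_hat == pytest.approx(
            float(c @ fit.fixed_effects_.to_numpy()))
        assert r.se == pytest.approx(
            float(np.sqrt(c @ fit.cov_fixed_.to_numpy() @ c)))

    def test_unconverged_fit_rejected(self):
        class Dummy:
            converged_ = False
        with pytest.raises(ValueError):
            policy_contrast(Dummy())
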