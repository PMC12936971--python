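"""Warped Bayesian linear regression normative models."""

import numpy as np
import pytest
from scipy import stats

from msnbiotype.normative import (
    NormativeConfig,
    check_site_effects,
    deviation_z,
    fit_normative,
    transfer_recalibrate,
)


def simulate_identity_warp(n, seed, noise_sd=0.3):
    """Data from the identity-warp model: smooth age curve + sex effect."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(6, 18, n)
    sex = rng.integers(0, 2, n)
    mean = 0.5 + 0.2 * np.sin(age / 3.0) + 0.1 * sex
    y = mean + rng.normal(0, noise_sd, n)
    return y, age, sex, mean, noise_sd


class TestFit:
    def test_mean_curve_recovery(self):
        y, age, sex, mean, _ = simulate_identity_warp(5000, 0, noise_sd=0.2)
        model = fit_normative(y, age, sex)
        grid_age = np.linspace(7.0, 17.0, 40)
        for s in (0, 1):
            mu, _ = model.predictive(grid_age, np.full(40, s))
            truth = 0.5 + 0.2 * np.sin(grid_age / 3.0) + 0.1 * s
            recovered = model.unwarp_t(mu)
            # mean error a twentieth of the response SD; no point beyond ~3x that
            assert np.mean(np.abs(recovered - truth)) < 0.05 * np.std(y)
            assert np.max(np.abs(recovered - truth)) < 0.15 * np.std(y)

    def test_identity_warp_matches_closed_form_bayes(self):
        """With the warp pinned to identity, z equals the closed-form
        Gaussian-linear Bayesian solution computed independently."""
        y, age, sex, *_ = simulate_identity_warp(400, 1)
        cfg = NormativeConfig(warp="identity")
        model = fit_normative(y, age, sex, cfg)
        assert model.epsilon == 0.0 and model.delta == 1.0
        Phi = model.design(age, sex)
        t = (y - model.y_loc) / model.y_scale
        # closed-form posterior at the fitted (alpha, beta): alpha recovered
        # from the model's coefficient covariance
        beta = model.noise_precision
        Sigma = model.coef_cov
        alpha = np.linalg.eigvalsh(np.linalg.inv(Sigma) - beta * Phi.T @ Phi).mean()
        Sigma_cf = np.linalg.inv(alpha * np.eye(Phi.shape[1]) + beta * Phi.T @ Phi)
        mu_cf = beta * Sigma_cf @ Phi.T @ t
        z_model = deviation_z(model, y, age, sex)
        var_cf = np.einsum("ij,jk,ik->i", Phi, Sigma_cf, Phi) + 1 / beta
        z_cf = (t - Phi @ mu_cf) / np.sqrt(var_cf)
        assert np.allclose(z_model, z_cf, atol=1e-6)

    def test_skew_parameter_recovery(self):
        rng = np.random.default_rng(2)
        n = 5000
        age = rng.uniform(6, 18, n)
        sex = rng.integers(0, 2, n)
        t = 0.1 * (age - 12) / 6 + rng.normal(0, 0.5, n)
        eps_true, delta_true = 0.5, 1.0
        y = np.sinh((np.arcsinh(t) + eps_true) / delta_true)  # inverse warp
        model = fit_normative(y, age, sex)
        assert 0.3 <= model.epsilon <= 0.7

    def test_min_train_enforced(self):
        y, age, sex, *_ = simulate_identity_warp(30, 3)
        with pytest.raises(ValueError, match=">= 50"):
            fit_normative(y, age, sex)

    def test_warp_round_trip(self):
        y, age, sex, *_ = simulate_identity_warp(200, 4)
        model = fit_normative(y, age, sex)
        grid = np.linspace(y.min(), y.max(), 500)
        assert np.allclose(model.unwarp_t(model.warp_y(grid)), grid, atol=1e-9)


class TestDeviations:
    def test_predicted_median_scores_near_zero(self):
        y, age, sex, *_ = simulate_identity_warp(2000, 5)
        model = fit_normative(y, age, sex)
        mu, _ = model.predictive(age[:50], sex[:50])
        y_at_median = model.unwarp_t(mu)
        z = deviation_z(model, y_at_median, age[:50], sex[:50])
        assert np.max(np.abs(z)) < 0.05

    def test_extreme_rate_on_heldout_controls(self):
        y, age, sex, *_ = simulate_identity_warp(5000, 6)
        model = fit_normative(y[:2500], age[:2500], sex[:2500])
        z = deviation_z(model, y[2500:], age[2500:], sex[2500:])
        rate = np.mean(np.abs(z) >= 2)
        assert rate == pytest.approx(2 * stats.norm.cdf(-2), abs=0.01)

    def test_monotone_in_response(self):
        y, age, sex, *_ = simulate_identity_warp(300, 7)
        model = fit_normative(y, age, sex)
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.uniform(7, 17)
            s = rng.integers(0, 2)
            ys = np.sort(rng.uniform(y.min(), y.max(), 10))
            z = deviation_z(model, ys, np.full(10, a), np.full(10, s))
            assert np.all(np.diff(z) > 0)

    def test_extrapolation_rejected(self):
        y, age, sex, *_ = simulate_identity_warp(200, 9)
        model = fit_normative(y, age, sex)
        with pytest.raises(ValueError, match="outside training support"):
            deviation_z(model, y[:1], np.array([25.0]), sex[:1])

    def test_calibration_uniform_phi_z(self):
        """Phi(z) on held-out controls from the generative law is uniform."""
        y, age, sex, *_ = simulate_identity_warp(4000, 10)
        model = fit_normative(y[:2000], age[:2000], sex[:2000])
        z = deviation_z(model, y[2000:], age[2000:], sex[2000:])
        p = stats.kstest(stats.norm.cdf(z), "uniform").pvalue
        assert p > 0.01


class TestTransfer:
    def test_null_transfer_is_identity_like(self):
        y, age, sex, *_ = simulate_identity_warp(2000, 11)
        model = fit_normative(y[:1000], age[:1000], sex[:1000])
        recal = transfer_recalibrate(model, y[1000:], age[1000:], sex[1000:])
        assert abs(recal.cal_offset) < 0.1
        assert recal.cal_scale == pytest.approx(1.0, abs=0.1)

    def test_site_shift_recovered(self):
        y, age, sex, *_, sd = simulate_identity_warp(1200, 12)
        model = fit_normative(y[:1000], age[:1000], sex[:1000])
        shifted = y[1000:] + 2 * sd  # +2 SD site offset
        recal = transfer_recalibrate(model, shifted, age[1000:], sex[1000:])
        z = deviation_z(recal, shifted, age[1000:], sex[1000:])
        assert abs(z.mean()) < 0.1
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        y, age, sex, *_ = simulate_identity_warp(600, 13)
        model = fit_normative(y[:500], age[:500], sex[:500])
        once = transfer_recalibrate(model, y[500:], age[500:], sex[500:])
        twice = transfer_recalibrate(once, y[500:], age[500:], sex[500:])
        assert once.cal_offset == twice.cal_offset
        assert once.cal_scale == twice.cal_scale

    def test_too_few_adaptation_controls(self):
        y, age, sex, *_ = simulate_identity_warp(200, 14)
        model = fit_normative(y, age, sex)
        with pytest.raises(ValueError, match="hbn-1"):
            transfer_recalibrate(model, y[:5], age[:5], sex[:5], site="hbn-1")


class TestSiteCheck:
    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(15)
        z = rng.normal(0, 1, (200, 30))
        sites = rng.permutation(np.repeat([0, 1], 100))
        acc = check_site_effects(z, sites, seed=0)
        assert abs(acc - 0.5) < 0.12  # 2 SE-ish at n=200

    def test_unmodeled_shift_detected(self):
        rng = np.random.default_rng(16)
        sites = np.repeat([0, 1], 100)
        z = rng.normal(0, 1, (200, 30)) + sites[:, None] * 1.0
        assert check_site_effects(z, sites, seed=0) > 0.8

    def test_deterministic(self):
        rng = np.random.default_rng(17)
        z = rng.normal(0, 1, (100, 10))
        sites = np.repeat([0, 1], 50)
        assert check_site_effects(z, sites, seed=3) == check_site_effects(z, sites, seed=3)

    def test_needs_two_sites(self):
        with pytest.raises(ValueError):
            check_site_effects(np.zeros((10, 3)), np.zeros(10))
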