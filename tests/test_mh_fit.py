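"""Background subtraction, parameter recovery and summary derivation."""

import numpy as np
import pytest

from mpiphantom import (
    AAM2,
    MagnetizationCurve,
    MomentDistribution,
    derive_summary,
    fit_mh,
    mh_forward,
    subtract_background,
)


def field_grid(n=50, b_max=5.0):
    """Magnetometry-style sweep: zero plus a log-spaced ramp to b_max tesla."""
    return np.concatenate([[0.0], np.geomspace(1e-3, b_max, n - 1)])


def perturbed(dist, rng, frac=0.2):
    p = rng.uniform(1.0 - frac, 1.0 + frac, size=6)
    return MomentDistribution(
        beta=float(np.clip(dist.beta * p[0], 0.0, 1.0)),
        mu1=dist.mu1 * p[1],
        mu2=dist.mu2 * p[2],
        sigma1=dist.sigma1 * p[3],
        sigma2=dist.sigma2 * p[4],
        ms_molar=dist.ms_molar * p[5],
        temperature=dist.temperature,
    )


class TestSubtractBackground:
    def test_zero_blank_is_identity(self, mcp3):
        curve = mh_forward(mcp3, field_grid())
        blank = MagnetizationCurve(curve.field_t, np.zeros(len(curve)))
        out = subtract_background(curve, blank)
        np.testing.assert_array_equal(out.magnetization, curve.magnetization)

    def test_linear_diamagnetic_term_removed(self, mcp3):
        b = field_grid()
        signal = mh_forward(mcp3, b).magnetization
        chi = -1e-5
        blank_b = np.linspace(-0.1, 5.5, 300)
        raw = MagnetizationCurve(b, signal + chi * b)
        blank = MagnetizationCurve(blank_b, chi * blank_b)
        out = subtract_background(raw, blank)
        np.testing.assert_allclose(out.magnetization, signal, atol=1e-12)

    def test_non_overlapping_ranges_rejected(self, mcp3):
        curve = mh_forward(mcp3, field_grid())
        blank = MagnetizationCurve(np.linspace(2.0, 3.0, 20), np.zeros(20))
        with pytest.raises(ValueError, match="does not cover"):
            subtract_background(curve, blank)

    def test_molar_normalization(self, mcp3):
        b = field_grid()
        moment = mh_forward(mcp3, b).magnetization * 2e-6  # 2 umol Fe sample
        raw = MagnetizationCurve(b, moment)
        blank = MagnetizationCurve(b, np.zeros_like(b))
        out = subtract_background(raw, blank, iron_amount_mol=2e-6)
        np.testing.assert_allclose(
            out.magnetization, mh_forward(mcp3, b).magnetization, rtol=1e-12
        )

    def test_fitted_ms_unbiased_after_subtraction(self, mcp3):
        # raw = tracer + diamagnetic chi*B; subtraction must leave M_S within 1%
        b = field_grid()
        signal = mh_forward(mcp3, b).magnetization
        chi = -1e-5
        raw = MagnetizationCurve(b, signal + chi * b)
        blank = MagnetizationCurve(b, chi * b)
        corrected = subtract_background(raw, blank)
        fit = fit_mh(corrected, perturbed(mcp3, np.random.default_rng(5)))
        assert fit.distribution.ms_molar == pytest.approx(mcp3.ms_molar, rel=0.01)


class TestFitRecovery:
    def test_noiseless_recovery_from_perturbed_init(self, mcp3):
        curve = mh_forward(mcp3, field_grid())
        fit = fit_mh(curve, perturbed(mcp3, np.random.default_rng(7)))
        d = fit.distribution
        assert fit.converged
        assert d.beta == pytest.approx(0.73, rel=0.02)
        assert d.sigma2 == pytest.approx(0.13, rel=0.02)
        assert d.ms_molar == pytest.approx(5.81, rel=0.02)
        assert fit.d_v2_nm == pytest.approx(27.0, rel=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovery_identifiable_across_inits(self, mcp3, seed):
        curve = mh_forward(mcp3, field_grid())
        fit = fit_mh(curve, perturbed(mcp3, np.random.default_rng(100 + seed)))
        assert fit.distribution.beta == pytest.approx(mcp3.beta, rel=0.02)
        assert fit.distribution.mu2 == pytest.approx(mcp3.mu2, rel=0.02)

    def test_self_consistency_refit(self, mcp3):
        curve = mh_forward(mcp3, field_grid())
        fit = fit_mh(curve, perturbed(mcp3, np.random.default_rng(1)))
        refit_curve = mh_forward(fit.distribution, curve.field_t)
        refit = fit_mh(refit_curve, fit.distribution)
        assert refit.residual_norm < 1e-8 * refit.signal_norm

    def test_monte_carlo_recovery_under_noise(self, mcp3):
        # 1% multiplicative noise, 30 field points below saturation knee
        b = np.concatenate([[0.0], np.geomspace(1e-3, 5.0, 29)])
        clean = mh_forward(mcp3, b).magnetization
        errors_beta, errors_mu2 = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean * (1.0 + 0.01 * rng.standard_normal(b.size))
            noisy[0] = 0.0
            curve = MagnetizationCurve(b, noisy)
            fit = fit_mh(curve, perturbed(mcp3, rng, frac=0.1))
            errors_beta.append(abs(fit.distribution.beta - mcp3.beta))
            errors_mu2.append(abs(fit.distribution.mu2 - mcp3.mu2) / mcp3.mu2)
        assert np.median(errors_beta) < 0.05
        assert np.median(errors_mu2) < 0.05

    def test_estimated_ms_bounds_observed_magnetization(self, mcp3):
        curve = mh_forward(mcp3, field_grid())
        fit = fit_mh(curve, perturbed(mcp3, np.random.default_rng(2)))
        assert fit.distribution.ms_molar >= np.max(np.abs(curve.magnetization)) - 1e-9

    def test_too_few_points_rejected(self, mcp3):
        curve = mh_forward(mcp3, field_grid(n=10))
        with pytest.raises(ValueError, match="points"):
            fit_mh(curve)

    def test_mode_ordering_fixed_after_fit(self, mcp3):
        # start with swapped modes: fit must still label mode B as the larger
        curve = mh_forward(mcp3, field_grid())
        swapped = MomentDistribution(
            beta=1.0 - mcp3.beta,
            mu1=mcp3.mu2,
            mu2=mcp3.mu1,
            sigma1=mcp3.sigma2,
            sigma2=mcp3.sigma1,
            ms_molar=mcp3.ms_molar,
            temperature=mcp3.temperature,
        )
        fit = fit_mh(curve, swapped)
        assert fit.distribution.mu1 < fit.distribution.mu2


class TestDeriveSummary:
    def test_percent_smaller_than_tem(self, mcp3):
        curve = mh_forward(mcp3, field_grid())
        fit = fit_mh(curve, mcp3)
        summary = derive_summary(fit, tem_mean_diameter_nm=32.0)
        # d_v2 = 27 nm against a 32 nm TEM mean -> 16% smaller
        assert round(100.0 * (1.0 - 27.0 / 32.0)) == 16
        assert summary["percent_smaller_than_tem"] == pytest.approx(
            100.0 * (1.0 - summary["d_v2_nm"] / 32.0)
        )
        assert summary["mode_b_volume_percent"] == pytest.approx(73.0, rel=0.02)

    def test_volume_share_is_beta_percent(self):
        dist = MomentDistribution(1.0, 1e-19, 4e-18, 0.1, 0.1, 5.81)
        curve = mh_forward(dist, field_grid())
        fit = fit_mh(curve, dist)
        summary = derive_summary(fit)
        assert summary["mode_b_volume_percent"] == pytest.approx(100.0, abs=0.5)

    def test_beta_mu2_product(self, mcp3):
        curve = mh_forward(mcp3, field_grid())
        fit = fit_mh(curve, mcp3)
        assert fit.beta_mu2_aam2 == pytest.approx(0.73 * 3.9, rel=0.02)
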