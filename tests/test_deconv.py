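import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from angioqa import (
    DeconvolutionConfig,
    DegenerateCurveError,
    ImpulseResponse,
    InvalidInputError,
    StandardInjection,
    TimeDensityCurve,
    build_toeplitz,
    convolve,
    correct_tdc,
    deconvolve_svd,
    gamma_variate,
    standard_injection,
)
from conftest import make_curve


def brute_force_convolution(aif, h, dt):
    """O(N^2) double-loop discrete causal convolution oracle."""
    n = len(aif)
    out = np.zeros(n)
    for i in range(n):
        for j in range(i + 1):
            out[i] += aif[i - j] * h[j] * dt
    return out


class TestBuildToeplitz:
    def test_matches_definition(self):
        a = make_curve([2.0, 3.0, 5.0], dt=1.0)
        A = build_toeplitz(a)
        assert np.allclose(A, [[2, 0, 0], [3, 2, 0], [5, 3, 2]])

    def test_unit_impulse_gives_identity(self):
        a = make_curve([1.0, 0.0, 0.0], dt=1.0)
        assert np.allclose(build_toeplitz(a), np.eye(3))

    def test_dt_scaling(self):
        a = make_curve([1.0, 1.0, 1.0], dt=0.25)
        assert np.allclose(np.diag(build_toeplitz(a)), 0.25)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_toeplitz_matvec_equals_bruteforce_convolution(seed):
    """The Toeplitz operator is the discrete convolution, elementwise to 1e-12."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 65))
    dt = float(rng.uniform(0.05, 1.0))
    aif = rng.standard_normal(n)
    h = rng.standard_normal(n)
    A = build_toeplitz(TimeDensityCurve(aif, dt=dt))
    assert np.allclose(A @ h, brute_force_convolution(aif, h, dt), atol=1e-12)


class TestConvolve:
    def test_scaled_impulse_is_identity(self):
        dt = 0.5
        h = ImpulseResponse(np.array([0.3, 0.7, 0.1, 0.0]), dt=dt)
        imp = make_curve([1 / dt, 0, 0, 0], dt=dt)
        out = convolve(h, imp)
        assert np.allclose(out.values, h.values)

    def test_zero_response_gives_zero_curve(self):
        h = ImpulseResponse(np.zeros(5), dt=1.0)
        inj = make_curve([1, 2, 3, 2, 1])
        assert np.allclose(convolve(h, inj).values, 0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        dt = 0.2
        h = ImpulseResponse(rng.random(20), dt=dt)
        inj = TimeDensityCurve(rng.random(20), dt=dt)
        out = convolve(h, inj)
        assert np.allclose(out.values, brute_force_convolution(inj.values, h.values, dt), atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(8)
        dt = 0.1
        h1 = ImpulseResponse(rng.random(10), dt=dt)
        h2 = ImpulseResponse(rng.random(10), dt=dt)
        inj = TimeDensityCurve(rng.random(10), dt=dt)
        combo = convolve(ImpulseResponse(2 * h1.values + 3 * h2.values, dt=dt), inj)
        assert np.allclose(combo.values, 2 * convolve(h1, inj).values + 3 * convolve(h2, inj).values)

    def test_dt_mismatch_rejected(self):
        h = ImpulseResponse(np.ones(4), dt=0.1)
        inj = make_curve([1, 2, 3, 4], dt=0.2)
        with pytest.raises(InvalidInputError):
            convolve(h, inj)


class TestDeconvolveSvd:
    def test_impulse_aif_returns_dome_curve(self, raw_cfg):
        dt = 0.5
        q = make_curve([0.0, 1.0, 2.0, 1.0], dt=dt)
        aif = make_curve([1 / dt, 0, 0, 0], dt=dt)
        h = deconvolve_svd(aif, q, raw_cfg)
        assert np.allclose(h.values, q.values, atol=1e-12)

    def test_recovers_true_irf_from_noiseless_forward_model(self, noiseless_pair, exp_irf, raw_cfg):
        aif, q = noiseless_pair
        h = deconvolve_svd(aif, q, raw_cfg)
        assert np.max(np.abs(h.values - exp_irf.values)) < 1e-6

    def test_rank_one_truncation_matches_pinv_oracle(self):
        rng = np.random.default_rng(9)
        dt = 0.25
        aif = TimeDensityCurve(rng.random(12) + 0.5, dt=dt)
        q = TimeDensityCurve(rng.random(12), dt=dt)
        cfg = DeconvolutionConfig(truncation_fraction=1 - 1e-12, regularize_negative_irf=False, n_baseline=0)
        h = deconvolve_svd(aif, q, cfg)
        A = build_toeplitz(aif)
        U, s, Vt = np.linalg.svd(A)
        oracle = Vt[0] * (U[:, 0] @ q.values) / s[0]
        assert np.allclose(h.values, oracle, atol=1e-10)

    def test_zero_aif_is_degenerate(self, raw_cfg):
        aif = make_curve([0, 0, 0, 0])
        q = make_curve([1, 2, 3, 4])
        with pytest.raises(DegenerateCurveError):
            deconvolve_svd(aif, q, raw_cfg)

    def test_length_mismatch_rejected(self, raw_cfg):
        with pytest.raises(InvalidInputError):
            deconvolve_svd(make_curve([1, 2, 3]), make_curve([1, 2, 3, 4]), raw_cfg)

    def test_monotone_smoothing_in_truncation(self, noiseless_pair):
        """More aggressive truncation never increases the solution norm."""
        aif, q = noiseless_pair
        norms = []
        for frac in (0.0, 0.05, 0.15, 0.3, 0.6):
            cfg = DeconvolutionConfig(frac, regularize_negative_irf=False, n_baseline=0)
            norms.append(np.linalg.norm(deconvolve_svd(aif, q, cfg).values))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_scale_equivariance(self, noiseless_pair, raw_cfg):
        aif, q = noiseless_pair
        h1 = deconvolve_svd(aif, q, raw_cfg)
        h2 = deconvolve_svd(aif, q.with_values(4.0 * q.values), raw_cfg)
        assert np.allclose(h2.values, 4.0 * h1.values, atol=1e-8)


class TestStandardInjection:
    def test_peak_amplitude_at_mode(self):
        cfg = StandardInjection(amplitude=1.0, t_d=0.0, alpha=2.0, beta=1.0, dt=0.01, duration=10.0)
        curve = standard_injection(cfg)
        assert curve.values.max() == pytest.approx(1.0, abs=1e-4)
        assert curve.times[np.argmax(curve.values)] == pytest.approx(2.0, abs=0.01)

    def test_zero_amplitude_gives_zero_curve(self):
        cfg = StandardInjection(amplitude=0.0, dt=0.1, duration=5.0)
        assert np.allclose(standard_injection(cfg).values, 0.0)

    def test_grid_integral_matches_quadrature_oracle(self):
        from scipy.integrate import quad

        cfg = StandardInjection(amplitude=1.3, t_d=0.5, alpha=3.0, beta=0.4, dt=0.05, duration=15.0)
        curve = standard_injection(cfg)
        grid_integral = np.trapezoid(curve.values, dx=cfg.dt)
        exact, _ = quad(
            lambda t: gamma_variate(np.array([t]), cfg.amplitude, cfg.t_d, cfg.alpha, cfg.beta)[0],
            0.0,
            cfg.duration,
            limit=200,
        )
        assert abs(grid_integral - exact) / exact < 1e-3

    def test_curve_is_causal_and_nonnegative(self):
        cfg = StandardInjection(t_d=1.0, dt=0.1, duration=8.0)
        curve = standard_injection(cfg)
        assert np.all(curve.values >= 0)
        assert np.allclose(curve.values[curve.times <= 1.0], 0.0)


class TestCorrectTdc:
    def test_identity_when_actual_injection_is_standard(self, exp_irf, std_injection_cfg, std_curve):
        q = convolve(exp_irf, std_curve)
        cfg = DeconvolutionConfig(truncation_fraction=0.0, n_baseline=3)
        qnew = correct_tdc(std_curve, q, std_injection_cfg, cfg)
        assert np.max(np.abs(qnew.values - q.values)) < 1e-6

    def test_zero_dome_curve_gives_zero_output(self, std_injection_cfg, std_curve):
        q = std_curve.with_values(np.zeros(len(std_curve)))
        cfg = DeconvolutionConfig(truncation_fraction=0.0, n_baseline=0)
        assert np.allclose(correct_tdc(std_curve, q, std_injection_cfg, cfg).values, 0.0)

    def test_two_injections_give_same_corrected_curve(self, exp_irf, std_injection_cfg, grid):
        dt, duration = grid
        cfg = DeconvolutionConfig(truncation_fraction=0.0, n_baseline=3)
        qnews = []
        for amp, width in ((1.0, 1.0), (2.0, 3.0)):
            inj = standard_injection(
                StandardInjection(amplitude=amp, t_d=0.3, alpha=3, beta=width / 3, dt=dt, duration=duration)
            )
            q = convolve(exp_irf, inj)
            qnews.append(correct_tdc(inj, q, std_injection_cfg, cfg).values)
        peak = qnews[0].max()
        assert np.max(np.abs(qnews[0] - qnews[1])) / peak < 1e-3

    def test_scale_equivariance(self, noiseless_pair, std_injection_cfg):
        aif, q = noiseless_pair
        cfg = DeconvolutionConfig(truncation_fraction=0.0, n_baseline=0)
        q1 = correct_tdc(aif, q, std_injection_cfg, cfg)
        q2 = correct_tdc(aif, q.with_values(2.5 * q.values), std_injection_cfg, cfg)
        assert np.allclose(q2.values, 2.5 * q1.values, atol=1e-8)

    def test_recovers_pedestal_laden_noisy_curves(self, exp_irf, std_injection_cfg, grid):
        """With noise and additive pedestals on both curves, the corrected
        curve stays close to the noise-free corrected reference."""
        dt, duration = grid
        rng = np.random.default_rng(12)
        inj = standard_injection(StandardInjection(amplitude=1.4, t_d=1.2, alpha=3, beta=0.5, dt=dt, duration=duration))
        q = convolve(exp_irf, inj)
        sigma = q.values.max() / 20
        noisy_aif = inj.with_values(inj.values + 0.2 * inj.values.max() + rng.normal(0, inj.values.max() / 20, len(inj)))
        noisy_q = q.with_values(q.values + 0.15 * q.values.max() + rng.normal(0, sigma, len(q)))
        cfg = DeconvolutionConfig()  # defaults: truncation 0.15, baseline on
        qnew = correct_tdc(noisy_aif, noisy_q, std_injection_cfg, cfg)
        reference = convolve(exp_irf, standard_injection(std_injection_cfg))
        assert np.max(np.abs(qnew.values - reference.values)) / reference.values.max() < 0.15
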