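"""Blind source separation: period, (c, b) fit, alpha, beta, reference."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ppgdenoise import canonical_frame, make_hr_trace, make_pulse_waveform
from ppgdenoise.bss import (
    BSSConfig,
    build_reference,
    compute_beta,
    cost_cb,
    estimate_frame,
    estimate_period,
    fit_alpha,
    fit_c_b,
)
from ppgdenoise.errors import (
    DegenerateSignalError,
    PeriodNotFoundError,
    PoleError,
    ShapeError,
)

FS = 1000.0


def _orthogonal_sources(seed=0, n=8000):
    """Unit-shaped AC and MA made exactly orthogonal in-sample."""
    rng = np.random.default_rng(seed)
    ac = make_pulse_waveform(make_hr_trace(75.0, n / FS, FS), FS)
    from ppgdenoise import make_motion_artifact

    ma = make_motion_artifact(n / FS, FS, seed=rng, swing_amp=0.0)
    ma = ma - ac * (ma @ ac) / (ac @ ac)
    return ac, ma


class TestEstimatePeriod:
    def test_pure_tone_exact(self):
        x = np.sin(2 * np.pi * 1.0 * np.arange(8000) / FS)
        assert estimate_period(x, FS) == 1000

    def test_synthetic_pulse_75_bpm(self):
        x = make_pulse_waveform(make_hr_trace(75.0, 8.0, FS), FS)
        assert abs(estimate_period(x, FS) - 800) <= 2

    def test_white_noise_not_found(self):
        x = np.random.default_rng(0).normal(size=8000)
        with pytest.raises(PeriodNotFoundError):
            estimate_period(x, FS)

    def test_short_frame_rejected(self):
        with pytest.raises(ShapeError):
            estimate_period(np.zeros(2000), FS)


class TestFitCB:
    def test_recovers_mixing_ratio(self):
        rec = canonical_frame(seed=7)
        Ta = estimate_period(rec.x2, rec.fs)
        fit = fit_c_b(rec.x1, rec.x2, Ta)
        assert fit.converged
        assert fit.c == pytest.approx(2.0, abs=0.1)

    def test_artifact_free_frame_flagged_degenerate(self):
        ac, _ = _orthogonal_sources(seed=1)
        noise = 0.01 * np.random.default_rng(1).normal(size=(2, ac.size))
        x1, x2 = 0.5 * ac + noise[0], ac + noise[1]
        fit = fit_c_b(x1, x2, 800)
        assert not fit.converged

    def test_predictor_formula_on_periodic_signal(self):
        # for a known-periodic S the single-tap predictor equals
        # E[S(n)S(n-Ta)] / E[S^2(n-Ta)] ~ 1 (direct evaluation)
        ac, ma = _orthogonal_sources(seed=2)
        x1, x2 = 0.5 * ac + 2.0 * ma, ac + ma
        Ta = 800
        fit = fit_c_b(x1, x2, Ta)
        S = x1 - fit.c * x2
        b_direct = np.mean(S[Ta:] * S[:-Ta]) / np.mean(S[:-Ta] ** 2)
        assert fit.b == pytest.approx(b_direct, abs=1e-6)
        assert fit.b == pytest.approx(1.0, abs=0.1)

    def test_frame_not_longer_than_period_rejected(self):
        with pytest.raises(ShapeError):
            fit_c_b(np.zeros(500), np.zeros(500), 800)

    def test_cost_at_fit_beats_dense_grid(self):
        rec = canonical_frame(seed=3)
        Ta = estimate_period(rec.x2, rec.fs)
        fit = fit_c_b(rec.x1, rec.x2, Ta)
        cs = np.linspace(-1.0, 4.0, 251)
        bs = np.linspace(-0.5, 1.5, 201)
        grid = cost_cb(rec.x1, rec.x2, Ta, cs[:, None], bs[None, :])
        assert fit.cost <= grid.min() * 1.001


class TestAlphaBeta:
    def test_alpha_self_projection(self):
        x = np.random.default_rng(0).normal(size=1000)
        assert fit_alpha(x, x.copy(), 0.0) == pytest.approx(1.0)

    def test_alpha_zero_without_arterial_content(self):
        ac, ma = _orthogonal_sources(seed=4)
        x1 = 2.0 * ma  # a = 0: no AC in the red channel
        x2 = ac + ma
        assert fit_alpha(x1, x2, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_alpha_closed_form_orthogonal_mixing(self):
        # a=0.5, c=2, exact orthogonality -> alpha = a/(a-c) = -1/3
        ac, ma = _orthogonal_sources(seed=5)
        x1, x2 = 0.5 * ac + 2.0 * ma, ac + ma
        assert fit_alpha(x1, x2, 2.0) == pytest.approx(-1.0 / 3.0, abs=1e-9)

    def test_alpha_equals_numeric_minimizer(self):
        rec = canonical_frame(seed=9)
        c = 2.0

        def obj(alpha):
            n1 = rec.x1 - alpha * (rec.x1 - c * rec.x2)
            return np.mean(n1**2)

        res = minimize_scalar(obj, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-12})
        assert fit_alpha(rec.x1, rec.x2, c) == pytest.approx(res.x, abs=1e-6)

    def test_alpha_degenerate_rejected(self):
        x = np.random.default_rng(1).normal(size=100)
        with pytest.raises(DegenerateSignalError):
            fit_alpha(x, x.copy(), 1.0)  # S = x - x = 0

    def test_beta_zero_numerator(self):
        assert compute_beta(0.0, 5.0) == 0.0

    def test_beta_hand_value(self):
        assert compute_beta(-1.0 / 3.0, 2.0) == pytest.approx(0.5)

    def test_beta_pole(self):
        with pytest.raises(PoleError):
            compute_beta(1.0, 2.0)


class TestReference:
    def test_zero_beta_returns_x1(self):
        x1 = np.arange(5.0)
        ref = build_reference(x1, np.ones(5), 0.0)
        np.testing.assert_array_equal(ref.n_seq, x1)

    def test_identical_channels_unit_beta_cancels(self):
        x = np.random.default_rng(2).normal(size=100)
        assert not np.any(build_reference(x, x.copy(), 1.0).n_seq)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            build_reference(np.zeros(5), np.zeros(4), 0.5)

    def test_true_beta_isolates_artifact(self):
        # beta = a on a noise-free mixture leaves (c-a)*MA only
        ac, ma = _orthogonal_sources(seed=6)
        x1, x2 = 0.5 * ac + 2.0 * ma, ac + ma
        ref = build_reference(x1, x2, 0.5)
        assert abs(np.corrcoef(ref.n_seq, ma)[0, 1]) >= 0.99
        assert abs(np.corrcoef(ref.n_seq, ac)[0, 1]) <= 0.05


class TestEstimateFrame:
    def test_scale_covariance(self):
        rec = canonical_frame(seed=12)
        est1, ref1 = estimate_frame(rec.x1, rec.x2, rec.fs)
        k = 3.7
        est2, ref2 = estimate_frame(k * rec.x1, k * rec.x2, rec.fs)
        assert est2.c == pytest.approx(est1.c, rel=1e-6)
        assert est2.alpha == pytest.approx(est1.alpha, rel=1e-6)
        assert est2.beta == pytest.approx(est1.beta, rel=1e-6)
        np.testing.assert_allclose(ref2.n_seq, k * ref1.n_seq, rtol=1e-9)

    def test_first_frame_fallbacks(self):
        # white noise on both channels: no period, degenerate fit ->
        # 75 bpm prior and a zeroed reference
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(size=8000), rng.normal(size=8000)
        est, ref = estimate_frame(x1, x2, FS)
        assert "ta_fallback" in est.flags
        assert est.Ta == 800
        assert "reference_zeroed" in est.flags
        assert not np.any(ref.n_seq)

    def test_previous_estimates_carried(self):
        rec = canonical_frame(seed=13)
        prev, _ = estimate_frame(rec.x1, rec.x2, rec.fs)
        rng = np.random.default_rng(4)
        x1, x2 = rng.normal(size=8000), rng.normal(size=8000)
        est, ref = estimate_frame(x1, x2, FS, prev=prev)
        assert est.Ta == prev.Ta
        assert est.beta == pytest.approx(prev.beta)
        assert "beta_carried" in est.flags
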