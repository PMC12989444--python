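"""Peak detection, windowed heart rate, alignment, agreement metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgdenoise import (
    align_by_peak_xcorr,
    bland_altman,
    detect_peaks,
    hr_reference_series,
    hr_series,
    mae,
    make_hr_trace,
    make_pulse_waveform,
    pearson_r,
)
from ppgdenoise.errors import (
    DegenerateSignalError,
    EmptyInputError,
    ShapeError,
)
from ppgdenoise.hrmetrics import agreement_report, paired_valid

FS = 1000.0


class TestDetectPeaks:
    def test_clean_60_bpm_pulse(self):
        x = make_pulse_waveform(make_hr_trace(60.0, 8.0, FS), FS)
        peaks = detect_peaks(x, FS)
        assert abs(len(peaks) - 8) <= 1
        gaps = np.diff(peaks)
        assert np.all(np.abs(gaps - 1000) <= 10)

    def test_all_zero_signal_empty(self):
        assert detect_peaks(np.zeros(1000), FS).size == 0

    def test_single_impulse(self):
        x = np.zeros(1000)
        x[500] = 1.0
        peaks = detect_peaks(x, FS)
        assert list(peaks) == [500]

    def test_empty_signal_rejected(self):
        with pytest.raises(EmptyInputError):
            detect_peaks(np.zeros(0), FS)


class TestHRSeries:
    def test_uniform_one_second_spacing(self):
        peaks = np.arange(0, 32000, 1000)
        hrs = hr_series(peaks, FS, window_s=8.0, total_s=32.0)
        assert np.all(hrs.valid)
        np.testing.assert_allclose(hrs.bpm, 60.0)

    def test_ramp_tracks_truth(self):
        hr = make_hr_trace(75.0, 40.0, FS, drift_bpm=15.0, drift_period_s=80.0)
        x = make_pulse_waveform(hr, FS)
        est = hr_series(detect_peaks(x, FS), FS, 8.0, 40.0)
        ref = hr_reference_series(hr, FS, 8.0)
        e, r = paired_valid(est, ref)
        assert e.size >= 4
        assert np.max(np.abs(e - r)) <= 1.0

    def test_single_peak_window_invalid(self):
        hrs = hr_series(np.array([100]), FS, window_s=8.0, total_s=8.0)
        assert not hrs.valid[0]
        assert np.isnan(hrs.bpm[0])

    def test_missed_beat_interval_screened(self):
        # drop one peak from a uniform train: the doubled interval is
        # rejected and the window HR stays 60
        peaks = np.arange(0, 8000, 800)
        peaks = np.delete(peaks, 4)
        hrs = hr_series(peaks, FS, window_s=8.0, total_s=8.0)
        assert hrs.bpm[0] == pytest.approx(75.0, abs=0.5)


class TestAlignment:
    def test_identical_trains_zero_lag(self):
        peaks = np.arange(500, 20000, 800)
        lag, clamped = align_by_peak_xcorr(peaks, peaks, FS)
        assert lag == 0.0
        assert not clamped

    def test_known_shift_recovered(self):
        ref = np.arange(500, 20000, 800)
        lag, clamped = align_by_peak_xcorr(ref + 250, ref, FS)
        assert lag == pytest.approx(0.25, abs=0.05)
        assert not clamped

    def test_shift_beyond_search_range_clamped(self):
        # aperiodic train shifted slightly past the search bound; broad
        # smoothing makes the correlation rise monotonically toward the
        # true lag, pinning the restricted argmax at the boundary
        rng = np.random.default_rng(0)
        ref = np.cumsum(rng.integers(600, 1000, size=30)) + 500
        lag, clamped = align_by_peak_xcorr(
            ref + 2200, ref, FS, max_lag_s=2.0, sigma_s=0.3
        )
        assert clamped
        assert abs(lag) == pytest.approx(2.0, abs=0.01)

    def test_empty_train_rejected(self):
        with pytest.raises(EmptyInputError):
            align_by_peak_xcorr(np.array([]), np.array([1]), FS)


class TestAgreement:
    def test_perfect_agreement_identities(self):
        est = np.array([60.0, 62.0, 64.0, 63.0])
        rep = agreement_report(est, est.copy())
        assert rep.R == pytest.approx(1.0)
        assert rep.MAE == 0.0
        assert rep.bias_mu == 0.0 and rep.sd_sigma == 0.0
        assert (rep.loa_low, rep.loa_high) == (0.0, 0.0)

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_three_points(self):
        est = np.array([60.0, 62.0, 64.0])
        ref = np.array([61.0, 61.0, 65.0])
        assert pearson_r(est, ref) == pytest.approx(0.8660, abs=5e-4)
        assert mae(est, ref) == pytest.approx(1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_constant_offset(self):
        ref = np.array([60.0, 70.0, 80.0])
        mu, sd, lo, hi = bland_altman(ref + 5.0, ref)
        assert (mu, sd) == (5.0, 0.0)
        assert (lo, hi) == (5.0, 5.0)

    def test_bland_altman_hand_computed(self):
        ref = np.array([60.0, 60.0, 60.0])
        est = ref + np.array([-1.0, 0.0, 1.0])
        mu, sd, lo, hi = bland_altman(est, ref)
        assert mu == 0.0
        assert sd == pytest.approx(1.0)  # sample SD, n-1
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            mae(np.zeros(3), np.zeros(4))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_r_invariant_to_affine_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        est = rng.normal(70, 5, size=12)
        ref = rng.normal(70, 5, size=12)
        r0 = pearson_r(est, ref)
        r1 = pearson_r(3.2 * est + 17.0, ref)
        assert r1 == pytest.approx(r0, abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_mae_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(70, 10, size=(3, 15))
        assert mae(a, c) <= mae(a, b) + mae(b, c) + 1e-12

    def test_loa_identity_holds(self):
        rng = np.random.default_rng(3)
        est, ref = rng.normal(75, 6, size=(2, 30))
        rep = agreement_report(est, ref)
        assert rep.loa_low == pytest.approx(rep.bias_mu - 1.96 * rep.sd_sigma)
        assert rep.loa_high == pytest.approx(rep.bias_mu + 1.96 * rep.sd_sigma)
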