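"""Peak detection, windowed heart rate, peak-train alignment, and
agreement statistics (Pearson R, MAE, Bland-Altman limits of agreement).

HR is computed per window (8 s default) as 60 over the mean inter-beat
interval of the peaks inside the window; a window with fewer than two
intervals is marked invalid.  Agreement between an estimated and a
reference HR series is summarized by the Pearson correlation, the mean
absolute error in bpm, and the Bland-Altman bias mu, sample SD sigma and
limits of agreement [mu - 1.96 sigma, mu + 1.96 sigma] of the paired
differences (est - ref convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import correlate, find_peaks

from .errors import DegenerateSignalError, EmptyInputError, ShapeError

__all__ = [
    "HRSeries",
    "AgreementReport",
    "detect_peaks",
    "hr_series",
    "hr_reference_series",
    "align_by_peak_xcorr",
    "pearson_r",
    "mae",
    "bland_altman",
    "agreement_report",
]

BPM_CEILING = 180.0  # minimum peak separation corresponds to this rate


@dataclass
class HRSeries:
    """Windowed heart-rate estimates."""

    window_centers: np.ndarray  # seconds
    bpm: np.ndarray
    valid: np.ndarray  # bool per window


@dataclass
class AgreementReport:
    R: float
    MAE: float
    bias_mu: float
    sd_sigma: float
    loa_low: float
    loa_high: float
    n_pairs: int


def detect_peaks(
    signal: np.ndarray,
    fs: float,
    prominence_frac: float = 0.3,
) -> np.ndarray:
    """Systolic-peak indices: local maxima separated by at least the
    180 bpm period, exceeding an adaptive prominence threshold set as a
    fraction of the robust signal range (5th-95th percentile)."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise EmptyInputError("empty signal")
    spread = float(np.percentile(x, 95) - np.percentile(x, 5))
    if spread <= 0:
        spread = float(np.max(x) - np.min(x))
    if spread <= 0:
        return np.zeros(0, dtype=int)
    distance = max(int(fs * 60.0 / BPM_CEILING), 1)
    peaks, _ = find_peaks(x, distance=distance,
                          prominence=prominence_frac * spread)
    return peaks


def hr_series(
    peaks: np.ndarray,
    fs: float,
    window_s: float = 8.0,
    total_s: Optional[float] = None,
    bpm_range: tuple = (40.0, 180.0),
    ibi_rel_tol: float = 0.3,
) -> HRSeries:
    """Windowed HR from a peak train.

    Each window [k*w, (k+1)*w) gets HR = 60 / mean(IBI) over the
    inter-beat intervals whose both endpoints fall inside the window.
    Before averaging, intervals are screened the way heart-rate
    variability pipelines screen ectopic/artifact beats: an IBI outside
    the physiologic range or deviating from the window median by more
    than ``ibi_rel_tol`` (a missed beat doubles an interval, a spurious
    peak splits one) is discarded.  Fewer than two surviving intervals
    marks the window invalid.
    """
    if window_s <= 0:
        raise ShapeError("window_s must be positive")
    peaks = np.asarray(peaks, dtype=float)
    if total_s is None:
        total_s = float(peaks[-1] / fs) if peaks.size else 0.0
    n_win = max(int(np.ceil(total_s / window_s - 1e-12)), 0)
    centers = np.empty(n_win)
    bpm = np.full(n_win, np.nan)
    valid = np.zeros(n_win, dtype=bool)
    times = peaks / fs
    ibi_lo, ibi_hi = 60.0 / bpm_range[1], 60.0 / bpm_range[0]
    for k in range(n_win):
        lo, hi = k * window_s, min((k + 1) * window_s, total_s)
        centers[k] = 0.5 * (lo + hi)
        inside = times[(times >= lo) & (times < hi)]
        if inside.size < 3:
            continue
        ibi = np.diff(inside)
        med = float(np.median(ibi))
        keep = (
            (ibi >= ibi_lo) & (ibi <= ibi_hi)
            & (np.abs(ibi - med) <= ibi_rel_tol * med)
        )
        if np.count_nonzero(keep) >= 2:
            bpm[k] = 60.0 / float(np.mean(ibi[keep]))
            valid[k] = True
    return HRSeries(window_centers=centers, bpm=bpm, valid=valid)


def hr_reference_series(
    hr_trace: np.ndarray,
    fs: float,
    window_s: float = 8.0,
) -> HRSeries:
    """Windowed mean of a per-sample ground-truth HR trace."""
    hr = np.asarray(hr_trace, dtype=float)
    total_s = hr.size / fs
    n_win = max(int(np.ceil(total_s / window_s - 1e-12)), 0)
    centers = np.empty(n_win)
    bpm = np.empty(n_win)
    for k in range(n_win):
        i0 = int(round(k * window_s * fs))
        i1 = min(int(round((k + 1) * window_s * fs)), hr.size)
        centers[k] = 0.5 * (i0 + i1) / fs
        bpm[k] = float(np.mean(hr[i0:i1]))
    return HRSeries(window_centers=centers, bpm=bpm,
                    valid=np.ones(n_win, dtype=bool))


def align_by_peak_xcorr(
    ppg_peaks: np.ndarray,
    ref_peaks: np.ndarray,
    fs: float,
    max_lag_s: float = 2.0,
    sigma_s: float = 0.05,
) -> tuple[float, bool]:
    """Delay between two beat trains via cross-correlation of smoothed
    impulse trains (50 ms Gaussian kernel by default).

    Returns (lag_s, clamped): positive lag means the PPG train lags the
    reference; ``clamped`` flags an argmax pinned at the search boundary
    (true shift at or beyond max_lag_s).
    """
    ppg_peaks = np.asarray(ppg_peaks, dtype=int)
    ref_peaks = np.asarray(ref_peaks, dtype=int)
    if ppg_peaks.size == 0 or ref_peaks.size == 0:
        raise EmptyInputError("both peak trains must be non-empty")
    length = int(max(ppg_peaks.max(), ref_peaks.max())) + 1
    a = np.zeros(length)
    b = np.zeros(length)
    a[ppg_peaks] = 1.0
    b[ref_peaks] = 1.0
    sigma = max(sigma_s * fs, 1.0)
    a = gaussian_filter1d(a, sigma)
    b = gaussian_filter1d(b, sigma)
    xc = correlate(a, b, mode="full", method="fft")
    lags = np.arange(-length + 1, length)
    max_lag = int(round(max_lag_s * fs))
    sel = np.abs(lags) <= max_lag
    xc, lags = xc[sel], lags[sel]
    i = int(np.argmax(xc))
    clamped = i == 0 or i == lags.size - 1
    return float(lags[i] / fs), clamped


def pearson_r(est: np.ndarray, ref: np.ndarray) -> float:
    """Sample Pearson correlation between two HR series."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ShapeError("series must have equal length")
    if est.size < 3:
        raise ShapeError("need at least 3 pairs")
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        raise DegenerateSignalError("correlation undefined for constant series")
    return float(np.corrcoef(est, ref)[0, 1])


def mae(est: np.ndarray, ref: np.ndarray) -> float:
    """Mean absolute error (bpm)."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ShapeError("series must have equal length")
    if est.size == 0:
        raise EmptyInputError("empty series")
    return float(np.mean(np.abs(est - ref)))


def bland_altman(est: np.ndarray, ref: np.ndarray) -> tuple[float, float, float, float]:
    """Bias, sample SD (n-1), and limits of agreement of est - ref."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ShapeError("series must have equal length")
    if est.size < 2:
        raise ShapeError("need at least 2 pairs")
    d = est - ref
    mu = float(np.mean(d))
    sigma = float(np.std(d, ddof=1))
    return mu, sigma, mu - 1.96 * sigma, mu + 1.96 * sigma


def agreement_report(est: np.ndarray, ref: np.ndarray) -> AgreementReport:
    """Full agreement summary between estimated and reference HR."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    mu, sigma, lo, hi = bland_altman(est, ref)
    try:
        r = pearson_r(est, ref)
    except DegenerateSignalError:
        r = 1.0 if np.allclose(est, ref) else np.nan
    return AgreementReport(
        R=r, MAE=mae(est, ref), bias_mu=mu, sd_sigma=sigma,
        loa_low=lo, loa_high=hi, n_pairs=int(est.size),
    )


def paired_valid(est: HRSeries, ref: HRSeries) -> tuple[np.ndarray, np.ndarray]:
    """Pair two windowed series on windows valid in both."""
    n = min(est.bpm.size, ref.bpm.size)
    ok = est.valid[:n] & ref.valid[:n]
    return est.bpm[:n][ok], ref.bpm[:n][ok]
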