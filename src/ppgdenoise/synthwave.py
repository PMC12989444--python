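"""Seeded dual-wavelength PPG simulator with known ground truth.

Signal model
------------
The infrared (940 nm) and red (660 nm) channels share one arterial
pulsation AC and one motion-artifact process MA, mixed linearly::

    x2 = AC + MA + drift2 + noise2          (infrared)
    x1 = a*AC + c*MA + drift1 + noise1      (red)

with amplitude ratios a = AC_R/AC_IR and c = MA_R/MA_IR.  The artifact
is a band-limited (0.5-5 Hz) Gaussian process plus a randomized
swing-frequency sinusoid, active only inside scheduled motion bursts, so
it spectrally overlaps the cardiac band -- the regime a purely
frequency-selective filter cannot handle.  The generator also emulates
the experimental protocol used for validation: repeated cycles of a
10 s stationary rest followed by 16 s of arm swinging.

All randomness flows from a single master seed through spawned
``numpy.random.SeedSequence`` streams, so identical (config, seed) pairs
produce byte-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import DomainError, EmptyInputError, ShapeError

__all__ = [
    "GroundTruth",
    "DualChannelRecording",
    "ScenarioConfig",
    "make_hr_trace",
    "make_pulse_waveform",
    "make_motion_artifact",
    "synthesize_recording",
    "protocol_swing",
    "canonical_frame",
]

BPM_MIN = 40.0
BPM_MAX = 180.0


@dataclass
class GroundTruth:
    """Clean components underlying a simulated recording.

    ``resid1``/``resid2`` hold the exact drift+noise added to each
    channel, so ``x2 - ac_ir - ma_ir - resid2 == 0`` identically.
    """

    ac_ir: np.ndarray
    ma_ir: np.ndarray
    hr_trace: Optional[np.ndarray] = None
    a: Optional[float] = None
    c_true: Optional[float] = None
    resid1: Optional[np.ndarray] = None
    resid2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ac_ir = np.asarray(self.ac_ir, dtype=float)
        self.ma_ir = np.asarray(self.ma_ir, dtype=float)
        if self.ma_ir.shape != self.ac_ir.shape:
            raise ShapeError("ac_ir and ma_ir must have equal length")
        if self.hr_trace is not None:
            self.hr_trace = np.asarray(self.hr_trace, dtype=float)
            if self.hr_trace.shape != self.ac_ir.shape:
                raise ShapeError("hr_trace length must match ac_ir")
            _check_bpm(self.hr_trace)
        if self.a is not None and not self.a > 0:
            raise DomainError(f"amplitude ratio a must be > 0, got {self.a}")


@dataclass
class DualChannelRecording:
    """Synchronously sampled red (x1) / infrared (x2) pair."""

    x1: np.ndarray
    x2: np.ndarray
    fs: float
    labels: Optional[np.ndarray] = None  # per-sample 'rest'/'swing'
    truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape:
            raise ShapeError("x1 and x2 must have equal length")
        if not self.fs > 0:
            raise DomainError(f"fs must be > 0, got {self.fs}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.x1.shape:
                raise ShapeError("labels length must match signals")

    @property
    def n_samples(self) -> int:
        return self.x1.size

    @property
    def duration_s(self) -> float:
        return self.x1.size / self.fs


@dataclass
class ScenarioConfig:
    """Parameters of the rest/swing acquisition protocol.

    Defaults emulate the validation protocol: 3 cycles of 10 s rest +
    16 s arm swing (78 s total) at 1000 Hz, heart rate 75 bpm with a
    slow +/-3 bpm drift, artifact dominating the infrared AC during
    swings (ma_amplitude ~ 3.6x the AC standard deviation).
    """

    fs: float = 1000.0
    rest_s: float = 10.0
    swing_s: float = 16.0
    cycles: int = 3
    hr_base_bpm: float = 75.0
    hr_drift_bpm: float = 3.0
    hr_drift_period_s: float = 60.0
    a: float = 0.5
    c_true: float = 2.0
    ma_amplitude: float = 2.0
    ma_band_hz: tuple = (0.5, 5.0)
    swing_freq_band_hz: tuple = (0.8, 2.0)
    drift_amp: float = 0.2
    drift_max_hz: float = 0.2
    noise_sd: float = 0.05
    ac_morphology: tuple = (1.0, 0.4, 0.2)

    @property
    def duration_s(self) -> float:
        return self.cycles * (self.rest_s + self.swing_s)


def _check_bpm(hr: np.ndarray) -> None:
    if hr.size and (np.min(hr) < BPM_MIN or np.max(hr) > BPM_MAX):
        raise DomainError(
            f"heart rate must lie in [{BPM_MIN:g}, {BPM_MAX:g}] bpm, "
            f"got range [{np.min(hr):g}, {np.max(hr):g}]"
        )


def make_hr_trace(
    bpm: float,
    duration_s: float,
    fs: float,
    drift_bpm: float = 0.0,
    drift_period_s: float = 60.0,
    drift_phase: float = 0.0,
) -> np.ndarray:
    """Per-sample instantaneous heart rate: constant plus a slow sinusoidal
    drift.  ``duration_s == 0`` yields an empty trace."""
    if not fs > 0:
        raise DomainError("fs must be > 0")
    n = int(round(duration_s * fs))
    if n == 0:
        return np.zeros(0)
    t = np.arange(n) / fs
    hr = bpm + drift_bpm * np.sin(2 * np.pi * t / drift_period_s + drift_phase)
    _check_bpm(hr)
    return hr


def make_pulse_waveform(
    hr_trace: np.ndarray,
    fs: float,
    morphology: Sequence[float] = (1.0, 0.4, 0.2),
) -> np.ndarray:
    """Quasi-periodic arterial waveform with instantaneous fundamental
    frequency hr_trace/60.

    The pulse is a sum of harmonics with decaying amplitudes driven by a
    phase integrator, giving a well-defined periodicity and a single
    dominant peak per beat.  Output is zero-mean with unit peak amplitude.
    """
    hr = np.asarray(hr_trace, dtype=float)
    if hr.size == 0:
        raise EmptyInputError("hr_trace is empty")
    if not fs > 0:
        raise DomainError("fs must be > 0")
    _check_bpm(hr)
    phase = 2 * np.pi * np.cumsum(hr / 60.0) / fs
    x = np.zeros_like(phase)
    for k, amp in enumerate(morphology, start=1):
        x += amp * np.sin(k * phase)
    x -= x.mean()
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    return x


def _ma_sos(band: tuple, fs: float):
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise DomainError(f"band must satisfy 0 < lo < hi < fs/2, got {band}")
    return butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def make_motion_artifact(
    duration_s: float,
    fs: float,
    band: tuple = (0.5, 5.0),
    burst_schedule: Optional[Sequence[tuple]] = None,
    amplitude: float = 1.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    swing_freq_band: tuple = (0.8, 2.0),
    swing_amp: float = 1.0,
    taper_s: float = 0.5,
) -> np.ndarray:
    """Band-limited stochastic motion artifact, active only inside bursts.

    Model: zero-phase 4th-order Butterworth band-pass filtered white
    Gaussian noise plus one sinusoid per burst at a randomized swing
    frequency (amplitude ``swing_amp`` relative to the unit-variance
    noise; 0 gives a purely broadband artifact), windowed to zero
    outside the bursts with cosine tapers at the burst edges.
    ``amplitude`` sets the standard deviation over the taper-free burst
    interior.
    """
    if not fs > 0:
        raise DomainError("fs must be > 0")
    sos = _ma_sos(band, fs)
    n = int(round(duration_s * fs))
    if n == 0:
        return np.zeros(0)
    if burst_schedule is None:
        burst_schedule = [(0.0, duration_s)]
    for start, stop in burst_schedule:
        if not (0.0 <= start < stop <= duration_s + 1e-9):
            raise DomainError(f"burst ({start}, {stop}) outside [0, {duration_s}]")
    if amplitude == 0:
        return np.zeros(n)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    noise = sosfiltfilt(sos, rng.standard_normal(n))
    noise /= max(noise.std(), np.finfo(float).tiny)

    t = np.arange(n) / fs
    swing = np.zeros(n)
    envelope = np.zeros(n)
    interior = np.zeros(n, dtype=bool)
    for start, stop in burst_schedule:
        i0, i1 = int(round(start * fs)), min(int(round(stop * fs)), n)
        if i1 <= i0:
            continue
        f_sw = rng.uniform(*swing_freq_band)
        ph = rng.uniform(0, 2 * np.pi)
        swing[i0:i1] += swing_amp * np.sin(2 * np.pi * f_sw * t[i0:i1] + ph)
        m = i1 - i0
        n_taper = min(int(round(taper_s * fs)), m // 4)
        win = np.ones(m)
        if n_taper > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
            win[:n_taper] = ramp
            win[-n_taper:] = ramp[::-1]
        envelope[i0:i1] = np.maximum(envelope[i0:i1], win)
        interior[i0 + n_taper : i1 - n_taper if n_taper else i1] = True

    ma = (noise + swing) * envelope
    ref = ma[interior] if interior.any() else ma[envelope > 0]
    sd = ref.std()
    if sd > 0:
        ma *= amplitude / sd
    return ma


def synthesize_recording(
    ac_ir: np.ndarray,
    ma_ir: np.ndarray,
    a: float,
    c_true: float,
    drift_amp: float = 0.2,
    noise_sd: float = 0.05,
    fs: float = 1000.0,
    seed: int | np.random.SeedSequence = 0,
    hr_trace: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
    drift_max_hz: float = 0.2,
) -> DualChannelRecording:
    """Mix clean components into a two-channel recording with ground truth.

    x2 = ac_ir + ma_ir + drift2 + noise2 and x1 = a*ac_ir + c_true*ma_ir
    + drift1 + noise1, with independently seeded per-channel drift and
    white noise.  The exact residuals are stored in the attached
    GroundTruth so the mixing identity is checkable to the last bit.
    """
    ac = np.asarray(ac_ir, dtype=float)
    ma = np.asarray(ma_ir, dtype=float)
    if ac.shape != ma.shape:
        raise ShapeError("ac_ir and ma_ir must have equal length")
    if not a > 0:
        raise DomainError(f"a must be > 0, got {a}")
    n = ac.size
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    sub = ss.spawn(3)
    rng_drift = np.random.default_rng(sub[0])
    t = np.arange(n) / fs

    def _drift(rng):
        if drift_amp == 0 or n == 0:
            return np.zeros(n)
        f = rng.uniform(0.25 * drift_max_hz, drift_max_hz)
        ph = rng.uniform(0, 2 * np.pi)
        return drift_amp * np.sin(2 * np.pi * f * t + ph)

    drift1 = _drift(rng_drift)
    drift2 = _drift(rng_drift)
    noise1 = noise_sd * np.random.default_rng(sub[1]).standard_normal(n)
    noise2 = noise_sd * np.random.default_rng(sub[2]).standard_normal(n)
    resid1 = drift1 + noise1
    resid2 = drift2 + noise2
    truth = GroundTruth(
        ac_ir=ac, ma_ir=ma, hr_trace=hr_trace, a=a, c_true=c_true,
        resid1=resid1, resid2=resid2,
    )
    x1 = a * ac + c_true * ma + resid1
    x2 = ac + ma + resid2
    return DualChannelRecording(x1=x1, x2=x2, fs=fs, labels=labels, truth=truth)


def swing_intervals(config: ScenarioConfig) -> list[tuple]:
    """(start, stop) seconds of the swing segments of the protocol."""
    out = []
    cycle = config.rest_s + config.swing_s
    for k in range(config.cycles):
        start = k * cycle + config.rest_s
        out.append((start, start + config.swing_s))
    return out


def protocol_swing(
    config: Optional[ScenarioConfig] = None,
    seed: int = 0,
) -> DualChannelRecording:
    """Simulate one rest/swing protocol session with ground truth.

    Alternates rest (artifact-free) and swing (artifact-contaminated)
    segments per the scenario config and labels every sample.
    """
    cfg = config or ScenarioConfig()
    fs = cfg.fs
    duration = cfg.duration_s
    n = int(round(duration * fs))
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(3)

    rng_hr = np.random.default_rng(sub[0])
    hr = make_hr_trace(
        cfg.hr_base_bpm, duration, fs,
        drift_bpm=cfg.hr_drift_bpm,
        drift_period_s=cfg.hr_drift_period_s,
        drift_phase=rng_hr.uniform(0, 2 * np.pi),
    )
    ac = make_pulse_waveform(hr, fs, cfg.ac_morphology)

    bursts = swing_intervals(cfg)
    ma = make_motion_artifact(
        duration, fs, band=cfg.ma_band_hz, burst_schedule=bursts,
        amplitude=cfg.ma_amplitude, seed=np.random.default_rng(sub[1]),
        swing_freq_band=cfg.swing_freq_band_hz,
    )

    labels = np.full(n, "rest", dtype="<U5")
    for start, stop in bursts:
        labels[int(round(start * fs)) : int(round(stop * fs))] = "swing"

    return synthesize_recording(
        ac, ma, a=cfg.a, c_true=cfg.c_true,
        drift_amp=cfg.drift_amp, noise_sd=cfg.noise_sd, fs=fs,
        seed=sub[2], hr_trace=hr, labels=labels,
        drift_max_hz=cfg.drift_max_hz,
    )


def canonical_frame(
    seed: int = 0,
    duration_s: float = 8.0,
    fs: float = 1000.0,
    a: float = 0.5,
    c_true: float = 2.0,
    ma_amplitude: float = 0.15,
    noise_sd: float = 0.01,
) -> DualChannelRecording:
    """One fully contaminated frame in the canonical mixing setting used
    throughout the estimation test batteries: periodic AC (heart rate
    drawn uniformly in 60-90 bpm), purely broadband band-limited MA over
    the whole frame (no swing sinusoid), no baseline drift, high-SNR
    channel noise."""
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(3)
    bpm = float(np.random.default_rng(sub[0]).uniform(60.0, 90.0))
    hr = make_hr_trace(bpm, duration_s, fs)
    ac = make_pulse_waveform(hr, fs)
    ma = make_motion_artifact(
        duration_s, fs, amplitude=ma_amplitude,
        seed=np.random.default_rng(sub[1]), swing_amp=0.0,
    )
    return synthesize_recording(
        ac, ma, a=a, c_true=c_true, drift_amp=0.0, noise_sd=noise_sd,
        fs=fs, seed=sub[2], hr_trace=hr,
    )
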