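"""Normalization, Butterworth band-pass conditioning, and framing.

Order of operations follows the acquisition pipeline: each channel is
first normalized to [-1, 1] over the whole recording, then conditioned
with a 4th-order Butterworth band-pass (0.5-5 Hz at 1000 Hz by default)
that removes baseline drift and out-of-band noise while keeping the
cardiac band intact.  The conditioned recording is then cut into
consecutive non-overlapping frames (8 s default) which every downstream
stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from scipy.signal import butter, sosfilt, sosfiltfilt

from .errors import DegenerateSignalError, DomainError, ShapeError
from .synthwave import DualChannelRecording

__all__ = [
    "Frame",
    "normalize_unit_range",
    "bandpass",
    "bandpass_sos",
    "frame_stream",
    "preprocess_recording",
]

MIN_FRAME_S = 4.0  # shortest usable frame: keeps the period lag estimable


@dataclass
class Frame:
    """A per-frame view of both channels."""

    index: int
    start: int  # sample offset, 0-based
    x1: np.ndarray
    x2: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.x1.shape != self.x2.shape:
            raise ShapeError("frame channels must have equal length")

    @property
    def n_samples(self) -> int:
        return self.x1.size


def normalize_unit_range(signal: np.ndarray) -> np.ndarray:
    """Affine map of the signal onto [-1, +1] (min -> -1, max -> +1)."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ShapeError("normalization needs at least 2 samples")
    lo, hi = np.min(x), np.max(x)
    if not hi > lo:
        raise DegenerateSignalError("constant signal has no range to normalize")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def bandpass_sos(fs: float, lo: float = 0.5, hi: float = 5.0, order: int = 4):
    """Second-order sections of the band-pass filter.

    ``order`` counts the analog Butterworth prototype order; the digital
    band-pass therefore has 2*order poles.
    """
    if not (0 < lo < hi < fs / 2):
        raise DomainError(
            f"band must satisfy 0 < lo < hi < fs/2, got ({lo}, {hi}) at fs={fs}"
        )
    return butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(
    signal: np.ndarray,
    fs: float,
    lo: float = 0.5,
    hi: float = 5.0,
    order: int = 4,
    zero_phase: bool = False,
) -> np.ndarray:
    """Band-pass filter a signal.

    Causal (streaming-compatible) by default; ``zero_phase=True`` runs
    the filter forward-backward instead.  The causal path warm-starts
    the filter over an odd-reflected pre-extension (discarded from the
    output) so the slow low-cut pole does not ring through the first
    seconds of the recording; steady-state behavior is unchanged.
    """
    sos = bandpass_sos(fs, lo, hi, order)
    x = np.asarray(signal, dtype=float)
    if zero_phase:
        return sosfiltfilt(sos, x)
    n_pad = min(int(round(3.0 / lo * fs)), max(x.size - 1, 0))
    if n_pad == 0:
        return sosfilt(sos, x)
    pad = 2.0 * x[0] - x[n_pad:0:-1]
    return sosfilt(sos, np.concatenate([pad, x]))[n_pad:]


def frame_stream(
    recording: DualChannelRecording,
    frame_len_s: float = 8.0,
    hop_s: Optional[float] = None,
    min_partial_s: float = MIN_FRAME_S,
) -> Iterator[Frame]:
    """Cut a recording into consecutive frames.

    Frames tile the recording without overlap (hop defaults to the frame
    length).  A final partial frame is emitted iff it is at least
    ``min_partial_s`` long, otherwise it is dropped.
    """
    fs = recording.fs
    n = recording.n_samples
    if n < int(round(MIN_FRAME_S * fs)):
        raise ShapeError(
            f"recording of {n / fs:g} s is shorter than the minimum frame "
            f"length ({MIN_FRAME_S:g} s)"
        )
    flen = int(round(frame_len_s * fs))
    hop = int(round((hop_s if hop_s is not None else frame_len_s) * fs))
    if flen <= 0 or hop <= 0:
        raise DomainError("frame length and hop must be positive")
    min_partial = int(round(min_partial_s * fs))
    index = 0
    start = 0
    while start < n:
        stop = min(start + flen, n)
        if stop - start < flen and stop - start < min_partial:
            break
        yield Frame(
            index=index, start=start,
            x1=recording.x1[start:stop], x2=recording.x2[start:stop],
            fs=fs,
        )
        index += 1
        start += hop


def preprocess_recording(
    recording: DualChannelRecording,
    lo: float = 0.5,
    hi: float = 5.0,
    order: int = 4,
    zero_phase: bool = False,
) -> DualChannelRecording:
    """Normalize both channels to [-1, 1], then band-pass them.

    Returns a new recording; labels and ground truth are carried over
    untouched (truth components stay on the raw amplitude scale).
    """
    x1 = bandpass(normalize_unit_range(recording.x1), recording.fs, lo, hi,
                  order, zero_phase)
    x2 = bandpass(normalize_unit_range(recording.x2), recording.fs, lo, hi,
                  order, zero_phase)
    return DualChannelRecording(
        x1=x1, x2=x2, fs=recording.fs,
        labels=recording.labels, truth=recording.truth,
    )
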