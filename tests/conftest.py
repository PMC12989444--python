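"""Shared fixtures.

Heavy seeded batteries (canonical estimation frames, end-to-end protocol
runs) are built once per session and shared across the tests that
consume them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from ppgdenoise import canonical_frame, denoise_recording, protocol_swing
from ppgdenoise.bss import estimate_frame
from ppgdenoise.hrmetrics import (
    detect_peaks,
    hr_reference_series,
    hr_series,
    mae,
    paired_valid,
)
from ppgdenoise.preprocess import preprocess_recording

N_CANONICAL = 100
N_PROTOCOL = 20


@dataclass
class CanonicalCase:
    seed: int
    recording: object
    estimate: object
    reference: object


@pytest.fixture(scope="session")
def canonical_battery():
    """100 seeded canonical frames with their per-frame BSS results."""
    cases = []
    for seed in range(N_CANONICAL):
        rec = canonical_frame(seed=seed)
        est, ref = estimate_frame(rec.x1, rec.x2, rec.fs)
        cases.append(CanonicalCase(seed, rec, est, ref))
    return cases


@dataclass
class ProtocolRun:
    seed: int
    recording: object
    result: object
    clean_mae: float
    raw_mae: float


@pytest.fixture(scope="session")
def protocol_battery():
    """20 seeded protocol recordings run through the full pipeline, with
    windowed HR agreement for the cleaned and raw signals."""
    runs = []
    for seed in range(N_PROTOCOL):
        rec = protocol_swing(seed=seed)
        fs = rec.fs
        result = denoise_recording(rec)
        ref = hr_reference_series(rec.truth.hr_trace, fs, 8.0)

        cleaned = result.cleaned
        est = hr_series(detect_peaks(cleaned, fs), fs, 8.0, cleaned.size / fs)
        e, r = paired_valid(est, ref)
        clean_mae = mae(e, r)

        raw = preprocess_recording(rec).x2
        est_raw = hr_series(detect_peaks(raw, fs), fs, 8.0, raw.size / fs)
        e2, r2 = paired_valid(est_raw, ref)
        raw_mae = mae(e2, r2)

        runs.append(ProtocolRun(seed, rec, result, clean_mae, raw_mae))
    return runs
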