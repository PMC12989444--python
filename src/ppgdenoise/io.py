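"""On-disk formats: recordings, cleaned signals, diagnostics, reports.

Everything is plain text.  Recordings are CSV with header
``t,x1,x2[,label][,ac_ir,ma_ir,hr]`` (times in seconds, 0-based sample
indexing, decimal point, no locale handling); cleaned signals are CSV
``t,e``; per-frame diagnostics are JSON-lines; agreement reports are
JSON.  Floats are written with 17 significant digits and re-read with
round-trip parsing, so a write/read cycle reproduces values exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError
from .hrmetrics import AgreementReport
from .synthwave import DualChannelRecording, GroundTruth

__all__ = [
    "read_recording",
    "write_recording",
    "read_cleaned",
    "write_cleaned",
    "write_diagnostics",
    "write_results",
    "write_report",
    "read_report",
    "read_beats",
]

log = logging.getLogger(__name__)

_REL_TOL = 1e-6  # allowed relative deviation of the sample spacing


def _infer_fs(t: np.ndarray, path) -> float:
    if t.size < 2:
        raise SamplingError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0:
        raise SamplingError(f"{path}: non-increasing time column")
    if np.max(np.abs(dt - dt0)) > _REL_TOL * dt0:
        raise SamplingError(
            f"{path}: time column is not uniformly sampled "
            f"(max deviation {np.max(np.abs(dt - dt0)) / dt0:.3g} relative)"
        )
    return float((t.size - 1) / (t[-1] - t[0]))


def read_recording(path: str | Path) -> DualChannelRecording:
    """Read a two-channel recording CSV; fs is inferred from the time
    column, which must be uniform within 1e-6 relative."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t", "x1", "x2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    t = df["t"].to_numpy(dtype=float)
    fs = _infer_fs(t, path)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    truth = None
    if {"ac_ir", "ma_ir"} <= set(df.columns):
        hr = df["hr"].to_numpy(dtype=float) if "hr" in df.columns else None
        truth = GroundTruth(
            ac_ir=df["ac_ir"].to_numpy(dtype=float),
            ma_ir=df["ma_ir"].to_numpy(dtype=float),
            hr_trace=hr,
        )
    return DualChannelRecording(
        x1=df["x1"].to_numpy(dtype=float), x2=df["x2"].to_numpy(dtype=float),
        fs=fs, labels=labels, truth=truth,
    )


def write_recording(
    recording: DualChannelRecording,
    path: str | Path,
    include_truth: bool = True,
) -> None:
    """Write a recording as CSV (optionally with truth columns)."""
    n = recording.n_samples
    data = {
        "t": np.arange(n) / recording.fs,
        "x1": recording.x1,
        "x2": recording.x2,
    }
    if recording.labels is not None:
        data["label"] = recording.labels
    tr = recording.truth
    if include_truth and tr is not None:
        data["ac_ir"] = tr.ac_ir
        data["ma_ir"] = tr.ma_ir
        if tr.hr_trace is not None:
            data["hr"] = tr.hr_trace
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_cleaned(cleaned: np.ndarray, fs: float, path: str | Path) -> None:
    pd.DataFrame(
        {"t": np.arange(len(cleaned)) / fs, "e": cleaned}
    ).to_csv(path, index=False, float_format="%.17g")


def read_cleaned(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t", "e"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    t = df["t"].to_numpy(dtype=float)
    return df["e"].to_numpy(dtype=float), _infer_fs(t, path)


def _jsonable(value):
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return None if not math.isfinite(v) else v
    if isinstance(value, (np.integer, int)):
        return int(value)
    if isinstance(value, (tuple, list)):
        return [_jsonable(v) for v in value]
    return value


def write_diagnostics(frames: Iterable, path: str | Path) -> None:
    """Per-frame diagnostics as JSON-lines (one object per frame)."""
    frames = list(frames)
    if not frames:
        log.warning("writing empty diagnostics file: no frames")
    with open(path, "w") as fh:
        for fr in frames:
            rec = {
                "frame": fr.index,
                "start": fr.start,
                "Ta": fr.Ta,
                "c": fr.bss.c,
                "b": fr.bss.b,
                "alpha": fr.bss.alpha,
                "beta": fr.beta,
                "H": fr.H,
                "mode": fr.mode,
                "mu_star": fr.mu_star,
                "N_star": fr.N_star,
                "He": fr.He,
                "n_iter": fr.bss.n_iter,
                "converged": fr.bss.converged,
                "flags": list(fr.flags),
            }
            fh.write(json.dumps({k: _jsonable(v) for k, v in rec.items()}) + "\n")


def write_results(
    frames: Iterable,
    fs: float,
    cleaned_path: str | Path,
    diag_path: str | Path,
    report: "AgreementReport | None" = None,
    report_path: "str | Path | None" = None,
) -> None:
    """Write a pipeline run's outputs: cleaned CSV, diagnostics
    JSON-lines, and (optionally) the agreement report JSON."""
    frames = list(frames)
    cleaned = (
        np.concatenate([fr.e_seq for fr in frames]) if frames else np.zeros(0)
    )
    write_cleaned(cleaned, fs, cleaned_path)
    write_diagnostics(frames, diag_path)
    if report is not None and report_path is not None:
        write_report(report, report_path)


def write_report(report: AgreementReport, path: str | Path) -> None:
    payload = {k: _jsonable(v) for k, v in dataclasses.asdict(report).items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: str | Path) -> AgreementReport:
    return AgreementReport(**json.loads(Path(path).read_text()))


def read_beats(path: str | Path) -> np.ndarray:
    """Reference beat times in seconds from a CSV with a 'beat_s' column."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "beat_s" not in df.columns:
        raise FormatError(f"{path}: missing required column 'beat_s'")
    beats = df["beat_s"].to_numpy(dtype=float)
    if np.any(np.diff(beats) <= 0):
        raise FormatError(f"{path}: beat times must be strictly increasing")
    return beats
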