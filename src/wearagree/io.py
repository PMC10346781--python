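"""CSV/JSON readers and writers.

Signals travel as plain CSV with '#'-prefixed metadata header lines
(subject, session, device, modality, fs, units) followed by
``time_s,value`` rows — UTF-8, comma separator, '.' decimal. Ground truth
travels as a JSON sidecar. Malformed files are rejected with line-numbered
messages rather than silently coerced.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GroundTruth, RawSignal


class SignalFormatError(ValueError):
    """Malformed signal CSV, with the offending line number in the message."""


def write_signal_csv(sig: RawSignal, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject: {sig.subject}\n")
        fh.write(f"# session: {sig.session}\n")
        fh.write(f"# device: {sig.device}\n")
        fh.write(f"# modality: {sig.modality}\n")
        fh.write(f"# fs: {float(sig.fs)!r}\n")
        fh.write(f"# units: {sig.units}\n")
        fh.write("time_s,value\n")
        t = sig.time_s
        for ti, vi in zip(t, sig.values):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_signal_csv(path) -> RawSignal:
    """Parse a signal CSV; full-precision round trip with write_signal_csv."""
    path = Path(path)
    meta: dict = {}
    times, values = [], []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise SignalFormatError(
                        f"{path}:{lineno}: malformed metadata line {line!r}")
                key, _, val = line.lstrip("#").partition(":")
                meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "time_s,value":
                    raise SignalFormatError(
                        f"{path}:{lineno}: expected header 'time_s,value', got {line!r}")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SignalFormatError(
                    f"{path}:{lineno}: expected two comma-separated fields")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise SignalFormatError(f"{path}:{lineno}: {exc}") from None
    if "fs" not in meta:
        raise SignalFormatError(f"{path}: missing required 'fs' metadata line")
    t = np.asarray(times)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise SignalFormatError(f"{path}: time column is not strictly increasing")
    return RawSignal(
        values=np.asarray(values),
        fs=float(meta["fs"]),
        units=meta.get("units", "au"),
        modality=meta.get("modality", "ppg"),
        device=meta.get("device", ""),
        subject=meta.get("subject", ""),
        session=int(meta.get("session", 0) or 0),
    )


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "beat_times_s": truth.beat_times_s.tolist(),
        "true_hr_per_window_bpm": np.asarray(truth.true_hr_per_window_bpm,
                                             dtype=float).tolist(),
        "scr_event_times_s": truth.scr_event_times_s.tolist(),
        "true_scl_per_window_us": np.asarray(truth.true_scl_per_window_us,
                                             dtype=float).tolist(),
        "artifact_intervals_s": [list(iv) for iv in truth.artifact_intervals_s],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return GroundTruth(
        beat_times_s=np.asarray(payload["beat_times_s"]),
        true_hr_per_window_bpm=np.asarray(payload["true_hr_per_window_bpm"]),
        scr_event_times_s=np.asarray(payload["scr_event_times_s"]),
        true_scl_per_window_us=np.asarray(payload["true_scl_per_window_us"]),
        artifact_intervals_s=[tuple(iv) for iv in payload["artifact_intervals_s"]],
    )


FEATURE_COLUMNS = ["subject", "session", "device", "window_index",
                   "hr_bpm", "scl_us", "n_responses"]


def write_features_csv(features: pd.DataFrame, path) -> None:
    """Write the long-format feature table with a stable column order."""
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    features.loc[:, cols].to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_atomic(obj, path) -> None:
    """Write JSON to a temp file then rename, so readers never see partials."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
    os.replace(tmp, path)
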