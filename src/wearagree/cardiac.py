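"""Beat detection, inter-beat intervals and 30-s heart-rate features.

A Pan-Tompkins-style detector (derivative, squaring, 0.15-s moving-window
integration, adaptive dual thresholds with a 0.25-s refractory period) is
run on the conditioned pulse wave; beats inside artefactual 2-s windows are
discarded, intervals spanning an artefactual gap or outside the
physiological 0.25-2.0 s band (30-240 bpm) are marked invalid, and HR is
the mean of 60/IBI over valid intervals per 30-s window, matching the
consumer device's output cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RawSignal, WINDOW_S, window_slices
from .ppg import ArtifactMask

IBI_MIN_S = 0.25   # 240 bpm ceiling
IBI_MAX_S = 2.0    # 30 bpm floor: at least one beat per 2-s window
REFRACTORY_S = 0.25
INTEGRATION_WIN_S = 0.15


@dataclass
class BeatSeries:
    """Detected beat times (s) with the 2-s window each beat fell in."""

    beat_times_s: np.ndarray
    source_window: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.source_window = np.asarray(self.source_window, dtype=int)
        if self.beat_times_s.size > 1 and not np.all(np.diff(self.beat_times_s) > 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.beat_times_s.size


@dataclass
class IbiSeries:
    """Consecutive inter-beat intervals with validity flags.

    ``start_times_s[i]`` is the time of the first beat of interval ``i``;
    the interval midpoint used for window assignment is
    ``start_times_s + ibi_s / 2``.
    """

    ibi_s: np.ndarray
    start_times_s: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.ibi_s = np.asarray(self.ibi_s, dtype=float)
        self.start_times_s = np.asarray(self.start_times_s, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.start_times_s + self.ibi_s / 2


def _parabolic_refine(values: np.ndarray, k: int) -> float:
    """Sub-sample apex position via a parabola through (k-1, k, k+1)."""
    if k <= 0 or k >= values.size - 1:
        return float(k)
    y0, y1, y2 = values[k - 1], values[k], values[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(k)
    return k + 0.5 * (y0 - y2) / denom


def _detect_segment(v: np.ndarray, fs: float) -> list[float]:
    """Pan-Tompkins core on one contiguous clean segment; times in seconds."""
    if v.size < int(fs):
        return []
    deriv = np.diff(v) * fs
    sq = deriv ** 2
    k = max(int(round(INTEGRATION_WIN_S * fs)), 1)
    integ = np.convolve(sq, np.ones(k) / k, mode="same")

    from scipy.signal import find_peaks

    min_dist = max(int(REFRACTORY_S * fs), 1)
    peaks, _ = find_peaks(integ, distance=min_dist)
    if peaks.size == 0:
        return []

    # adaptive dual-threshold initialisation from the first 2 s
    lead = integ[: int(2 * fs)]
    spki = float(np.max(lead)) if lead.size else float(np.max(integ))
    npki = float(np.mean(lead)) * 0.5 if lead.size else 0.0

    accepted = []
    for p in peaks:
        thr = npki + 0.25 * (spki - npki)
        if integ[p] > thr:
            accepted.append(p)
            spki = 0.125 * integ[p] + 0.875 * spki
        else:
            npki = 0.125 * integ[p] + 0.875 * npki

    # refine to the pulse apex in the conditioned signal
    half = int(round(0.2 * fs))
    times = []
    for p in accepted:
        i0, i1 = max(p - half, 0), min(p + half + 1, v.size)
        kk = i0 + int(np.argmax(v[i0:i1]))
        times.append(_parabolic_refine(v, kk) / fs)
    return times


def detect_beats(sig: RawSignal, mask: ArtifactMask | None = None) -> BeatSeries:
    """Pan-Tompkins beat detection applied only to non-artefactual portions.

    The band-pass stage is the already-applied 1-15 Hz filter. The signal
    is split at artefactual windows and the detector — derivative,
    squaring, 0.15-s moving-window integration, adaptive dual thresholds
    (running signal/noise peak estimates with 1/8 update weight), 0.25-s
    refractory — runs independently on each contiguous clean segment, so a
    rejected spike can never inflate the adaptive threshold of clean data.
    Accepted candidates are refined to the pulse apex with sub-sample
    parabolic interpolation. An all-artifact signal yields an empty series,
    not an error.
    """
    fs = sig.fs
    v = sig.values

    # contiguous clean segments in samples
    if mask is None:
        segments = [(0, v.size)]
    else:
        segments = []
        run_start = None
        for w, r in zip(mask.windows, mask.reasons):
            if r:
                if run_start is not None:
                    segments.append((run_start, w.start))
                    run_start = None
            else:
                if run_start is None:
                    run_start = w.start
        if run_start is not None:
            segments.append((run_start, min(mask.windows[-1].stop, v.size)))

    beat_times: list[float] = []
    for s0, s1 in segments:
        beat_times.extend(s0 / fs + t for t in _detect_segment(v[s0:s1], fs))
    beat_times = np.array(sorted(set(beat_times)))

    # enforce refractory period on the pooled, refined times
    if beat_times.size:
        kept = [beat_times[0]]
        for t in beat_times[1:]:
            if t - kept[-1] >= REFRACTORY_S:
                kept.append(t)
        beat_times = np.array(kept)

    win_len = (mask.windows[0].stop - mask.windows[0].start
               if mask is not None and mask.windows else int(2 * fs))
    source = (beat_times * fs / win_len).astype(int) if beat_times.size else \
        np.empty(0, dtype=int)
    return BeatSeries(beat_times, source)


def compute_ibi(beats: BeatSeries, mask: ArtifactMask | None = None) -> IbiSeries:
    """Consecutive beat-to-beat intervals with validity flags.

    An interval is invalid if it lies outside the physiological 0.25-2.0 s
    band or if its span intersects any artefactual window (the beat pair
    then brackets removed signal, so the difference is not a true IBI).
    Fewer than two beats yield an empty series.
    """
    t = beats.beat_times_s
    if t.size < 2:
        e = np.empty(0)
        return IbiSeries(e, e.copy(), np.empty(0, dtype=bool))
    ibi = np.diff(t)
    start = t[:-1]
    valid = (ibi >= IBI_MIN_S) & (ibi <= IBI_MAX_S)
    if mask is not None:
        art_spans = [
            (w.start / mask.fs, w.stop / mask.fs)
            for w, r in zip(mask.windows, mask.reasons) if r
        ]
        for a0, a1 in art_spans:
            overlap = (start < a1) & (start + ibi > a0)
            valid &= ~overlap
    return IbiSeries(ibi, start, valid)


def compute_hr_windows(ibi: IbiSeries, duration_s: float,
                       window_s: float = WINDOW_S) -> pd.DataFrame:
    """Mean 60/IBI over valid intervals per 30-s window.

    Intervals are assigned to the window containing their midpoint. Windows
    with no valid interval get NaN and ``n_valid`` 0 — missing, never
    silently dropped.
    """
    wins = window_slices(duration_s, window_s)
    mids = ibi.midpoints_s
    rows = []
    for i, (t0, t1) in enumerate(wins):
        sel = ibi.valid & (mids >= t0) & (mids < t1)
        n_valid = int(sel.sum())
        hr = float(np.mean(60.0 / ibi.ibi_s[sel])) if n_valid else np.nan
        rows.append({"window_index": i + 1, "hr_bpm": hr, "n_valid": n_valid})
    return pd.DataFrame(rows)


def hr_from_signal(sig: RawSignal, mask: ArtifactMask,
                   window_s: float = WINDOW_S) -> pd.DataFrame:
    """Convenience: beats -> IBI -> windowed HR for one conditioned signal."""
    beats = detect_beats(sig, mask)
    ibi = compute_ibi(beats, mask)
    return compute_hr_windows(ibi, duration_s=sig.duration_s, window_s=window_s)
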