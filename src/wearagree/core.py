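"""Core containers shared across the pipeline.

The pipeline passes around uniformly sampled physiological traces
(:class:`RawSignal`) plus a per-recording ground-truth channel
(:class:`GroundTruth`) when the data came from the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

WINDOW_S = 30.0  # output cadence of the aggregated consumer device


class ConfigurationError(ValueError):
    """Raised when a signal/config combination is physically invalid."""


@dataclass
class RawSignal:
    """A uniformly sampled physiological trace.

    Parameters
    ----------
    values : ndarray
        Sample values in ``units``.
    fs : float
        Sampling rate in samples/s.
    units : str
        Physical units, e.g. ``"au"`` for blood-volume pulse or ``"uS"``.
    modality : str
        ``"ppg"`` or ``"eda"``.
    device, subject, session
        Provenance labels carried through the pipeline.
    """

    values: np.ndarray
    fs: float
    units: str = "au"
    modality: str = "ppg"
    device: str = ""
    subject: str = ""
    session: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1:
            raise ConfigurationError("signal values must be one-dimensional")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def copy_with(self, **kwargs) -> "RawSignal":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Truth channel emitted by the simulator and carried past device models.

    ``artifact_intervals_s`` accumulates every injected corruption as
    ``(start_s, end_s, kind)`` so recovery tests can score detectors against
    what was actually injected.
    """

    beat_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_hr_per_window_bpm: np.ndarray = field(default_factory=lambda: np.empty(0))
    scr_event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_scl_per_window_us: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_intervals_s: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.scr_event_times_s = np.asarray(self.scr_event_times_s, dtype=float)
        if self.beat_times_s.size > 1 and not np.all(np.diff(self.beat_times_s) > 0):
            raise ValueError("beat times must be strictly increasing")

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            beat_times_s=self.beat_times_s.copy(),
            true_hr_per_window_bpm=np.array(self.true_hr_per_window_bpm, dtype=float),
            scr_event_times_s=self.scr_event_times_s.copy(),
            true_scl_per_window_us=np.array(self.true_scl_per_window_us, dtype=float),
            artifact_intervals_s=list(self.artifact_intervals_s),
        )


def window_slices(duration_s: float, window_s: float = WINDOW_S):
    """Non-overlapping ``window_s`` intervals tiling ``[0, duration_s)``.

    Returns a list of ``(start_s, end_s)`` tuples; the session design
    (90 s at 30-s cadence) makes the tiling exact.
    """
    n = int(round(duration_s / window_s))
    return [(i * window_s, (i + 1) * window_s) for i in range(n)]
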