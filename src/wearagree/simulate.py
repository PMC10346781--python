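"""Synthetic multi-device PPG/EDA cohort generator.

Emulates the study design the downstream analysis assumes: a cohort of
subjects, each recorded over three consecutive 90-s resting sessions by
three device classes simultaneously —

* a laboratory device sampling raw PPG and EDA at 64 Hz,
* a research wearable sampling raw PPG at 64 Hz and raw EDA at 4 Hz,
* a consumer wearable that exposes no raw data, only one HR value and one
  "EDA responses" count per 30-s window.

All devices observe the *same* underlying physiology (one beat train, one
sudomotor driver per subject-session), so cross-device agreement is true by
construction and every downstream stage can be scored against ground truth.
Motion artifacts (spikes, dropouts, step discontinuities) are injected per
device and logged in the truth channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import ConfigurationError, GroundTruth, RawSignal, WINDOW_S, window_slices


class UnsupportedOperationError(ValueError):
    """Raised when an operation is asked of a device that cannot perform it."""


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass
class DeviceProfile:
    """Acquisition characteristics of one device class.

    ``aggregated_only`` devices emit only per-30-s HR and EDA-response
    counts; raw sampling rates and artifact rates are then irrelevant.
    Rates are events per minute.
    """

    name: str
    fs_ppg: float = 0.0
    fs_eda: float = 0.0
    noise_sd_ppg: float = 0.0
    noise_sd_eda: float = 0.0
    spike_rate: float = 0.0
    dropout_rate: float = 0.0
    discontinuity_rate: float = 0.0
    aggregated_only: bool = False
    hr_bias_bpm: float = 0.0
    hr_noise_sd_bpm: float = 3.0
    count_noise_sd: float = 0.5
    # motion artifacts are a pulse-wave phenomenon in this design; the EDA
    # chain has no artifact-rejection stage, so injections default to PPG
    artifact_modalities: tuple = ("ppg",)

    def __post_init__(self) -> None:
        for f in ("fs_ppg", "fs_eda", "spike_rate", "dropout_rate",
                  "discontinuity_rate", "noise_sd_ppg", "noise_sd_eda"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0")

    def fs_for(self, modality: str) -> float:
        return self.fs_ppg if modality == "ppg" else self.fs_eda

    def noise_for(self, modality: str) -> float:
        return self.noise_sd_ppg if modality == "ppg" else self.noise_sd_eda


@dataclass
class PulseTemplate:
    """Two-Gaussian beat morphology: systolic upstroke plus dicrotic bump.

    One dominant local maximum per beat, at the beat time itself.
    """

    systolic_width_s: float = 0.06
    dicrotic_delay_s: float = 0.28
    dicrotic_width_s: float = 0.09
    dicrotic_amp: float = 0.35

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        sy = np.exp(-0.5 * (t / self.systolic_width_s) ** 2)
        di = self.dicrotic_amp * np.exp(
            -0.5 * ((t - self.dicrotic_delay_s) / self.dicrotic_width_s) ** 2
        )
        return sy + di


@dataclass
class PpgSimConfig:
    duration_s: float = 90.0
    mean_hr_bpm: float = 70.0
    hr_sd_bpm: float = 2.0       # slow within-session drift
    ibi_jitter_sd_s: float = 0.02  # beat-to-beat
    pulse_template: PulseTemplate = field(default_factory=PulseTemplate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.mean_hr_bpm < 30:
            # the 2-s artifact-window premise requires >= 1 beat per 2 s
            raise ConfigurationError("mean_hr_bpm must be >= 30")


@dataclass
class EdaSimConfig:
    duration_s: float = 90.0
    tonic_baseline_us: float = 5.0
    tonic_drift_us_per_min: float = 0.3
    scr_rate_per_min: float = 2.0
    scr_amp_range_us: tuple = (0.1, 0.6)
    bateman_tau1_s: float = 0.75
    bateman_tau2_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.tonic_baseline_us <= 0:
            raise ConfigurationError("tonic_baseline_us must be positive")
        if not (0 < self.bateman_tau1_s < self.bateman_tau2_s):
            raise ConfigurationError("need 0 < tau1 < tau2 for the Bateman kernel")


@dataclass
class CohortConfig:
    """Population-level distributions for subject physiology.

    Resting defaults: mean HR ~ Normal(70, 7) bpm, baseline SCL ~
    LogNormal(ln 5, 0.3) µS, 2 spontaneous SCRs per minute.
    """

    n_subjects: int = 12
    n_sessions: int = 3
    session_s: float = 90.0
    hr_mean_bpm: float = 70.0
    hr_between_sd_bpm: float = 7.0
    hr_within_sd_bpm: float = 2.0
    ibi_jitter_sd_s: float = 0.02
    scl_log_mean: float = math.log(5.0)
    scl_log_sd: float = 0.3
    scl_drift_sd_us_per_min: float = 0.3
    scr_rate_per_min: float = 2.0
    scr_amp_range_us: tuple = (0.1, 0.6)


# --------------------------------------------------------------------------
# kernels and truth helpers
# --------------------------------------------------------------------------

def bateman(t: np.ndarray, tau1: float, tau2: float) -> np.ndarray:
    """Unit-peak Bateman impulse response exp(-t/tau2) - exp(-t/tau1), t >= 0."""
    if not (0 < tau1 < tau2):
        raise ConfigurationError("need 0 < tau1 < tau2")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau2) - np.exp(-np.maximum(t, 0) / tau1), 0.0)
    # analytic peak of the difference of exponentials
    tpk = (math.log(tau2) - math.log(tau1)) / (1 / tau1 - 1 / tau2)
    peak = math.exp(-tpk / tau2) - math.exp(-tpk / tau1)
    return out / peak


def hr_per_window_from_beats(beat_times_s: np.ndarray, duration_s: float,
                             window_s: float = WINDOW_S) -> np.ndarray:
    """Per-window mean of 60/IBI with intervals assigned by midpoint.

    Same assignment rule the HR feature extractor uses, so the simulator's
    truth and the pipeline's estimate are directly comparable. Windows with
    no interval midpoint get NaN.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    wins = window_slices(duration_s, window_s)
    out = np.full(len(wins), np.nan)
    if beat_times_s.size < 2:
        return out
    ibi = np.diff(beat_times_s)
    mid = beat_times_s[:-1] + ibi / 2
    for i, (t0, t1) in enumerate(wins):
        sel = (mid >= t0) & (mid < t1)
        if sel.any():
            out[i] = np.mean(60.0 / ibi[sel])
    return out


# --------------------------------------------------------------------------
# raw-signal simulation
# --------------------------------------------------------------------------

def simulate_ppg(cfg: PpgSimConfig, fs: float) -> tuple[RawSignal, GroundTruth]:
    """Noise-free pulse-wave train at ``fs`` with ground-truth beat times.

    Beat-to-beat intervals follow 60/HR(t) with HR drifting slowly
    (``hr_sd_bpm``) around the subject mean plus white IBI jitter.
    """
    if fs < 8:
        raise ConfigurationError("fs must be >= 8 samples/s for a pulse waveform")
    rng = np.random.default_rng(cfg.seed)

    # slow HR drift: random walk on a 10-s grid, smoothly interpolated
    knots = np.arange(0, cfg.duration_s + 10.0, 10.0)
    walk = np.cumsum(rng.normal(0.0, cfg.hr_sd_bpm / 2.0, size=knots.size))
    walk -= walk.mean()

    # start past the template's left support so the first pulse is rendered
    # whole; a recording naturally starts mid-cycle, never mid-peak
    beats = [0.4]
    while True:
        t = beats[-1]
        hr_t = cfg.mean_hr_bpm + np.interp(t, knots, walk)
        hr_t = max(hr_t, 30.0)
        ibi = 60.0 / hr_t + rng.normal(0.0, cfg.ibi_jitter_sd_s)
        ibi = max(ibi, 0.25)
        if t + ibi > cfg.duration_s:
            break
        beats.append(t + ibi)
    beat_times = np.asarray(beats)

    n = int(round(cfg.duration_s * fs))
    t_grid = np.arange(n) / fs
    values = np.zeros(n)
    half = 0.8  # template support, seconds
    for bt in beat_times:
        i0 = max(int((bt - half) * fs), 0)
        i1 = min(int((bt + half) * fs) + 1, n)
        values[i0:i1] += cfg.pulse_template.evaluate(t_grid[i0:i1] - bt)

    truth = GroundTruth(
        beat_times_s=beat_times,
        true_hr_per_window_bpm=hr_per_window_from_beats(beat_times, cfg.duration_s),
    )
    sig = RawSignal(values, fs=fs, units="au", modality="ppg")
    return sig, truth


def simulate_eda(cfg: EdaSimConfig, fs: float) -> tuple[RawSignal, GroundTruth]:
    """Skin-conductance trace: drifting tonic level plus Bateman-shaped SCRs.

    The phasic component is a sum of unit-peak Bateman kernels scaled by
    per-event amplitudes at Poisson-distributed event times; truth records
    event times and the exact per-window mean tonic level.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs

    tonic = cfg.tonic_baseline_us + cfg.tonic_drift_us_per_min * t / 60.0

    # homogeneous Poisson SCR events
    events = []
    if cfg.scr_rate_per_min > 0:
        tt = rng.exponential(60.0 / cfg.scr_rate_per_min)
        while tt < cfg.duration_s:
            events.append(tt)
            tt += rng.exponential(60.0 / cfg.scr_rate_per_min)
    events = np.asarray(events)
    lo, hi = cfg.scr_amp_range_us
    amps = rng.uniform(lo, hi, size=events.size)

    phasic = np.zeros(n)
    for et, a in zip(events, amps):
        phasic += a * bateman(t - et, cfg.bateman_tau1_s, cfg.bateman_tau2_s)

    wins = window_slices(cfg.duration_s)
    scl = np.array([
        cfg.tonic_baseline_us + cfg.tonic_drift_us_per_min * ((t0 + t1) / 2) / 60.0
        for t0, t1 in wins
    ])
    truth = GroundTruth(scr_event_times_s=events, true_scl_per_window_us=scl)
    sig = RawSignal(tonic + phasic, fs=fs, units="uS", modality="eda")
    return sig, truth


# --------------------------------------------------------------------------
# device model
# --------------------------------------------------------------------------

def _median_window_max(values: np.ndarray, fs: float, window_s: float = 2.0) -> float:
    """Median over 2-s windows of the within-window maximum |amplitude|."""
    w = max(int(round(window_s * fs)), 1)
    n_full = values.size // w
    if n_full == 0:
        return float(np.max(np.abs(values))) if values.size else 0.0
    m = np.abs(values[: n_full * w]).reshape(n_full, w).max(axis=1)
    return float(np.median(m))


def apply_device_model(sig: RawSignal, truth: GroundTruth, prof: DeviceProfile,
                       seed: int) -> tuple[RawSignal, GroundTruth]:
    """Pass a pristine physiological trace through one device's acquisition.

    Resamples to the device rate (polyphase, anti-aliased), adds Gaussian
    sensor noise, and injects Poisson-placed motion artifacts: additive
    spikes (3-5x the median 2-s-window amplitude, hence detectable by the
    2x-median rule by construction), dropouts (signal forced to 0) and step
    discontinuities. Every injected interval is appended to the returned
    truth's ``artifact_intervals_s``.
    """
    if prof.aggregated_only:
        raise UnsupportedOperationError(
            f"device {prof.name!r} exposes no raw {sig.modality} stream"
        )
    fs_out = prof.fs_for(sig.modality)
    if fs_out <= 0:
        raise UnsupportedOperationError(
            f"device {prof.name!r} exposes no raw {sig.modality} stream"
        )
    rng = np.random.default_rng(seed)
    truth = truth.copy()

    values = sig.values
    if fs_out != sig.fs:
        from fractions import Fraction

        frac = Fraction(fs_out / sig.fs).limit_denominator(1000)
        values = sps.resample_poly(values, frac.numerator, frac.denominator,
                                   padtype="line")
    n = values.size
    fs = fs_out
    duration = n / fs
    values = values.copy()

    noise_sd = prof.noise_for(sig.modality)
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=n)

    ref = _median_window_max(values, fs)
    inject = sig.modality in prof.artifact_modalities

    def _poisson_times(rate_per_min: float) -> np.ndarray:
        if not inject:
            return np.empty(0)
        lam = rate_per_min * duration / 60.0
        k = rng.poisson(lam)
        return np.sort(rng.uniform(0.0, duration, size=k))

    for t0 in _poisson_times(prof.spike_rate):
        width = 0.06
        i0, i1 = int(t0 * fs), min(int((t0 + width) * fs) + 1, n)
        amp = rng.uniform(3.0, 5.0) * max(ref, 1e-12)
        values[i0:i1] += amp
        truth.artifact_intervals_s.append((t0, min(t0 + width, duration), "spike"))

    for t0 in _poisson_times(prof.dropout_rate):
        width = rng.uniform(0.5, 1.5)
        i0, i1 = int(t0 * fs), min(int((t0 + width) * fs) + 1, n)
        values[i0:i1] = 0.0
        truth.artifact_intervals_s.append((t0, min(t0 + width, duration), "dropout"))

    for t0 in _poisson_times(prof.discontinuity_rate):
        width = rng.uniform(1.0, 3.0)
        i0, i1 = int(t0 * fs), min(int((t0 + width) * fs) + 1, n)
        step = rng.choice([-1.0, 1.0]) * rng.uniform(0.8, 1.5) * max(ref, 1e-12)
        values[i0:i1] += step
        truth.artifact_intervals_s.append((t0, min(t0 + width, duration), "discontinuity"))

    out = sig.copy_with(values=values, fs=fs, device=prof.name)
    return out, truth


def emulate_aggregated_device(hr_truth: np.ndarray, scr_truth: np.ndarray,
                              prof: DeviceProfile, seed: int,
                              duration_s: float = 90.0) -> pd.DataFrame:
    """Consumer-device output: one HR value and one response count per 30 s.

    HR is the true window HR plus device bias and Gaussian noise, rounded to
    integer bpm; the EDA-responses count is the number of true SCR events in
    the window plus rounded miscount noise, clipped at zero. The count
    definition is an explicit stand-in for the device's proprietary metric.
    """
    if not prof.aggregated_only:
        raise UnsupportedOperationError(
            f"device {prof.name!r} is not an aggregated-output device"
        )
    rng = np.random.default_rng(seed)
    hr_truth = np.asarray(hr_truth, dtype=float)
    scr_truth = np.asarray(scr_truth, dtype=float)
    wins = window_slices(duration_s)

    rows = []
    for i, (t0, t1) in enumerate(wins):
        hr = hr_truth[i] if i < hr_truth.size else np.nan
        if np.isfinite(hr):
            hr_out = round(hr + prof.hr_bias_bpm + rng.normal(0.0, prof.hr_noise_sd_bpm))
        else:
            hr_out = np.nan
        n_true = int(np.sum((scr_truth >= t0) & (scr_truth < t1)))
        miscount = int(round(rng.normal(0.0, prof.count_noise_sd)))
        rows.append({
            "window_index": i + 1,
            "hr_bpm": hr_out,
            "n_responses": max(n_true + miscount, 0),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def default_profiles() -> list[DeviceProfile]:
    """The three device classes of the study design, with realistic defaults."""
    return [
        DeviceProfile("shimmer", fs_ppg=64, fs_eda=64, noise_sd_ppg=0.01,
                      noise_sd_eda=0.005, spike_rate=0.3, dropout_rate=0.1,
                      discontinuity_rate=0.1),
        DeviceProfile("empatica", fs_ppg=64, fs_eda=4, noise_sd_ppg=0.03,
                      noise_sd_eda=0.01, spike_rate=2.0, dropout_rate=0.3,
                      discontinuity_rate=0.3),
        DeviceProfile("fitbit", aggregated_only=True, hr_bias_bpm=0.0,
                      hr_noise_sd_bpm=3.0, count_noise_sd=0.5),
    ]


def zero_noise_profiles() -> list[DeviceProfile]:
    """Same devices with every noise/artifact parameter at zero."""
    profs = default_profiles()
    for p in profs:
        p.noise_sd_ppg = p.noise_sd_eda = 0.0
        p.spike_rate = p.dropout_rate = p.discontinuity_rate = 0.0
        p.hr_noise_sd_bpm = p.hr_bias_bpm = p.count_noise_sd = 0.0
    return profs


@dataclass
class SimulatedSession:
    """One subject-session: per-device raw views plus the shared truth.

    ``signals[device][modality]`` are the device's raw traces,
    ``truths[device][modality]`` the truth channels carrying that device's
    injected artifact intervals; ``aggregated[device]`` holds 30-s outputs
    for aggregated-only devices. ``truth`` is the pristine physiology.
    """

    subject_id: str
    session_index: int
    signals: dict
    truths: dict
    aggregated: dict
    truth: GroundTruth


_SIM_FS = 64.0  # physiological master rate before device models


def simulate_session(subject_id: str, session_index: int,
                     ppg_cfg: PpgSimConfig, eda_cfg: EdaSimConfig,
                     profiles: list[DeviceProfile], seed: int) -> SimulatedSession:
    ppg, truth_ppg = simulate_ppg(ppg_cfg, fs=_SIM_FS)
    eda, truth_eda = simulate_eda(eda_cfg, fs=_SIM_FS)
    truth = GroundTruth(
        beat_times_s=truth_ppg.beat_times_s,
        true_hr_per_window_bpm=truth_ppg.true_hr_per_window_bpm,
        scr_event_times_s=truth_eda.scr_event_times_s,
        true_scl_per_window_us=truth_eda.true_scl_per_window_us,
    )

    signals: dict = {}
    truths: dict = {}
    aggregated: dict = {}
    for k, prof in enumerate(profiles):
        if prof.aggregated_only:
            aggregated[prof.name] = emulate_aggregated_device(
                truth.true_hr_per_window_bpm, truth.scr_event_times_s, prof,
                seed=seed + 1000 + k, duration_s=ppg_cfg.duration_s,
            )
            continue
        signals[prof.name] = {}
        truths[prof.name] = {}
        for m, (raw, tr) in (("ppg", (ppg, truth)), ("eda", (eda, truth))):
            if prof.fs_for(m) > 0:
                dev_sig, dev_truth = apply_device_model(
                    raw, tr, prof, seed=seed + 2000 + 10 * k + (0 if m == "ppg" else 1)
                )
                dev_sig.subject = subject_id
                dev_sig.session = session_index
                signals[prof.name][m] = dev_sig
                truths[prof.name][m] = dev_truth

    return SimulatedSession(subject_id, session_index, signals, truths,
                            aggregated, truth)


def simulate_cohort(n_subjects: int = 12,
                    profiles: list[DeviceProfile] | None = None,
                    seed: int = 0,
                    cohort: CohortConfig | None = None) -> list[SimulatedSession]:
    """Generate the full cohort: ``n_subjects`` x 3 sessions of 90 s.

    Subject-level physiology (mean HR, baseline SCL, tonic drift) is drawn
    once per subject from the population distributions in ``cohort``; each
    session then gets its own beat train and SCR event stream from that
    physiology, and every device views the same underlying session.
    Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    cohort = cohort or CohortConfig(n_subjects=n_subjects)
    profiles = profiles if profiles is not None else default_profiles()
    master = np.random.default_rng(seed)

    sessions = []
    for s in range(n_subjects):
        subj = f"S{s + 1:02d}"
        mean_hr = float(np.clip(master.normal(cohort.hr_mean_bpm, cohort.hr_between_sd_bpm),
                                45.0, 120.0))
        baseline = float(np.exp(master.normal(cohort.scl_log_mean, cohort.scl_log_sd)))
        drift = float(master.normal(0.0, cohort.scl_drift_sd_us_per_min))
        for k in range(cohort.n_sessions):
            sess_seed = int(master.integers(0, 2**31 - 1))
            ppg_cfg = PpgSimConfig(
                duration_s=cohort.session_s, mean_hr_bpm=mean_hr,
                hr_sd_bpm=cohort.hr_within_sd_bpm,
                ibi_jitter_sd_s=cohort.ibi_jitter_sd_s, seed=sess_seed,
            )
            eda_cfg = EdaSimConfig(
                duration_s=cohort.session_s, tonic_baseline_us=baseline,
                tonic_drift_us_per_min=drift,
                scr_rate_per_min=cohort.scr_rate_per_min,
                scr_amp_range_us=cohort.scr_amp_range_us, seed=sess_seed + 1,
            )
            sessions.append(simulate_session(subj, k + 1, ppg_cfg, eda_cfg,
                                             profiles, seed=sess_seed))
    return sessions
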