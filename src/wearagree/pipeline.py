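"""End-to-end orchestration: simulate -> condition -> features -> agreement.

One call runs the whole study design on a synthetic cohort: per
subject-session-device, the PPG chain yields windowed HR, the EDA chain
yields windowed SCL and response counts, aggregated-only devices contribute
their emitted 30-s outputs directly, and the feature table feeds the
per-subject Pearson and group rmcorr agreement analyses for each device
pair. Fully deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import cardiac, eda, ppg
from .core import WINDOW_S
from .io import write_features_csv, write_json_atomic
from .simulate import CohortConfig, DeviceProfile, default_profiles, simulate_cohort


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    seed: int
    n_subjects: int = 12
    n_sessions: int = 3
    session_s: float = 90.0
    window_s: float = WINDOW_S
    profiles: list = field(default_factory=default_profiles)
    cohort: CohortConfig | None = None
    filter_spec: ppg.FilterSpec = field(default_factory=ppg.FilterSpec)
    artifact_cfg: ppg.ArtifactConfig = field(default_factory=ppg.ArtifactConfig)
    eda_tau: tuple = (0.75, 2.0)
    eda_ridge: float = 1e-3
    eda_fs_dec: float = 8.0
    scr_amp_min_us: float = 0.01
    out_dir: str | None = None

    def cohort_config(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        return CohortConfig(n_subjects=self.n_subjects,
                            n_sessions=self.n_sessions,
                            session_s=self.session_s)

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, (DeviceProfile, ppg.FilterSpec, ppg.ArtifactConfig,
                              CohortConfig)):
                return vars(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        blob = json.dumps(vars(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# canonical device pairings: each comparison device against the laboratory
# reference, with the consumer count metric paired against laboratory SCL
def default_comparisons(profiles: list) -> list[dict]:
    lab = profiles[0].name
    out = []
    for prof in profiles[1:]:
        if prof.aggregated_only:
            out.append({"feature": "hr_bpm", "device_a": prof.name,
                        "device_b": lab, "feature_b": "hr_bpm"})
            out.append({"feature": "n_responses", "device_a": prof.name,
                        "device_b": lab, "feature_b": "scl_us"})
        else:
            out.append({"feature": "hr_bpm", "device_a": prof.name,
                        "device_b": lab, "feature_b": "hr_bpm"})
            out.append({"feature": "scl_us", "device_a": prof.name,
                        "device_b": lab, "feature_b": "scl_us"})
    return out


def session_features(session, cfg: RunConfig) -> pd.DataFrame:
    """Run the PPG and EDA chains on one simulated session's device views."""
    rows = []
    n_win = int(round(cfg.session_s / cfg.window_s))
    base = (session.session_index - 1) * n_win

    for device, mods in session.signals.items():
        hr = scl = counts = None
        if "ppg" in mods:
            cleaned, mask = ppg.clean_ppg(mods["ppg"], cfg.filter_spec,
                                          cfg.artifact_cfg)
            hr = cardiac.hr_from_signal(cleaned, mask, cfg.window_s)
        if "eda" in mods:
            lp = eda.lowpass_eda(mods["eda"])
            dec = eda.continuous_decomposition(
                lp, tau_init=cfg.eda_tau, ridge=cfg.eda_ridge,
                fs_dec=cfg.eda_fs_dec)
            scl = eda.scl_windows(dec, cfg.window_s)
            counts = eda.count_scr_responses(dec, cfg.scr_amp_min_us,
                                             cfg.window_s)
        for i in range(n_win):
            rows.append({
                "subject": session.subject_id,
                "session": session.session_index,
                "device": device,
                "window_index": base + i + 1,
                "hr_bpm": float(hr.iloc[i]["hr_bpm"]) if hr is not None else np.nan,
                "scl_us": float(scl.iloc[i]["scl_us"]) if scl is not None else np.nan,
                "n_responses": (int(counts.iloc[i]["n_responses"])
                                if counts is not None else np.nan),
            })

    for device, table in session.aggregated.items():
        for i in range(n_win):
            rows.append({
                "subject": session.subject_id,
                "session": session.session_index,
                "device": device,
                "window_index": base + i + 1,
                "hr_bpm": float(table.iloc[i]["hr_bpm"]),
                "scl_us": np.nan,
                "n_responses": int(table.iloc[i]["n_responses"]),
            })
    return pd.DataFrame(rows)


def truth_features(sessions, cfg: RunConfig) -> pd.DataFrame:
    """Ground-truth windowed HR/SCL table aligned with the feature table."""
    rows = []
    n_win = int(round(cfg.session_s / cfg.window_s))
    for s in sessions:
        base = (s.session_index - 1) * n_win
        for i in range(n_win):
            t0, t1 = i * cfg.window_s, (i + 1) * cfg.window_s
            ev = s.truth.scr_event_times_s
            rows.append({
                "subject": s.subject_id,
                "session": s.session_index,
                "window_index": base + i + 1,
                "true_hr_bpm": float(s.truth.true_hr_per_window_bpm[i]),
                "true_scl_us": float(s.truth.true_scl_per_window_us[i]),
                "true_n_scr": int(np.sum((ev >= t0) & (ev < t1))),
            })
    return pd.DataFrame(rows)


@dataclass
class RunResult:
    manifest: dict
    features: pd.DataFrame
    truth: pd.DataFrame
    agreements: dict  # (feature, device_a, device_b) -> AgreementSummary
    sessions: list

    def summary(self) -> str:
        parts = [f"Pipeline run {self.manifest['config_hash']}: "
                 f"{self.manifest['n_subjects']} subjects, "
                 f"{len(self.features)} feature rows"]
        parts += [s.summary() for s in self.agreements.values()]
        return "\n\n".join(parts)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis; optionally write tables under out_dir."""
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        sessions = simulate_cohort(cfg.n_subjects, cfg.profiles, cfg.seed,
                                   cfg.cohort_config())
        feats = pd.concat([session_features(s, cfg) for s in sessions],
                          ignore_index=True)
        truth = truth_features(sessions, cfg)
        agreements = {}
        for comp in default_comparisons(cfg.profiles):
            tbl = agr.paired_table(feats, comp["device_a"], comp["device_b"],
                                   comp["feature"], comp["feature_b"])
            key = (comp["feature"], comp["device_a"], comp["device_b"])
            agreements[key] = agr.summarize_agreement(
                tbl, feature=comp["feature"], device_a=comp["device_a"],
                device_b=comp["device_b"])
        caught = sorted({str(w.message) for w in wlist})

    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "n_sessions": cfg.n_sessions,
        "devices": [p.name for p in cfg.profiles],
        "rows": {
            "features": int(len(feats)),
            "truth": int(len(truth)),
            "sessions": len(sessions),
        },
        "warnings": caught,
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_features_csv(feats, out / "features.csv")
        truth.to_csv(out / "truth.csv", index=False)
        report = {}
        for (feature, da, db), summ in agreements.items():
            report[f"{feature}:{da}:{db}"] = {
                "pearson": [vars(p) for p in summ.pearson],
                "n_significant_positive": summ.n_significant_positive,
                "rmcorr": (None if summ.rmc is None else {
                    "r_rm": summ.rmc.r_rm, "df": summ.rmc.df,
                    "p": summ.rmc.p, "slope": summ.rmc.slope,
                    "n_subjects": summ.rmc.n_subjects,
                    "n_total": summ.rmc.n_total,
                }),
            }
        write_json_atomic(report, out / "agreement.json")
        write_json_atomic(manifest, out / "manifest.json")

    return RunResult(manifest=manifest, features=feats, truth=truth,
                     agreements=agreements, sessions=sessions)
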