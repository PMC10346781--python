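"""Device-agreement statistics: per-subject Pearson and repeated-measures
correlation.

Each subject contributes up to nine paired 30-s feature values (HR, SCL or
EDA-response counts) per device pair. Agreement is assessed two ways:

* per-subject Pearson product-moment correlation, with a two-sided p-value
  from the t transform on n - 2 degrees of freedom, reported per subject
  together with a tally of subjects showing r > 0 and p < 0.05;
* a single group-level repeated-measures correlation (rmcorr): an ANCOVA
  with subject-specific intercepts and a common slope, whose
  variance-ratio r_rm = sign(slope) * sqrt(SS_measure / (SS_measure +
  SS_error)) quantifies the shared within-subject association while
  separating inter-individual offsets from intra-individual covariation.
  Its error degrees of freedom are N_total - N_subjects - 1.

No multiple-testing correction is applied across the per-subject tests;
the tally is raw per-subject significance and is labelled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PearsonResult:
    """Per-subject product-moment correlation between two device series."""

    subject_id: str
    r: float          # NaN when undefined (constant series or n < 2)
    p: float          # NaN when n < 3 or r undefined
    n: int

    @property
    def significant_positive(self) -> bool:
        return bool(np.isfinite(self.r) and np.isfinite(self.p)
                    and self.r > 0 and self.p < 0.05)


@dataclass
class RmcorrResult:
    """Group repeated-measures correlation (common-slope ANCOVA)."""

    r_rm: float
    df: int
    p: float
    slope: float
    n_subjects: int
    n_total: int
    excluded_subjects: list = field(default_factory=list)

    def summary(self) -> str:
        return (
            "Repeated-measures correlation\n"
            f"  r_rm = {self.r_rm: .3f}, df = {self.df}, p = {self.p:.3g}\n"
            f"  common slope = {self.slope: .4f}\n"
            f"  {self.n_subjects} subjects, {self.n_total} paired points"
            + (f", excluded: {', '.join(self.excluded_subjects)}"
               if self.excluded_subjects else "")
        )


def _pairs_by_subject(tbl: pd.DataFrame) -> dict:
    """Complete (A, B) pairs per subject; rows with missing values dropped."""
    out = {}
    for subj, g in tbl.groupby("subject", sort=True):
        a = pd.to_numeric(g["value_a"], errors="coerce")
        b = pd.to_numeric(g["value_b"], errors="coerce")
        keep = a.notna() & b.notna()
        out[str(subj)] = (a[keep].to_numpy(float), b[keep].to_numpy(float))
    return out


def pearson_per_subject(tbl: pd.DataFrame) -> list[PearsonResult]:
    """Pearson r and two-sided p for each subject's paired series.

    ``tbl`` needs columns ``subject``, ``value_a``, ``value_b`` (and
    typically ``window_index``). Subjects with a constant series have an
    undefined r, reported as NaN rather than 0; p is reported only when at
    least 3 pairs are available.
    """
    results = []
    for subj, (a, b) in _pairs_by_subject(tbl).items():
        n = a.size
        if n < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            results.append(PearsonResult(subj, np.nan, np.nan, n))
            continue
        if n >= 3:
            r, p = stats.pearsonr(a, b)
        else:
            r = float(np.corrcoef(a, b)[0, 1])
            p = np.nan
        results.append(PearsonResult(subj, float(r), float(p), n))
    return results


def rmcorr(tbl: pd.DataFrame) -> RmcorrResult:
    """Repeated-measures correlation via dummy-coded common-slope ANCOVA.

    Fits ``value_b ~ subject intercepts + slope * value_a`` by least
    squares. SS_measure is the reduction in residual sum of squares gained
    by adding the common slope to the intercepts-only model; r_rm carries
    the slope's sign. Subjects with fewer than 2 complete pairs or a
    constant A-series contribute no within-subject information and are
    excluded (and reported); if none remain, a ValueError is raised.
    """
    pairs = _pairs_by_subject(tbl)
    excluded = [s for s, (a, b) in pairs.items()
                if a.size < 2 or np.ptp(a) == 0]
    kept = {s: ab for s, ab in pairs.items() if s not in excluded}
    if not kept:
        raise ValueError("no subject has >= 2 pairs with varying values")

    subjects = sorted(kept)
    a = np.concatenate([kept[s][0] for s in subjects])
    b = np.concatenate([kept[s][1] for s in subjects])
    codes = np.concatenate([
        np.full(kept[s][0].size, i) for i, s in enumerate(subjects)
    ])
    n_total, n_sub = a.size, len(subjects)

    # dummy-coded intercepts (one column per subject, no global intercept)
    D = np.zeros((n_total, n_sub))
    D[np.arange(n_total), codes] = 1.0
    X_full = np.hstack([D, a[:, None]])

    beta_full, _, _, _ = np.linalg.lstsq(X_full, b, rcond=None)
    ss_error = float(np.sum((b - X_full @ beta_full) ** 2))
    beta_int, _, _, _ = np.linalg.lstsq(D, b, rcond=None)
    ss_reduced = float(np.sum((b - D @ beta_int) ** 2))
    ss_measure = max(ss_reduced - ss_error, 0.0)

    slope = float(beta_full[-1])
    df = n_total - n_sub - 1
    denom = ss_measure + ss_error
    r_rm = math.copysign(math.sqrt(ss_measure / denom), slope) if denom > 0 else np.nan
    if df > 0 and ss_error > 0:
        f_stat = ss_measure / (ss_error / df)
        p = float(stats.f.sf(f_stat, 1, df))
    elif df > 0 and ss_measure > 0:
        p = 0.0  # perfect fit
    else:
        p = np.nan
    return RmcorrResult(r_rm=float(r_rm), df=int(df), p=p, slope=slope,
                        n_subjects=n_sub, n_total=n_total,
                        excluded_subjects=excluded)


@dataclass
class AgreementSummary:
    """Per device pair and feature: subject-level and group-level agreement."""

    feature: str
    device_a: str
    device_b: str
    pearson: list
    rmc: RmcorrResult | None
    n_significant_positive: int = 0
    note: str = "per-subject p-values are uncorrected for multiple testing"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"subject": pr.subject_id, "r": pr.r, "p": pr.p, "n": pr.n,
             "significant_positive": pr.significant_positive}
            for pr in self.pearson
        ])

    def summary(self) -> str:
        lines = [
            f"Agreement: {self.feature}  [{self.device_a} vs {self.device_b}]",
            f"  subjects with r > 0 and p < 0.05: "
            f"{self.n_significant_positive}/{len(self.pearson)}",
        ]
        if self.rmc is not None:
            lines.append(
                f"  rmcorr: r_rm = {self.rmc.r_rm: .3f}, "
                f"df = {self.rmc.df}, p = {self.rmc.p:.3g}"
            )
        lines.append(f"  note: {self.note}")
        return "\n".join(lines)


def summarize_agreement(tbl: pd.DataFrame, feature: str = "",
                        device_a: str = "A", device_b: str = "B") -> AgreementSummary:
    """Compute per-subject Pearson, group rmcorr and the significance tally."""
    pearson = pearson_per_subject(tbl)
    try:
        rmc = rmcorr(tbl)
    except ValueError:
        rmc = None
    n_sig = sum(pr.significant_positive for pr in pearson)
    return AgreementSummary(feature=feature, device_a=device_a,
                            device_b=device_b, pearson=pearson, rmc=rmc,
                            n_significant_positive=n_sig)


def paired_table(features: pd.DataFrame, device_a: str, device_b: str,
                 feature: str, feature_b: str | None = None) -> pd.DataFrame:
    """Build the paired per-subject table for one feature and device pair.

    ``features`` is the long-format pipeline output with columns
    ``subject, device, window_index`` and one column per feature. Windows
    missing on either device are dropped (pairwise deletion).
    ``feature_b`` allows cross-feature pairing, e.g. a consumer device's
    response counts against a laboratory device's SCL.
    """
    feature_b = feature_b or feature
    fa = features.loc[features["device"] == device_a,
                      ["subject", "window_index", feature]].rename(
                          columns={feature: "value_a"})
    fb = features.loc[features["device"] == device_b,
                      ["subject", "window_index", feature_b]].rename(
                          columns={feature_b: "value_b"})
    merged = fa.merge(fb, on=["subject", "window_index"])
    return merged.dropna(subset=["value_a", "value_b"]).reset_index(drop=True)
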