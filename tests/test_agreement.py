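"""Per-subject Pearson and repeated-measures correlation.

Independent oracles live here: a direct product-moment evaluation for
Pearson's r and an explicitly dummy-coded ANCOVA least-squares solve for
rmcorr, both checked against the module implementations; pingouin serves
as an external cross-check of the rmcorr triple.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wearagree as wa
from wearagree.agreement import paired_table, pearson_per_subject, rmcorr


def _table(subjects):
    """Build a paired table from {subject: (a_values, b_values)}."""
    rows = []
    for subj, (a, b) in subjects.items():
        for i, (x, y) in enumerate(zip(a, b)):
            rows.append({"subject": subj, "window_index": i + 1,
                         "value_a": x, "value_b": y})
    return pd.DataFrame(rows)


def _pearson_oracle(x, y):
    """Product-moment formula evaluated directly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def _rmcorr_oracle(tbl):
    """Dummy-coded common-slope ANCOVA solved explicitly."""
    subjects = sorted(tbl["subject"].unique())
    a = tbl["value_a"].to_numpy(float)
    b = tbl["value_b"].to_numpy(float)
    D = np.zeros((len(tbl), len(subjects)))
    for i, s in enumerate(tbl["subject"]):
        D[i, subjects.index(s)] = 1.0
    X = np.hstack([D, a[:, None]])
    beta = np.linalg.lstsq(X, b, rcond=None)[0]
    sse_full = np.sum((b - X @ beta) ** 2)
    beta0 = np.linalg.lstsq(D, b, rcond=None)[0]
    sse_red = np.sum((b - D @ beta0) ** 2)
    ss_measure = sse_red - sse_full
    df = len(tbl) - len(subjects) - 1
    r = math.copysign(math.sqrt(ss_measure / (ss_measure + sse_full)), beta[-1])
    f = ss_measure / (sse_full / df)
    return r, df, float(stats.f.sf(f, 1, df))


def _random_table(seed, n_subjects=12, n_windows=9):
    rng = np.random.default_rng(seed)
    subjects = {}
    for s in range(n_subjects):
        a = rng.normal(70, 5, n_windows) + rng.normal(0, 10)
        b = 0.8 * a + rng.normal(0, 2, n_windows) + rng.normal(0, 5)
        subjects[f"S{s:02d}"] = (a, b)
    return _table(subjects)


class TestPearson:
    def test_identity_series_gives_r_one(self):
        x = np.arange(9.0)
        res = pearson_per_subject(_table({"S01": (x, x)}))
        assert res[0].r == pytest.approx(1.0)
        assert res[0].significant_positive

    def test_negated_series_gives_r_minus_one(self):
        x = np.arange(9.0)
        res = pearson_per_subject(_table({"S01": (x, -x)}))
        assert res[0].r == pytest.approx(-1.0)
        assert not res[0].significant_positive

    def test_matches_product_moment_oracle(self):
        x = np.arange(1.0, 10.0)
        y = np.array([1, 2, 3, 4, 5, 6, 7, 8, 7.0])
        res = pearson_per_subject(_table({"S01": (x, y)}))
        assert abs(res[0].r - _pearson_oracle(x, y)) < 1e-12

    def test_constant_series_reported_missing_not_zero(self):
        res = pearson_per_subject(_table({"S01": (np.ones(9), np.arange(9.0))}))
        assert np.isnan(res[0].r)
        assert np.isnan(res[0].p)

    def test_two_points_give_r_without_p(self):
        res = pearson_per_subject(_table({"S01": ([1.0, 2.0], [2.0, 5.0])}))
        assert res[0].r == pytest.approx(1.0)
        assert np.isnan(res[0].p)


class TestRmcorr:
    def test_common_slope_with_offsets_gives_r_one(self):
        x = np.arange(9.0)
        tbl = _table({f"S{i}": (x, 2 * x + 10 * i) for i in range(4)})
        res = rmcorr(tbl)
        assert res.r_rm == pytest.approx(1.0)
        assert res.df == 4 * 9 - 4 - 1

    def test_negated_slope_gives_r_minus_one(self):
        x = np.arange(9.0)
        tbl = _table({f"S{i}": (x, -2 * x + 10 * i) for i in range(4)})
        assert rmcorr(tbl).r_rm == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_explicit_ancova_oracle(self, seed):
        tbl = _random_table(seed)
        res = rmcorr(tbl)
        r, df, p = _rmcorr_oracle(tbl)
        assert abs(res.r_rm - r) < 1e-10
        assert res.df == df
        assert abs(res.p - p) < 1e-10

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        tbl = _random_table(7)
        res = rmcorr(tbl)
        ref = pingouin.rm_corr(data=tbl.assign(s=tbl["subject"]),
                               x="value_a", y="value_b", subject="s")
        assert abs(res.r_rm - float(ref["r"].iloc[0])) < 1e-6
        assert res.df == int(ref["dof"].iloc[0])
        assert abs(res.p - float(ref["pval"].iloc[0])) < 1e-6

    def test_affine_rescaling_leaves_r_rm_unchanged(self):
        tbl = _random_table(3)
        r0 = rmcorr(tbl).r_rm
        tbl2 = tbl.assign(value_a=2.5 * tbl.value_a - 7,
                          value_b=0.3 * tbl.value_b + 11)
        assert rmcorr(tbl2).r_rm == pytest.approx(r0, abs=1e-10)

    def test_single_subject_reduces_to_pearson(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=9)
        b = 0.5 * a + rng.normal(0, 0.3, 9)
        tbl = _table({"S01": (a, b)})
        assert rmcorr(tbl).r_rm == pytest.approx(_pearson_oracle(a, b))

    def test_constant_subjects_excluded_and_reported(self):
        x = np.arange(9.0)
        tbl = _table({"S1": (x, 2 * x), "S2": (np.ones(9), x)})
        res = rmcorr(tbl)
        assert res.excluded_subjects == ["S2"]
        assert res.n_subjects == 1

    def test_all_constant_subjects_is_an_error(self):
        tbl = _table({"S1": (np.ones(9), np.arange(9.0))})
        with pytest.raises(ValueError):
            rmcorr(tbl)

    def test_independent_devices_center_on_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(200):
            subjects = {
                f"S{i}": (rng.normal(size=9), rng.normal(size=9))
                for i in range(12)
            }
            rs.append(rmcorr(_table(subjects)).r_rm)
        assert abs(float(np.mean(rs))) < 0.05


class TestSummary:
    def test_perfect_agreement_counts_all_subjects(self):
        x = np.arange(9.0)
        tbl = _table({f"S{i}": (x, x + i) for i in range(5)})
        summ = wa.summarize_agreement(tbl)
        assert summ.n_significant_positive == 5

    def test_no_association_counts_zero(self):
        rng = np.random.default_rng(0)
        tbl = _table({f"S{i}": (rng.normal(size=9), rng.normal(size=9))
                      for i in range(3)})
        summ = wa.summarize_agreement(tbl)
        assert summ.n_significant_positive <= 1  # chance-level at alpha=.05

    def test_tally_matches_generator_controlled_truth(self):
        rng = np.random.default_rng(21)
        x = np.arange(9.0)
        agree_subjects = {f"A{i}": (x, 3 * x + rng.normal(0, 0.1, 9))
                          for i in range(4)}
        noise_subjects = {f"N{i}": (rng.normal(size=9), rng.normal(size=9))
                          for i in range(4)}
        summ = wa.summarize_agreement(_table({**agree_subjects,
                                              **noise_subjects}))
        by_subj = {p.subject_id: p.significant_positive for p in summ.pearson}
        assert all(by_subj[s] for s in agree_subjects)
        assert summ.n_significant_positive >= 4


class TestPairedTable:
    def test_pairs_aligned_on_subject_and_window(self):
        feats = pd.DataFrame({
            "subject": ["S1"] * 4,
            "device": ["lab", "lab", "wear", "wear"],
            "window_index": [1, 2, 1, 2],
            "hr_bpm": [60.0, 61.0, 62.0, 63.0],
        })
        tbl = paired_table(feats, "wear", "lab", "hr_bpm")
        assert len(tbl) == 2
        assert list(tbl["value_a"]) == [62.0, 63.0]
        assert list(tbl["value_b"]) == [60.0, 61.0]

    def test_missing_windows_dropped_pairwise(self):
        feats = pd.DataFrame({
            "subject": ["S1"] * 4,
            "device": ["lab", "lab", "wear", "wear"],
            "window_index": [1, 2, 1, 2],
            "hr_bpm": [60.0, np.nan, 62.0, 63.0],
        })
        tbl = paired_table(feats, "wear", "lab", "hr_bpm")
        assert len(tbl) == 1

    def test_cross_feature_pairing(self):
        feats = pd.DataFrame({
            "subject": ["S1", "S1"],
            "device": ["lab", "consumer"],
            "window_index": [1, 1],
            "scl_us": [5.0, np.nan],
            "n_responses": [np.nan, 2.0],
        })
        tbl = paired_table(feats, "consumer", "lab", "n_responses",
                           feature_b="scl_us")
        assert len(tbl) == 1
        assert tbl.loc[0, "value_a"] == 2.0
        assert tbl.loc[0, "value_b"] == 5.0
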