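"""PPG conditioning chain and artifact detectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import wearagree as wa
from wearagree.core import ConfigurationError, RawSignal
from wearagree.ppg import (
    ArtifactConfig,
    FilterSpec,
    Window,
    combine_masks,
    detect_amplitude_artifacts,
    detect_derivative_artifacts,
    segment_windows,
    standardized_squared_derivative,
    window_local_maxima,
)


def _sine(freq_hz, fs=64.0, duration_s=30.0):
    t = np.arange(int(duration_s * fs)) / fs
    return RawSignal(np.sin(2 * np.pi * freq_hz * t), fs=fs)


def _designed_gain(freq_hz, spec=None, fs=64.0):
    """Oracle: squared magnitude response of the zero-phase Butterworth."""
    spec = spec or FilterSpec()
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return np.abs(h[0]) ** 2  # forward-backward filtering squares |H|


class TestBandpass:
    def test_dc_component_rejected(self):
        sig = RawSignal(np.full(64 * 30, 3.7), fs=64)
        out = wa.bandpass_filter(sig)
        mid = out.values[64 * 5:-64 * 5]
        assert np.max(np.abs(mid)) < 1e-6 * 3.7

    @pytest.mark.parametrize("freq", [5.0, 25.0])
    def test_gain_matches_designed_magnitude_response(self, freq):
        out = wa.bandpass_filter(_sine(freq))
        measured = np.max(np.abs(out.values[64 * 10:64 * 20]))
        expected = _designed_gain(freq)
        if freq == 5.0:
            assert abs(measured - 1.0) < 0.05
        assert measured < max(expected * 1.5, 1e-4)

    def test_linearity(self):
        a, b = _sine(3.0), _sine(7.0)
        summed = wa.bandpass_filter(RawSignal(a.values + b.values, fs=64))
        parts = wa.bandpass_filter(a).values + wa.bandpass_filter(b).values
        assert np.allclose(summed.values, parts, atol=1e-9)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            wa.bandpass_filter(RawSignal(np.zeros(300), fs=20))


class TestRectify:
    def test_positive_skew_unchanged(self, conditioned_ppg):
        sig = conditioned_ppg[0]
        out = wa.rectify_by_skewness(sig)
        assert np.array_equal(out.values, sig.values)

    def test_negated_pulse_train_restored(self, clean_ppg_70bpm):
        sig, _ = clean_ppg_70bpm
        filt = wa.bandpass_filter(sig)
        flipped = filt.copy_with(values=-filt.values)
        out = wa.rectify_by_skewness(flipped)
        assert np.array_equal(out.values, filt.values)

    def test_involution(self, clean_ppg_70bpm):
        sig, _ = clean_ppg_70bpm
        filt = wa.bandpass_filter(sig)
        once = wa.rectify_by_skewness(filt)
        twice = wa.rectify_by_skewness(once)
        assert np.array_equal(once.values, twice.values)

    def test_constant_signal_warns_and_passes_through(self):
        sig = RawSignal(np.ones(640), fs=64)
        with pytest.warns(UserWarning):
            out = wa.rectify_by_skewness(sig)
        assert np.array_equal(out.values, sig.values)


class TestWindowing:
    def test_90s_at_64hz_gives_45_full_windows(self):
        sig = RawSignal(np.zeros(90 * 64), fs=64)
        wins = segment_windows(sig)
        assert len(wins) == 45
        assert all(w.full and w.stop - w.start == 128 for w in wins)

    def test_trailing_remainder_becomes_short_window(self):
        sig = RawSignal(np.zeros(3 * 64), fs=64)
        wins = segment_windows(sig)
        assert len(wins) == 2
        assert wins[0].full and not wins[1].full

    def test_windows_tile_contiguously(self):
        sig = RawSignal(np.zeros(90 * 64 + 17), fs=64)
        wins = segment_windows(sig)
        assert wins[0].start == 0
        assert wins[-1].stop == sig.n
        assert all(a.stop == b.start for a, b in zip(wins, wins[1:]))

    def test_empty_signal_rejected(self):
        with pytest.raises(ConfigurationError):
            segment_windows(RawSignal(np.zeros(0), fs=64))

    def test_local_maxima_positions(self):
        ramp = np.concatenate([np.linspace(0, 1, 128), np.zeros(128)])
        sig = RawSignal(ramp, fs=64)
        wins = segment_windows(sig)
        maxima = window_local_maxima(sig, wins)
        assert maxima[0][2] == 127          # monotone ramp peaks at the end
        assert maxima[1][1] == 0.0          # all-zero window has maximum 0
        assert maxima[1][2] == 128          # earliest sample on ties


class TestAmplitudeDetector:
    def _maxima(self, values):
        wins = [Window(i, i * 128, (i + 1) * 128, True)
                for i in range(len(values))]
        return [(w, float(v), w.start) for w, v in zip(wins, values)]

    def test_twice_median_rule_flags_outlier(self):
        mask = detect_amplitude_artifacts(self._maxima([1, 1, 1, 1, 3.1]))
        assert [bool(r) for r in mask.reasons] == [False] * 4 + [True]
        assert mask.reasons[-1] == {"high_amp"}

    def test_identical_maxima_never_flagged(self):
        mask = detect_amplitude_artifacts(self._maxima([2.0] * 6))
        assert not mask.is_artifact.any()

    def test_near_zero_maximum_flags_no_signal(self):
        mask = detect_amplitude_artifacts(self._maxima([1, 1, 1, 1, 0.0]))
        assert mask.reasons[-1] == {"low_amp"}

    def test_raising_a_flagged_maximum_keeps_it_flagged(self):
        base = [1, 1, 1, 1, 2.5]
        m1 = detect_amplitude_artifacts(self._maxima(base))
        assert "high_amp" in m1.reasons[-1]
        for boost in (3.0, 5.0, 50.0):
            m2 = detect_amplitude_artifacts(self._maxima(base[:-1] + [boost]))
            assert "high_amp" in m2.reasons[-1]


class TestDerivativeDetector:
    def test_three_sigma_coverage_on_gaussian_noise(self):
        # first differences of a Gaussian random walk are the Gaussian itself
        rng = np.random.default_rng(0)
        walk = np.cumsum(rng.standard_normal(200_000))
        z2 = standardized_squared_derivative(walk, fs=1.0)
        frac = float(np.mean(z2 <= 9.0))
        assert abs(frac - 0.9973) < 1e-3

    def test_constant_signal_produces_no_flags(self):
        sig = RawSignal(np.ones(64 * 10), fs=64)
        wins = segment_windows(sig)
        with pytest.warns(UserWarning):
            mask = detect_derivative_artifacts(sig, wins)
        assert not mask.is_artifact.any()

    @pytest.mark.parametrize("mode", ["dilate", "convolve-first"])
    def test_step_discontinuity_flagged(self, mode, clean_ppg_70bpm):
        sig, _ = clean_ppg_70bpm
        filt = wa.bandpass_filter(sig)
        v = filt.values.copy()
        v[int(45.3 * 64):] += 2.0 * np.max(np.abs(v))  # mid-window step
        sig2 = filt.copy_with(values=v)
        cfg = ArtifactConfig(deriv_mode=mode)
        mask = detect_derivative_artifacts(sig2, segment_windows(sig2, cfg),
                                           cfg)
        flagged = {w.index for w, r in zip(mask.windows, mask.reasons) if r}
        assert int(45.3 // 2) in flagged


class TestCombineMasks:
    def _mask(self, flags, reason):
        wins = [Window(i, i * 128, (i + 1) * 128, True)
                for i in range(len(flags))]
        reasons = [{reason} if f else set() for f in flags]
        return wa.ArtifactMask(windows=wins, fs=64, reasons=reasons)

    def test_union_of_disjoint_flags(self):
        c = combine_masks(self._mask([1, 0, 0], "high_amp"),
                          self._mask([0, 0, 1], "derivative"))
        assert [bool(r) for r in c.reasons] == [True, False, True]

    def test_same_window_collects_both_reasons(self):
        c = combine_masks(self._mask([1, 0], "high_amp"),
                          self._mask([1, 0], "derivative"))
        assert c.reasons[0] == {"high_amp", "derivative"}

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            combine_masks(self._mask([1, 0], "high_amp"),
                          self._mask([1, 0, 0], "high_amp"))


class TestChainProperties:
    @given(st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_masks_invariant_under_positive_rescaling(self, scale):
        sig, _ = wa.simulate_ppg(
            wa.PpgSimConfig(mean_hr_bpm=65, seed=4), fs=64)
        prof = wa.DeviceProfile("noisy", fs_ppg=64, noise_sd_ppg=0.02,
                                spike_rate=2.0)
        noisy, _ = wa.apply_device_model(sig, wa.GroundTruth(), prof, seed=9)
        _, mask1 = wa.clean_ppg(noisy)
        _, mask2 = wa.clean_ppg(noisy.copy_with(values=noisy.values * scale))
        assert mask1.reasons == mask2.reasons

    def test_spike_windows_are_flagged_on_synthetic_truth(self):
        hits = total = 0
        for seed in range(5):
            sig, _ = wa.simulate_ppg(
                wa.PpgSimConfig(mean_hr_bpm=70, seed=seed), fs=64)
            prof = wa.DeviceProfile("spiky", fs_ppg=64, spike_rate=4.0)
            noisy, truth = wa.apply_device_model(sig, wa.GroundTruth(), prof,
                                                 seed=seed)
            _, mask = wa.clean_ppg(noisy)
            flagged = mask.sample_mask(noisy.n)
            for t0, t1, kind in truth.artifact_intervals_s:
                total += 1
                if flagged[int(t0 * 64):int(t1 * 64) + 1].any():
                    hits += 1
        assert total >= 10
        assert hits / total >= 0.9

    def test_clean_zero_noise_signal_rarely_flagged(self, conditioned_ppg):
        _, mask, _ = conditioned_ppg
        assert mask.artifact_fraction() <= 0.02
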