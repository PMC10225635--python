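import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grf3d import ForceStream, SubjectInfo, TrialMeta
from grf3d.preprocess import (AmbiguousSyncWarning, FilterSpec, butter_filter,
                              detect_gait_events, estimate_offset,
                              filter_and_resample_force, preprocess_trial,
                              resample_force, select_stride_window,
                              synchronize)
from grf3d.simulate import GeneratorConfig, simulate_trial
from grf3d.types import Trial


class TestButterFilter:
    def test_unity_dc_gain(self):
        x = np.full(2000, 5.0)
        y = butter_filter(x, FilterSpec(2, 5.97), 240.0)
        assert np.allclose(y[200:-200], 5.0, atol=1e-6)

    def test_zero_phase_preserves_peak_location(self):
        x = np.concatenate([np.linspace(0, 1, 200), np.linspace(1, 0, 200)])
        y = butter_filter(x, FilterSpec(3, 10.0), 240.0)
        assert abs(int(np.argmax(y)) - int(np.argmax(x))) <= 1

    def test_bidirectional_attenuation_is_magnitude_squared(self):
        """A 20 Hz sinusoid through the 1st-order 8.74 Hz zero-phase filter
        comes out with amplitude |H|² = 1/(1+(20/8.74)²) ≈ 0.160."""
        t = np.arange(0, 10, 1 / 240.0)
        x = np.sin(2 * np.pi * 20.0 * t)
        y = butter_filter(x, FilterSpec(1, 8.74, bidirectional=True), 240.0)
        amp = np.abs(y[400:-400]).max()
        assert amp == pytest.approx(0.160, abs=0.005)

    def test_rejects_cutoff_at_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butter_filter(np.zeros(100), FilterSpec(2, 120.0), 240.0)

    def test_rejects_short_signal(self):
        with pytest.raises(ValueError, match="short"):
            butter_filter(np.zeros(10), FilterSpec(6, 30.0), 240.0)

    def test_filter_then_window_commutes_on_interior(self):
        rng = np.random.default_rng(0)
        x = butter_filter(rng.standard_normal(4000), FilterSpec(4, 20.0), 240.0)
        spec = FilterSpec(3, 10.0)
        full = butter_filter(x, spec, 240.0)[1000:3000]
        windowed = butter_filter(x[500:3500], spec, 240.0)[500:2500]
        assert np.allclose(full[200:-200], windowed[200:-200], atol=1e-6)


class TestResample:
    def test_constant_preserved(self):
        f = ForceStream(np.full((4096, 3), 500.0), 2048.0)
        out = resample_force(f, 240.0)
        assert np.allclose(out.grf, 500.0)
        assert out.rate_hz == 240.0

    def test_low_frequency_amplitude_preserved(self):
        t = np.arange(0, 4, 1 / 2048.0)
        f = ForceStream(np.outer(np.sin(2 * np.pi * 5 * t), [1, 1, 1]), 2048.0)
        out = resample_force(f, 240.0)
        assert np.abs(out.vertical).max() == pytest.approx(1.0, rel=0.01)

    def test_sample_count_scales(self):
        f = ForceStream(np.zeros((20480, 3)), 2048.0)
        out = resample_force(f, 240.0)
        assert abs(out.n_samples - 20480 * 240 / 2048) <= 1

    def test_upsampling_rejected(self):
        f = ForceStream(np.zeros((100, 3)), 240.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample_force(f, 2048.0)


def _square_vgrf(rate=240.0, pattern=((0.0, 0.1), (800.0, 0.2), (0.0, 0.1))):
    parts = [np.full(int(round(d * rate)), v) for v, d in pattern]
    return np.concatenate(parts)


class TestGaitEvents:
    def test_square_wave_single_stance(self):
        ev = detect_gait_events(_square_vgrf(), 240.0)
        stances = ev.stance_intervals()
        assert len(stances) == 1
        a, b = stances[0]
        assert (b - a) / 240.0 == pytest.approx(0.2, abs=2 / 240.0)

    def test_short_spike_not_labelled(self):
        """A 0.03 s spike to 100 N inside flight does not create a stance."""
        v = _square_vgrf(pattern=((0.0, 0.2), (100.0, 0.03), (0.0, 0.2),
                                  (800.0, 0.2), (0.0, 0.1)))
        ev = detect_gait_events(v, 240.0)
        assert len(ev.stance_intervals()) == 1

    def test_short_dropout_absorbed_into_stance(self):
        v = _square_vgrf(pattern=((0.0, 0.1), (800.0, 0.1), (0.0, 0.03),
                                  (800.0, 0.1), (0.0, 0.1)))
        ev = detect_gait_events(v, 240.0)
        stances = ev.stance_intervals()
        assert len(stances) == 1
        a, b = stances[0]
        assert (b - a) / 240.0 == pytest.approx(0.23, abs=2 / 240.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="no stance"):
            detect_gait_events(np.zeros(1000), 240.0)

    def test_idempotent_and_noise_invariant(self):
        v = _square_vgrf(pattern=((0.0, 0.1), (800.0, 0.2), (0.0, 0.1),
                                  (700.0, 0.2), (0.0, 0.1)))
        base = detect_gait_events(v, 240.0).intervals
        noisy = v + np.random.default_rng(0).normal(0, 4.9, v.shape)
        assert detect_gait_events(noisy, 240.0).intervals == base

    def test_mask_matches_intervals(self):
        ev = detect_gait_events(_square_vgrf(), 240.0)
        mask = ev.stance_mask()
        assert mask.sum() == sum(b - a for a, b in ev.stance_intervals())


class TestSynchronize:
    def test_recovers_injected_offset(self, subject):
        cfg = GeneratorConfig(duration_s=12.0, seed=0)
        trial, truth = simulate_trial(TrialMeta(12.0, "preferred", 12.0),
                                      subject, np.random.default_rng(42), cfg)
        _, info = preprocess_trial(trial, n_strides=5)
        assert abs(info["offset_samples"] - truth.offset_samples) <= 1

    def test_pure_noise_warns_ambiguous(self, subject):
        rng = np.random.default_rng(0)
        with pytest.warns(AmbiguousSyncWarning):
            estimate_offset(rng.standard_normal(3000),
                            rng.standard_normal(3000), 240)

    @settings(max_examples=8, deadline=None)
    @given(k=st.integers(min_value=-240, max_value=240))
    def test_offset_recovery_property(self, k):
        """synchronize(synthesize(offset=k)) recovers k within ±1 sample."""
        cfg = GeneratorConfig(duration_s=12.0, offset_range_samples=(k, k), seed=5)
        subject = SubjectInfo("S01", 70.0)
        trial, truth = simulate_trial(TrialMeta(10.0, "preferred", 12.0),
                                      subject, np.random.default_rng(99), cfg)
        assert truth.offset_samples == k
        force = filter_and_resample_force(trial.force, 240.0)
        staged = Trial(subject, trial.meta, trial.sensors,
                       ForceStream(force.grf[: trial.n_samples], 240.0))
        _, est = synchronize(staged)
        assert abs(est - k) <= 1


class TestStrideWindow:
    def test_window_centred_mid_trial(self, subject):
        cfg = GeneratorConfig(duration_s=90.0, seed=1)
        trial, truth = simulate_trial(TrialMeta(10.0, "preferred", 90.0),
                                      subject, np.random.default_rng(1), cfg)
        proc, info = preprocess_trial(trial, n_strides=40)
        a, b = proc.stride_window
        ev = info["events"]
        onsets = ev.stance_onsets()
        start_step = int(np.searchsorted(onsets, a))
        center_stride = (start_step + 40) / 2  # window covers 80 steps
        assert abs(center_stride - info["n_strides_available"] / 2) <= 2

    def test_too_few_strides_reports_count(self, subject):
        cfg = GeneratorConfig(duration_s=10.0, seed=1)
        trial, _ = simulate_trial(TrialMeta(10.0, "preferred", 10.0),
                                  subject, np.random.default_rng(1), cfg)
        with pytest.raises(ValueError, match=r"\d+ strides available < 40"):
            preprocess_trial(trial, n_strides=40)

    def test_single_stride_window_spans_two_steps(self):
        v = _square_vgrf(pattern=((0.0, 0.1), (800.0, 0.2), (0.0, 0.1),
                                  (800.0, 0.2), (0.0, 0.1), (800.0, 0.2),
                                  (0.0, 0.1)))
        ev = detect_gait_events(v, 240.0)
        onsets = ev.stance_onsets()
        assert len(onsets) == 3  # 2 steps -> exactly one stride
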