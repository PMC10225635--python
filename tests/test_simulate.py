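import numpy as np
import pytest

from grf3d import (GRAVITY_MS2, GeneratorConfig, SensorId, SubjectInfo,
                   TrialMeta)
from grf3d.simulate import (generate_cohort, generate_grf_waveform,
                            sample_subjects, simulate_cohort, simulate_trial)


def _truth(subject, cond="preferred", vel=12.0, cfg=None, seed=1):
    cfg = cfg or GeneratorConfig(duration_s=30.0)
    return generate_grf_waveform(TrialMeta(vel, cond, cfg.duration_s), subject,
                                 np.random.default_rng(seed), cfg)


class TestWaveform:
    def test_flight_samples_exactly_zero(self, subject):
        truth = _truth(subject)
        mask = np.ones(truth.grf.shape[0], dtype=bool)
        for a, b in zip(truth.foot_strikes, truth.toe_offs):
            mask[a:b] = False
        assert np.all(truth.grf[mask] == 0.0)

    def test_stance_vertical_nonnegative(self, subject):
        truth = _truth(subject)
        assert truth.grf[:, 2].min() >= 0.0

    def test_impulse_balance_ten_strides(self, subject):
        """Average vertical GRF over an integer number of strides is one
        body weight within 1% (rescaling enforces impulse balance)."""
        truth = _truth(subject)
        a, b = truth.foot_strikes[0], truth.foot_strikes[20]
        mean_bw = truth.grf[a:b, 2].mean() / subject.bodyweight_n
        assert mean_bw == pytest.approx(1.0, abs=0.01)

    def test_stride_frequency_ratio_high_vs_preferred(self, subject):
        f = {}
        for cond in ("preferred", "high"):
            truth = _truth(subject, cond)
            steps = np.diff(truth.foot_strikes).mean()
            f[cond] = 240.0 / (2 * steps)
        assert f["high"] / f["preferred"] == pytest.approx(1.10, abs=0.011)

    def test_flight_fraction_matches_duty_factor(self, subject):
        cfg = GeneratorConfig(duration_s=30.0)
        truth = _truth(subject, vel=10.0, cfg=cfg)
        stance = sum(b - a for a, b in zip(truth.foot_strikes, truth.toe_offs))
        span = truth.toe_offs[-1] - truth.foot_strikes[0]
        flight_frac = 1 - stance / span
        assert flight_frac == pytest.approx(1 - 2 * cfg.duty_factor, abs=0.02)

    @pytest.mark.parametrize("vel", [10.0, 12.0, 14.0])
    @pytest.mark.parametrize("cond", ["low", "preferred", "high"])
    def test_vertical_peak_in_physiological_range(self, subject, vel, cond):
        truth = _truth(subject, cond, vel)
        for a, b in zip(truth.foot_strikes, truth.toe_offs):
            peak = truth.grf[a:b, 2].max() / subject.bodyweight_n
            assert 1.0 <= peak <= 4.0

    def test_too_short_stance_rejected(self, subject):
        cfg = GeneratorConfig(duty_factor=0.08, duration_s=10.0)
        with pytest.raises(ValueError, match="too short"):
            _truth(subject, cfg=cfg)


class TestSensors:
    def test_linear_partition_identity(self, subject, noise_free_cfg, clean_trial):
        """0.55·pelvis + 0.23·(tibL + tibR) reproduces the centre-of-mass
        acceleration when noise, transients and sway are off."""
        trial, truth = clean_trial
        a_com = truth.grf[:, 2] / subject.body_mass_kg - GRAVITY_MS2
        rec = (0.55 * trial.sensor(SensorId.PELVIS).vertical
               + 0.23 * (trial.sensor(SensorId.TIBIA_LEFT).vertical
                         + trial.sensor(SensorId.TIBIA_RIGHT).vertical))
        interior = slice(200, -200)
        assert np.abs(rec[interior] - a_com[interior]).max() < 0.05

    def test_mass_invariance_of_accelerations(self, noise_free_cfg):
        meta = TrialMeta(12.0, "preferred", 30.0)
        t1, _ = simulate_trial(meta, SubjectInfo("A", 60.0),
                               np.random.default_rng(5), noise_free_cfg)
        t2, _ = simulate_trial(meta, SubjectInfo("B", 120.0),
                               np.random.default_rng(5), noise_free_cfg)
        for sid in SensorId:
            np.testing.assert_allclose(t1.sensor(sid).acc, t2.sensor(sid).acc,
                                       atol=1e-9)

    def test_injected_offset_delays_force(self, subject, noise_free_cfg):
        """Force foot strikes lag the acceleration transients by exactly the
        injected offset (compared at the sensor rate)."""
        meta = TrialMeta(12.0, "preferred", 30.0)
        trial, truth = simulate_trial(meta, subject, np.random.default_rng(3),
                                      noise_free_cfg)
        k = truth.offset_samples
        t240 = np.arange(truth.grf.shape[0]) / 240.0
        tf = np.arange(trial.force.n_samples) / 2048.0
        v240 = np.interp(t240, tf, trial.force.vertical)
        # undo the delay and compare with truth
        shifted = np.interp(t240 + k / 240.0, t240, v240, left=0, right=0)
        interior = slice(600, -600)
        err = shifted[interior] - truth.grf[interior, 2]
        # two linear interpolations (240->2048->240) leave only knot error
        assert np.abs(err).max() < 0.005 * truth.grf[:, 2].max()


class TestCohortGeneration:
    def test_default_protocol_size(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=3, duration_s=4.0, seed=2)
        paths = generate_cohort(cfg, tmp_path)
        assert len(paths) == 3 * 9

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=2, velocities_kmh=(10.0,),
                              sf_conditions=("preferred",), duration_s=4.0, seed=9)
        generate_cohort(cfg, tmp_path / "a")
        generate_cohort(cfg, tmp_path / "b")
        for p in sorted((tmp_path / "a").rglob("*")):
            if p.is_file():
                q = tmp_path / "b" / p.relative_to(tmp_path / "a")
                assert p.read_bytes() == q.read_bytes(), p.name

    def test_mass_distribution(self):
        cfg = GeneratorConfig(n_subjects=1000)
        subjects = sample_subjects(cfg, np.random.default_rng(0))
        masses = np.array([s.body_mass_kg for s in subjects])
        assert masses.mean() == pytest.approx(73.7, abs=2.0)
        assert np.all((masses > 40) & (masses < 120))
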