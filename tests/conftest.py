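import numpy as np
import pytest

from grf3d import GeneratorConfig, SubjectInfo, TrialMeta
from grf3d.simulate import simulate_trial


@pytest.fixture(scope="session")
def subject():
    return SubjectInfo("S01", 70.0)


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Generator config with every stochastic disturbance switched off."""
    return GeneratorConfig(sensor_noise_sd_ms2=0.0, impact_transient_ms2=0.0,
                           swing_amp_ms2=0.0, subject_gain_sd=0.0,
                           duration_s=30.0)


@pytest.fixture(scope="session")
def clean_trial(subject, noise_free_cfg):
    """One noise-free trial at the central protocol condition."""
    meta = TrialMeta(12.0, "preferred", 30.0)
    rng = np.random.default_rng(1)
    return simulate_trial(meta, subject, rng, noise_free_cfg)


@pytest.fixture(scope="session")
def default_trial(subject):
    """One trial with all default disturbances on."""
    cfg = GeneratorConfig(duration_s=30.0)
    meta = TrialMeta(12.0, "preferred", 30.0)
    rng = np.random.default_rng(7)
    return simulate_trial(meta, subject, rng, cfg)
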