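import numpy as np
import pytest

import wearagree as wa


@pytest.fixture(scope="session")
def clean_ppg_70bpm():
    """Noise-free 90-s pulse wave at 70 bpm with slight beat jitter."""
    cfg = wa.PpgSimConfig(mean_hr_bpm=70, hr_sd_bpm=0, ibi_jitter_sd_s=0.02,
                          seed=11)
    return wa.simulate_ppg(cfg, fs=64)


@pytest.fixture(scope="session")
def conditioned_ppg(clean_ppg_70bpm):
    sig, truth = clean_ppg_70bpm
    cleaned, mask = wa.clean_ppg(sig)
    return cleaned, mask, truth


@pytest.fixture(scope="session")
def eda_session_with_scrs():
    """Noise-free 90-s EDA trace with three SCRs and a drifting tonic."""
    cfg = wa.EdaSimConfig(scr_rate_per_min=2, tonic_drift_us_per_min=0.3,
                          seed=3)
    return wa.simulate_eda(cfg, fs=64)


@pytest.fixture(scope="session")
def zero_noise_run():
    """Small zero-noise cohort pushed through the whole pipeline."""
    from wearagree.pipeline import RunConfig, run_pipeline

    cfg = RunConfig(seed=3, n_subjects=3, profiles=wa.zero_noise_profiles())
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_noise_run():
    """Default-noise cohort (study conditions) through the whole pipeline."""
    from wearagree.pipeline import RunConfig, run_pipeline

    return run_pipeline(RunConfig(seed=7, n_subjects=6))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
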