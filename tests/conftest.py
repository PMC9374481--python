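import numpy as np
import pytest

from visent.pipeline import load_config, run_pipeline
from visent.synth import SyntheticConfig, build_leadfield


@pytest.fixture(scope="session")
def leadfield():
    return build_leadfield((4, 4, 4), n_sensors=24, seed=3)


@pytest.fixture(scope="session")
def quiet_config():
    """Deterministic, noise-free single-subject configuration."""
    return SyntheticConfig(
        n_group={"ADS": 1, "HC": 1},
        n_trials=8,
        A_abs={"ADS": (1.0, 0.0), "HC": (1.0, 0.0)},
        cv_trial={"ADS": 0.0, "HC": 0.0},
        B_base={"ADS": (0.0, 0.0), "HC": (0.0, 0.0)},
        harmonic_gains=(),
        aperiodic=(-60.0, 1.0),  # effectively silent background
        sensor_noise_sd=0.0,
        artifact_rate=0.0,
    )


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run with the default demo configuration."""
    out = tmp_path_factory.mktemp("demo_run")
    config = load_config(overrides={"master_seed": 1})
    run_pipeline(config, out)
    return out
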