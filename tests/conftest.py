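import numpy as np
import pytest

from acsmon.config import (EpisodeConfig, HemoState, OpticalConstants,
                           RampStep, ThermalModelParams)


@pytest.fixture
def optical() -> OpticalConstants:
    return OpticalConstants()


@pytest.fixture
def hemo() -> HemoState:
    return HemoState()


@pytest.fixture
def thermal_params() -> ThermalModelParams:
    return ThermalModelParams()


@pytest.fixture
def quiet_episode() -> EpisodeConfig:
    """Short noiseless episode with the standard stepped loading."""
    return EpisodeConfig(
        duration=480.0,
        sample_rate=10.0,
        icp_profile=[
            RampStep(start=0.0, target=0.0, ramp=0.0),
            RampStep(start=90.0, target=50.0, ramp=30.0),
            RampStep(start=210.0, target=100.0, ramp=30.0),
            RampStep(start=330.0, target=150.0, ramp=30.0),
        ],
        flow_lag_tau=5.0,
        ac_fraction=0.0,
        noise_sd={"pressure": 0.0, "ppg": 0.0, "thermistor": 0.0},
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
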