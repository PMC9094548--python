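import numpy as np
import pytest

from pvpsim import (
    LungParams,
    SensorModel,
    SimConfig,
    VentSettings,
    run_simulation,
)

ZERO_NOISE = SensorModel(pressure_noise_sd=0.0, flow_noise_sd=0.0)


@pytest.fixture(scope="session")
def zero_noise():
    return ZERO_NOISE


@pytest.fixture(scope="session")
def midpoint_settings():
    """Adult midpoint bench condition: PIP 30, PEEP 5, RR 15, I:E 1:2."""
    return VentSettings(
        pip_target=30.0, peep_setting=5.0, respiratory_rate=15.0, ie_ratio=2.0
    )


@pytest.fixture(scope="session")
def midpoint_lung():
    return LungParams(compliance=20.0, resistance=20.0)


@pytest.fixture(scope="session")
def midpoint_result(midpoint_settings, midpoint_lung):
    """A settled 8-cycle zero-noise run at the midpoint condition (shared
    across tests; read-only)."""
    config = SimConfig(
        settings=midpoint_settings,
        lung=midpoint_lung,
        sensors=ZERO_NOISE,
        n_cycles=8,
        seed=0,
    )
    return run_simulation(config)


@pytest.fixture(scope="session")
def pediatric_config():
    """Pediatric bench condition: R 25, C 10, PIP 20, PEEP 5, RR 25,
    t_insp 0.6 s, 400 mL residual capacity."""
    return SimConfig(
        settings=VentSettings(
            pip_target=20.0, peep_setting=5.0, respiratory_rate=25.0, t_insp=0.6
        ),
        lung=LungParams(compliance=10.0, resistance=25.0, residual_capacity=400.0),
        n_cycles=60,
        seed=1,
    )
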