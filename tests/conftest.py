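import numpy as np
import pytest

from groundflow.controller import ControllerParams, SimulationConfig, simulate_flight
from groundflow.synthio import CohortSpec, generate_cohort
from groundflow.tunnel import RodConfiguration, TextureCondition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def level_flight():
    """Noise-free control flight: parallel rods, striped ground."""
    cfg = SimulationConfig(
        rods=RodConfiguration(mode="parallel"),
        texture=TextureCondition(kind="striped"),
        duration=4.0,
    )
    return simulate_flight(cfg, ControllerParams(), flight_id="level")


@pytest.fixture
def small_cohort():
    """Quick 3-flight null cohort with noise, for I/O and pipeline tests."""
    spec = CohortSpec(
        n_flights=3,
        conditions=(("parallel", "white"),),
        duration=3.0,
        seed=7,
    )
    return generate_cohort(spec)
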