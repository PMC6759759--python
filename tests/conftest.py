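import numpy as np
import pytest

from phageres.design import Lineage, SelectionRegime, default_design
from phageres.growth import GrowthCurve
from phageres.synthetic import SimulationConfig, TrueLineageParams


@pytest.fixture
def design():
    return default_design()


@pytest.fixture
def quiet_config():
    """Noise-free simulation config for exact-recovery tests."""
    return SimulationConfig(seed=7, noise_sd=0.0)


def make_params(
    r: float = 0.9,
    cost: float = 0.0,
    phage: str = "P1",
    ancestor: str = "PAO1_FT1",
    lag_h: float = 2.0,
    capacity_od: float = 1.0,
    sv_events=(),
) -> TrueLineageParams:
    lineage = Lineage(ancestor, SelectionRegime("first_step", (phage,)), "r1")
    return TrueLineageParams(
        lineage=lineage,
        resistance={phage: r},
        fitness_cost=cost,
        lag_h=lag_h,
        capacity_od=capacity_od,
        sv_events=list(sv_events),
    )


def logistic_curve(
    rate: float = 1.0,
    capacity: float = 1.0,
    t_mid: float = 12.0,
    duration: float = 24.0,
    dt: float = 0.5,
    lineage: str = "L",
    condition: str = "no_phage",
) -> GrowthCurve:
    t = np.arange(0.0, duration + 1e-9, dt)
    od = capacity / (1.0 + np.exp(-rate * (t - t_mid)))
    return GrowthCurve(lineage, condition, t, od)
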