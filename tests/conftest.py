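import numpy as np
import pytest

from ternabind.model import BindingParameters, ExperimentSetup, SystemState

#: Tiny positive stand-in for a switched-off rate constant (rates must be > 0).
OFF = 1e-300


def make_params(**overrides) -> BindingParameters:
    """All-rates-off parameter set with selected rates switched on."""
    base = {name: OFF for name in ("kf1", "kf2", "kf3", "kf4", "kr1", "kr2", "kr3", "kr4")}
    base.update(overrides)
    return BindingParameters(**base)


def random_params(rng: np.random.Generator, decades: float = 4.0) -> BindingParameters:
    """Log-uniform rate draw spanning ``decades`` orders of magnitude."""
    kf = 10.0 ** rng.uniform(-3.0, -3.0 + decades, 4) * 1e-1  # 1e-4 .. 1e-4*10^decades
    kr = 10.0 ** rng.uniform(-4.0, -4.0 + decades, 4)
    return BindingParameters(*kf, *kr)


def random_state(rng: np.random.Generator) -> SystemState:
    return SystemState(*rng.uniform(0.01, 10.0, 6))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_setup() -> ExperimentSetup:
    """Small co-incubation design with a short log-spaced dose grid."""
    return ExperimentSetup(
        n_effector_cells=1e5,
        n_target_cells=2e5,
        receptors_per_effector=1e5,
        antigens_per_target=2e4,
        volume_ml=0.2,
        antibody_mw=150_000.0,
        dose_grid=tuple(np.geomspace(1e-4, 1e1, 12)),
        t_max=1e7,
    )


@pytest.fixture
def moderate_params() -> BindingParameters:
    """A well-conditioned full system (all four reactions active)."""
    return BindingParameters(
        kf1=3e-3, kf2=1e-3, kf3=1e-3, kf4=3e-3, kr1=1e-3, kr2=5e-4, kr3=5e-4, kr4=1e-3
    )
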