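import numpy as np
import pytest

from dermafem import (
    CellGeometry,
    InterfaceSpec,
    LayerSpec,
    ModelConfig,
    simulate,
    study_default_config,
)
from dermafem.synthetic import ENDPOINT_TIME, default_sampling_times


def make_slab_config(
    D: float = 0.01,
    total_length: float = 1.0,
    c0: float = 1.0,
    n_elements: int = 2,
    area: float = 1.0,
) -> ModelConfig:
    """Four equal layers, P = 1 everywhere, equilibrium interfaces, equal D.

    Algebraically a single homogeneous slab with no-flux walls and the drug
    initially confined to the first quarter — the continuity limit used to
    compare against the analytic slab series solution.
    """
    quarter = total_length / 4
    layers = tuple(
        LayerSpec(name, quarter, D, c0 if name == "DC" else 0.0, n_elements)
        for name in ("DC", "SC", "RS", "RC")
    )
    interfaces = tuple(InterfaceSpec(i, 1.0, "equilibrium") for i in (1, 2, 3))
    return ModelConfig(
        geometry=CellGeometry(area=area, donor_volume=area * quarter,
                              receptor_volume=area * quarter),
        layers=layers,
        interfaces=interfaces,
        well_mixed_diffusivity=D,
    )


@pytest.fixture(scope="session")
def study():
    """Packaged study configuration with its Case 2 true parameters."""
    return study_default_config()


@pytest.fixture(scope="session")
def study_schedule():
    """Receiver sampling times plus the 51.5 h endpoint."""
    return np.unique(np.concatenate([default_sampling_times(), [ENDPOINT_TIME]]))


@pytest.fixture(scope="session")
def study_result(study, study_schedule):
    """One full-resolution forward run of the study configuration."""
    config, _ = study
    return simulate(config, study_schedule, dt=0.01)


@pytest.fixture(scope="session")
def fast_study():
    """Coarse variant used where many fits are run: exact self-consistency
    still holds because observations and fits share the forward model."""
    return study_default_config(n_elements=(2, 16, 24, 4))


FAST_DT = 0.05
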