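"""Synthetic Franz-cell experiments with known ground truth.

Emulates the study conditions: a 0.64 cm^2 exposure area, 1 mL donor loaded
with 5 mg/mL diclofenac sodium, a 12 mL stirred receptor, receptor sampling
at regular intervals over ~50 h, and endpoint tape-strip / residual-skin
drug content at 51.5 h.  Observation noise, when enabled, is multiplicative
Gaussian with a configurable coefficient of variation, mimicking the
between-replicate scatter of permeation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .config import (
    CellGeometry,
    InterfaceSpec,
    LayerSpec,
    ModelConfig,
    apply_parameters,
)
from .config import layer_volume
from .estimation import ObservationSet
from .fem import SimulationResult, simulate
from .observables import median_concentration

__all__ = [
    "NoiseModel",
    "CASE1_PARAMETERS",
    "CASE2_PARAMETERS",
    "study_default_config",
    "default_sampling_times",
    "generate_observations",
    "observations_from_result",
]

#: Case 1 estimates (three-layer reduction: P_2 pinned at unity).
CASE1_PARAMETERS: dict[str, float] = {
    "D_SC": 1.03e-4,  # cm^2/h
    "P_1": 4.97,
    "P_2": 1.00,
    "P_3": 0.102,
    "K_3": 0.054,  # cm/h
}

#: Case 2 estimates (all five permeation parameters free).
CASE2_PARAMETERS: dict[str, float] = {
    "D_SC": 1.49e-4,  # cm^2/h
    "P_1": 4.84,
    "P_2": 0.96,
    "P_3": 0.111,
    "K_3": 0.043,  # cm/h
}

#: Measured diffusivity of the rest-of-skin layer, cm^2/h.
D_RS_MEASURED = 1.80e-3

#: Endpoint (tape stripping / residual analysis) time, h.
ENDPOINT_TIME = 51.5

# Geometry defaults.  The SC thickness of dermatomed porcine ear skin is
# taken as 20 um; the full dermatomed membrane is ~1 mm, so RS makes up the
# remaining 0.098 cm.  Both are configurable.
SC_THICKNESS = 0.002  # cm
TOTAL_SKIN_THICKNESS = 0.1  # cm


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise specification.

    ``multiplicative_gaussian`` scales every observed value by
    ``1 + cv * z`` with ``z ~ N(0, 1)``, clipped at zero; ``none`` passes
    simulator output through bit-for-bit.
    """

    kind: Literal["none", "multiplicative_gaussian"] = "none"
    cv: float = 0.05
    seed: int = 0


def study_default_config(
    parameters: Mapping[str, float] | None = None,
    sc_thickness: float = SC_THICKNESS,
    total_skin_thickness: float = TOTAL_SKIN_THICKNESS,
    n_elements: tuple[int, int, int, int] = (4, 40, 60, 8),
    well_mixed_diffusivity: float = 1e4,
    donor_concentration: float = 5.0,
) -> tuple[ModelConfig, dict[str, float]]:
    """The packaged study configuration and its true permeation parameters.

    Returns ``(config, params)`` where ``params`` defaults to the Case 2
    parameter set and is already applied to ``config``.  Donor and receptor
    thicknesses follow from the chamber volumes and the exposure area.
    """
    params = dict(CASE2_PARAMETERS if parameters is None else parameters)
    geometry = CellGeometry(area=0.64, donor_volume=1.0, receptor_volume=12.0)
    rs_thickness = total_skin_thickness - sc_thickness
    layers = (
        LayerSpec("DC", geometry.donor_thickness, well_mixed_diffusivity,
                  donor_concentration, n_elements[0]),
        LayerSpec("SC", sc_thickness, CASE2_PARAMETERS["D_SC"], 0.0, n_elements[1]),
        LayerSpec("RS", rs_thickness, D_RS_MEASURED, 0.0, n_elements[2]),
        LayerSpec("RC", geometry.receptor_thickness, well_mixed_diffusivity,
                  0.0, n_elements[3]),
    )
    interfaces = (
        InterfaceSpec(1, partition=1.0, mode="equilibrium"),
        InterfaceSpec(2, partition=1.0, mode="equilibrium"),
        InterfaceSpec(3, partition=1.0, mode="finite", transfer=1.0),
    )
    config = ModelConfig(
        geometry=geometry,
        layers=layers,
        interfaces=interfaces,
        well_mixed_diffusivity=well_mixed_diffusivity,
    )
    return apply_parameters(config, params), params


def default_sampling_times() -> np.ndarray:
    """Receptor sampling every 2 h from 2 h to 50 h (endpoint 51.5 h extra)."""
    return np.arange(2.0, 50.0 + 1e-9, 2.0)


def _apply_noise(values: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none":
        return values
    if noise.kind == "multiplicative_gaussian":
        scaled = values * (1.0 + noise.cv * rng.standard_normal(values.shape))
        return np.clip(scaled, 0.0, None)
    raise ValueError(f"unknown noise kind {noise.kind!r}")


def observations_from_result(
    result: SimulationResult,
    sampling_times: np.ndarray,
    endpoint_time: float,
    noise: NoiseModel = NoiseModel(),
) -> ObservationSet:
    """Extract an ObservationSet from an existing simulation.

    Lets noisy replicates share one forward solve: re-noising the same
    noise-free truth with different seeds is how replicate datasets are made.

    Endpoint drug content is observed through the same per-layer summary the
    inverse problem uses: the reported mass is the layer's median nodal
    concentration times its volume.  At the endpoint the skin profiles are
    nearly linear, so this differs from the integrated mass only at the
    1e-3 relative level, but using one observation operator on both sides
    keeps noise-free self-consistency fits exactly unbiased.
    """
    series_times = np.asarray(sampling_times, dtype=float)
    if series_times[-1] < endpoint_time:
        series_times = np.append(series_times, endpoint_time)
    rng = np.random.default_rng(noise.seed)
    receiver = np.array([
        result.layer_mass("RC")[result.time_index(t)] for t in series_times
    ])
    endpoint = {
        name: median_concentration(result, name, endpoint_time)
        * layer_volume(result.config.geometry, result.config.layer(name))
        for name in ("DC", "SC", "RS")
    }
    receiver = _apply_noise(receiver, noise, rng)
    noisy_endpoint_vals = _apply_noise(
        np.array([endpoint["DC"], endpoint["SC"], endpoint["RS"]]), noise, rng
    )
    endpoint = dict(zip(("DC", "SC", "RS"), (float(v) for v in noisy_endpoint_vals)))
    return ObservationSet(
        times=series_times,
        receiver_mass=receiver,
        endpoint_time=float(endpoint_time),
        endpoint_masses=endpoint,
    )


def generate_observations(
    config: ModelConfig,
    true_params: Mapping[str, float] | None = None,
    sampling_times: np.ndarray | None = None,
    endpoint_time: float = ENDPOINT_TIME,
    noise: NoiseModel = NoiseModel(),
    dt: float = 0.01,
    refinement: float = 1,
) -> ObservationSet:
    """Forward-simulate and observe: the full synthetic-experiment pipeline.

    ``true_params`` (if given) override the permeation parameters in
    ``config``.  Receiver mass is read at ``sampling_times`` (default: every
    2 h to 50 h) plus the endpoint; donor/SC/RS masses are read at
    ``endpoint_time`` only, mirroring endpoint tape stripping.
    """
    if true_params is not None:
        config = apply_parameters(config, true_params)
    if sampling_times is None:
        sampling_times = default_sampling_times()
    sampling_times = np.asarray(sampling_times, dtype=float)
    if np.any(sampling_times <= 0) or np.any(sampling_times > endpoint_time):
        raise ValueError("sampling_times must lie within (0, endpoint_time]")
    output_times = np.unique(np.concatenate([sampling_times, [endpoint_time]]))
    result = simulate(config, output_times, dt=dt, refinement=refinement)
    return observations_from_result(result, sampling_times, endpoint_time, noise)
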