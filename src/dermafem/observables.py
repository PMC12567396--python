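"""Observable quantities derived from simulated concentration fields.

These are the quantities the experiment actually reports: drug mass per
compartment (spatial integration with the same consistent-mass quadrature
the solver uses, so conservation carries over discretely), the median
nodal concentration per layer (the robust summary used for endpoint
residuals), and the replacement-dilution bookkeeping applied to raw
receptor samples in standard Franz-cell practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import SimulationResult

__all__ = [
    "CompartmentSummary",
    "mass_in_layer",
    "median_concentration",
    "summarize",
    "sampling_correction",
]


@dataclass(frozen=True)
class CompartmentSummary:
    """Per-compartment masses (mg) and median concentrations (mg/cm^3)."""

    time: float
    masses: dict[str, float]
    median_concentrations: dict[str, float]


def mass_in_layer(result: SimulationResult, layer: str, t: float) -> float:
    """Drug mass (mg) in one layer at an output time.

    Uses the mass trajectories recorded by the solver
    (``1^T M_layer c``, i.e. area times the consistent-mass quadrature of
    the nodal field), so summing over layers reproduces the conserved total.
    """
    idx = result.time_index(t)  # raises KeyError naming the time
    return float(result.layer_mass(layer)[idx])


def median_concentration(result: SimulationResult, layer: str, t: float) -> float:
    """Median nodal concentration (mg/cm^3) of a layer at an output time.

    Even node counts use the midpoint-average convention (numpy's median).
    """
    idx = result.time_index(t)
    try:
        layer_pos = result.layer_names.index(layer)
    except ValueError:
        raise KeyError(
            f"unknown layer {layer!r}; expected one of {result.layer_names}"
        ) from None
    sl = result.mesh.layer_slices[layer_pos]
    return float(np.median(result.states[idx].values[sl]))


def summarize(result: SimulationResult, t: float) -> CompartmentSummary:
    """Masses and median concentrations of all four compartments at time t."""
    return CompartmentSummary(
        time=t,
        masses={name: mass_in_layer(result, name, t) for name in result.layer_names},
        median_concentrations={
            name: median_concentration(result, name, t) for name in result.layer_names
        },
    )


def sampling_correction(
    series,
    sample_volume: float,
    receptor_volume: float,
) -> np.ndarray:
    """Cumulative receiver mass (mg) from raw sampled concentrations.

    Each withdrawal removes ``sample_volume`` of receptor fluid (and its
    drug) and replaces it with fresh buffer, so the cumulative mass at
    sample n is the mass currently in the receptor plus everything removed
    before it::

        M_n = V_r * C_n + V_s * sum_{k<n} C_k

    ``series`` is a sequence of (time_h, concentration_mg_per_cm3) pairs
    with strictly increasing times; returns the cumulative masses.
    """
    if not sample_volume >= 0 or not receptor_volume > 0:
        raise ValueError("volumes must be positive (sample volume may be 0)")
    if sample_volume >= receptor_volume:
        raise ValueError(
            f"sample_volume {sample_volume} must be smaller than "
            f"receptor_volume {receptor_volume}"
        )
    arr = np.asarray(list(series), dtype=float)
    if arr.size == 0:
        return np.zeros(0)
    times, conc = arr[:, 0], arr[:, 1]
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    removed_before = sample_volume * (np.cumsum(conc) - conc)
    return receptor_volume * conc + removed_before
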