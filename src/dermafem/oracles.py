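"""Independent reference solutions for verifying the FEM solver.

Four oracles, deliberately sharing no assembly code with :mod:`dermafem.fem`:

* :func:`analytic_slab_solution` — cosine-eigenfunction series for a single
  homogeneous slab with no-flux walls (the continuity limit of the model);
* :func:`equilibrium_state` — closed-form t -> infinity state: uniform per
  layer, with the partition ratio across each interface and total mass
  conserved;
* :func:`steady_state_solution` — exact piecewise-linear steady profile and
  flux across SC + RS with fixed end concentrations (series-resistance
  algebra including partition and interfacial resistance);
* :func:`fd_reference` — a cell-centered finite-volume discretization with
  interface flux matching, integrated implicitly, for two-solver
  cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.integrate
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import ModelConfig, layer_volume, validate_config

__all__ = [
    "EquilibriumState",
    "SteadyState",
    "FDResult",
    "analytic_slab_solution",
    "equilibrium_state",
    "steady_state_solution",
    "fd_reference",
]


def analytic_slab_solution(
    D: float,
    L: float,
    initial_profile: Callable[[float], float],
    t: float,
    x,
    series_tol: float = 1e-14,
) -> np.ndarray | float:
    """Series solution of the 1D diffusion equation with no-flux walls.

    ``C(x, t) = a_0 + sum_n a_n cos(n pi x / L) exp(-D (n pi / L)^2 t)``,
    with coefficients from numerical quadrature of ``initial_profile``.
    The series is truncated once the decayed amplitude bound of the next
    term falls below ``series_tol`` (a hard cap protects t = 0, where a
    discontinuous profile has a slowly converging series).
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))

    def coeff(n: int) -> float:
        if n == 0:
            val, _ = scipy.integrate.quad(initial_profile, 0, L, limit=500)
            return val / L
        val, _ = scipy.integrate.quad(
            lambda s: initial_profile(s) * math.cos(n * math.pi * s / L),
            0, L, limit=500,
        )
        return 2.0 * val / L

    a0 = coeff(0)
    out = np.full_like(x_arr, a0)
    mean_abs, _ = scipy.integrate.quad(lambda s: abs(initial_profile(s)), 0, L,
                                       limit=500)
    amp_bound = max(2.0 * mean_abs / L, abs(a0), 1e-300)
    n = 1
    while n < 100_000:
        decay = math.exp(-D * (n * math.pi / L) ** 2 * t)
        # individual coefficients may vanish by symmetry, so truncation
        # relies on the uniform bound |a_n| <= 2 mean|f| times the decay
        if decay * amp_bound < series_tol and n > 2:
            break
        a_n = coeff(n)
        out += a_n * decay * np.cos(n * np.pi * x_arr / L)
        n += 1
    return out if np.ndim(x) else float(out[0])


@dataclass(frozen=True)
class EquilibriumState:
    """Uniform-per-layer equilibrium concentrations (mg/cm^3), keyed by layer."""

    concentrations: dict[str, float]

    def as_array(self, layer_names) -> np.ndarray:
        return np.array([self.concentrations[n] for n in layer_names])


def equilibrium_state(config: ModelConfig, total_mass: float) -> EquilibriumState:
    """Closed-form t -> infinity state of the four-layer system.

    At equilibrium each layer is uniform and the jump across interface i is
    exactly ``P_i``, so with ``c_1`` the donor concentration the layer
    concentrations are ``c_1 * prod(P_j, j < i)`` and mass conservation
    gives ``c_1 = M_total / (V_1 + V_2 P_1 + V_3 P_1 P_2 + V_4 P_1 P_2 P_3)``.
    """
    if total_mass < 0:
        raise ValueError(f"total_mass must be >= 0, got {total_mass}")
    partitions = [itf.partition for itf in config.interfaces]
    cum = np.concatenate([[1.0], np.cumprod(partitions)])  # relative conc per layer
    volumes = np.array([layer_volume(config.geometry, lay) for lay in config.layers])
    c1 = total_mass / float(volumes @ cum)
    return EquilibriumState(
        {lay.name: c1 * cum[i] for i, lay in enumerate(config.layers)}
    )


@dataclass(frozen=True)
class SteadyState:
    """Steady profile across SC + RS with fixed boundary concentrations.

    ``x`` (cm, measured from the SC outer face) and ``concentration`` give
    the piecewise-linear profile as four points: SC left/right face, RS
    left/right face; ``flux`` (mg cm^-2 h^-1) is the constant flux through
    every layer and interface.
    """

    x: np.ndarray
    concentration: np.ndarray
    flux: float


def steady_state_solution(
    config: ModelConfig, c_left: float, c_right: float
) -> SteadyState:
    """Exact steady state of the skin (SC + RS) between fixed concentrations.

    ``c_left`` is the donor-side concentration upstream of interface 1 and
    ``c_right`` the receptor-side concentration downstream of interface 3.
    Partition steps and finite interfacial resistances combine with the two
    diffusive resistances ``L/D`` in series; equilibrium interfaces
    contribute no kinetic resistance.
    """
    if c_left < 0 or c_right < 0:
        raise ValueError("boundary concentrations must be >= 0")
    sc, rs = config.layer("SC"), config.layer("RS")
    i1, i2, i3 = (config.interface(i) for i in (1, 2, 3))
    p1, p2, p3 = i1.partition, i2.partition, i3.partition
    inv_k1 = 0.0 if i1.mode == "equilibrium" else 1.0 / i1.transfer
    inv_k2 = 0.0 if i2.mode == "equilibrium" else 1.0 / i2.transfer
    inv_k3 = 0.0 if i3.mode == "equilibrium" else 1.0 / i3.transfer

    resistance = (
        p1 * p2 * inv_k1
        + p2 * sc.thickness / sc.diffusivity
        + p2 * inv_k2
        + rs.thickness / rs.diffusivity
        + inv_k3
    )
    flux = (p1 * p2 * c_left - c_right / p3) / resistance

    c_sc_left = p1 * (c_left - flux * inv_k1)
    c_sc_right = c_sc_left - flux * sc.thickness / sc.diffusivity
    c_rs_left = p2 * (c_sc_right - flux * inv_k2)
    c_rs_right = c_rs_left - flux * rs.thickness / rs.diffusivity
    x = np.array([0.0, sc.thickness, sc.thickness, sc.thickness + rs.thickness])
    conc = np.array([c_sc_left, c_sc_right, c_rs_left, c_rs_right])
    return SteadyState(x=x, concentration=conc, flux=float(flux))


@dataclass
class FDResult:
    """Finite-volume reference output (cell-centered states, layer masses)."""

    times: np.ndarray
    layer_masses: np.ndarray  # (n_times, n_layers), mg
    layer_names: tuple[str, ...]
    cell_centers: np.ndarray
    states: np.ndarray  # (n_times, n_cells), mg/cm^3

    def layer_mass(self, name: str) -> np.ndarray:
        return self.layer_masses[:, self.layer_names.index(name)]

    def time_index(self, t: float) -> int:
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=1e-10, atol=1e-12))
        if idx.size == 0:
            raise KeyError(f"time {t} h is not an output time")
        return int(idx[0])


def fd_reference(
    config: ModelConfig,
    output_times,
    n_cells_per_layer=None,
    dt: float = 0.01,
) -> FDResult:
    """Cell-centered finite-volume solution of the same four-layer problem.

    Within-layer faces carry the usual two-point flux; at a layer interface
    the two half-cell diffusive resistances and the interfacial condition
    are combined by eliminating the face concentrations::

        F = A (c_L - c_R / P) / (1/K + h_L/(2 D_L) + h_R/(2 P D_R))

    (``1/K = 0`` for equilibrium interfaces).  Column sums of the flux
    operator vanish, so mass is conserved discretely.  Backward Euler in
    time, with the same exact-landing output policy as the FEM path.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    times = np.asarray(output_times, dtype=float)
    if times.size == 0:
        raise ValueError("output_times must not be empty")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("output_times must be strictly increasing and >= 0")
    if n_cells_per_layer is None:
        n_cells_per_layer = [lay.n_elements for lay in config.layers]

    area = config.geometry.area
    widths, diffs, centers, c0 = [], [], [], []
    x_left = 0.0
    layer_slices = []
    offset = 0
    for lay, n_cells in zip(config.layers, n_cells_per_layer):
        h = lay.thickness / n_cells
        widths.extend([h] * n_cells)
        diffs.extend([lay.diffusivity] * n_cells)
        centers.extend(x_left + h * (np.arange(n_cells) + 0.5))
        c0.extend([lay.initial_concentration] * n_cells)
        layer_slices.append(slice(offset, offset + n_cells))
        offset += n_cells
        x_left += lay.thickness
    widths = np.array(widths)
    diffs = np.array(diffs)
    c = np.array(c0, dtype=float)
    n = len(widths)
    volumes = area * widths

    # face conductances G (mg per h per unit concentration difference
    # expression); build the divergence operator L with L c = net outflow
    interface_faces = {layer_slices[k].stop: config.interfaces[k] for k in range(3)}
    lmat = sp.lil_matrix((n, n))
    for f in range(1, n):  # face between cells f-1 and f
        left, right = f - 1, f
        itf = interface_faces.get(f)
        if itf is None:
            # within-layer: harmonic combination of the two half-cells
            r = widths[left] / (2 * diffs[left]) + widths[right] / (2 * diffs[right])
            g = area / r
            lmat[left, left] += g
            lmat[left, right] -= g
            lmat[right, left] -= g
            lmat[right, right] += g
        else:
            p = itf.partition
            inv_k = 0.0 if itf.mode == "equilibrium" else 1.0 / itf.transfer
            r = inv_k + widths[left] / (2 * diffs[left]) + widths[right] / (
                2 * p * diffs[right]
            )
            g = area / r
            lmat[left, left] += g
            lmat[left, right] -= g / p
            lmat[right, left] -= g
            lmat[right, right] += g / p
    lmat = lmat.tocsr()
    vol_mat = sp.diags(volumes).tocsr()

    factors: dict[float, object] = {}

    def advance(state: np.ndarray, h: float) -> np.ndarray:
        lu = factors.get(h)
        if lu is None:
            lu = spla.splu((vol_mat + h * lmat).tocsc())
            factors[h] = lu
        return lu.solve(volumes * state)

    t_now = 0.0
    states = np.zeros((times.size, n))
    masses = np.zeros((times.size, len(config.layers)))
    for i, t_out in enumerate(times):
        if t_out > t_now:
            span = t_out - t_now
            n_sub = max(1, math.ceil(span / dt - 1e-9))
            h = span / n_sub
            for _ in range(n_sub):
                c = advance(c, h)
            t_now = float(t_out)
        states[i] = c
        masses[i] = [volumes[sl] @ c[sl] for sl in layer_slices]

    return FDResult(
        times=times,
        layer_masses=masses,
        layer_names=tuple(lay.name for lay in config.layers),
        cell_centers=np.array(centers),
        states=states,
    )
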