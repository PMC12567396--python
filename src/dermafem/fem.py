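"""Linear-element FEM discretization and implicit time stepping.

Each layer is discretized with 1D linear elements; the semi-discrete system
is ``M dc/dt + A c = 0`` with

* ``M`` — consistent (optionally lumped) mass matrix, block-diagonal by
  layer and scaled by the exposure area, so ``1^T M c`` is drug mass in mg;
* ``A`` — within-layer diffusion stiffness plus, for finite interfaces,
  the Robin-type coupling ``K_i (C_i - C_{i+1}/P_i)`` entering rows of the
  two coincident interface nodes with opposite signs (column sums vanish,
  which is discrete mass conservation).

Equilibrium interfaces (the ``K -> inf`` limit) are handled by exact
degree-of-freedom elimination: the downstream node is a slave equal to
``P_i`` times the upstream master, and the slave's residual row is added to
the master's row (the interface flux, an internal Lagrange multiplier,
cancels in the sum).  The resulting Petrov-Galerkin reduction conserves
``1^T M c`` identically for any partition coefficient.

Time integration is backward Euler: ``(S M T + dt S A T) c_r = S M c_old``,
where ``S`` restricts (summing slave rows into masters) and ``T`` prolongs
(slave = P x master).  Factorizations of the step matrix are cached per dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import ModelConfig, validate_config
from .mesh import Mesh, build_mesh

__all__ = [
    "DiscreteSystem",
    "ConcentrationState",
    "SimulationResult",
    "assemble_system",
    "step",
    "simulate",
]


@dataclass(frozen=True)
class ConcentrationState:
    """Nodal concentration field (mg/cm^3) over all DOFs at one instant."""

    time: float
    values: np.ndarray


@dataclass
class DiscreteSystem:
    """Assembled operators for one mesh/config pair."""

    mesh: Mesh
    config: ModelConfig
    mass: sp.csr_matrix          # full-space M, mg per (mg/cm^3)
    transport: sp.csr_matrix     # full-space A (stiffness + finite coupling)
    constraint_map: dict[int, tuple[int, float]]  # slave -> (master, P)
    restriction: sp.csr_matrix   # S: full residual rows -> reduced rows
    prolongation: sp.csr_matrix  # T: reduced values -> full values
    retained: np.ndarray         # global indices of reduced DOFs
    layer_mass_weights: np.ndarray  # (4, n_dof): 1_layer^T M
    pinned: tuple[float | None, float | None] = (None, None)
    _reduced: dict = field(default_factory=dict, repr=False)
    _factors: dict = field(default_factory=dict, repr=False)

    def reduced_operators(self) -> tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]:
        """(S M, S M T, S A T), computed once."""
        if not self._reduced:
            sm = (self.restriction @ self.mass).tocsr()
            self._reduced = {
                "SM": sm,
                "SMT": (sm @ self.prolongation).tocsr(),
                "SAT": (self.restriction @ self.transport @ self.prolongation).tocsr(),
            }
        return self._reduced["SM"], self._reduced["SMT"], self._reduced["SAT"]

    def step_solver(self, dt: float):
        """Cached sparse LU factorization of (S M T + dt S A T)."""
        lu = self._factors.get(dt)
        if lu is None:
            _, smt, sat = self.reduced_operators()
            lhs = (smt + dt * sat).tolil()
            for reduced_idx, value in self._pinned_reduced():
                lhs.rows[reduced_idx] = [reduced_idx]
                lhs.data[reduced_idx] = [1.0]
            lu = spla.splu(lhs.tocsc())
            self._factors[dt] = lu
        return lu

    def _pinned_reduced(self):
        """Reduced-space (index, value) pairs for pinned outer boundaries."""
        out = []
        pos = {g: r for r, g in enumerate(self.retained)}
        n = self.mesh.n_dof
        for global_idx, value in ((0, self.pinned[0]), (n - 1, self.pinned[1])):
            if value is not None:
                out.append((pos[global_idx], float(value)))
        return out


def assemble_system(
    mesh: Mesh,
    config: ModelConfig,
    lumped: bool = False,
    pinned: tuple[float | None, float | None] = (None, None),
) -> DiscreteSystem:
    """Build mass/transport operators and the interface constraint reduction.

    ``pinned`` optionally imposes Dirichlet concentrations at the outer
    donor / receptor walls (used for steady-state verification; the default
    no-flux walls conserve mass).
    """
    if len(mesh.node_positions) != len(config.layers):
        raise ValueError(
            f"mesh has {len(mesh.node_positions)} layers, "
            f"config has {len(config.layers)}"
        )
    for nodes, layer in zip(mesh.node_positions, config.layers):
        if len(nodes) < 2:
            raise ValueError(f"layer {layer.name}: mesh needs >= 2 nodes")
        if not math.isclose(nodes[-1] - nodes[0], layer.thickness, rel_tol=1e-9):
            raise ValueError(
                f"layer {layer.name}: mesh extent {nodes[-1] - nodes[0]} "
                f"does not match thickness {layer.thickness}"
            )

    n = mesh.n_dof
    area = config.geometry.area
    mass = sp.lil_matrix((n, n))
    transport = sp.lil_matrix((n, n))

    for nodes, sl, layer in zip(mesh.node_positions, mesh.layer_slices, config.layers):
        offs = sl.start
        h = np.diff(nodes)
        for e, he in enumerate(h):
            a, b = offs + e, offs + e + 1
            if lumped:
                me = area * he / 2.0 * np.array([[1.0, 0.0], [0.0, 1.0]])
            else:
                me = area * he / 6.0 * np.array([[2.0, 1.0], [1.0, 2.0]])
            ke = area * layer.diffusivity / he * np.array([[1.0, -1.0], [-1.0, 1.0]])
            for i, gi in enumerate((a, b)):
                for j, gj in enumerate((a, b)):
                    mass[gi, gj] += me[i, j]
                    transport[gi, gj] += ke[i, j]

    constraint_map: dict[int, tuple[int, float]] = {}
    for itf in config.interfaces:
        a, b = mesh.interface_pairs[itf.index - 1]
        if itf.mode == "finite":
            k = itf.transfer * area
            transport[a, a] += k
            transport[a, b] += -k / itf.partition
            transport[b, a] += -k
            transport[b, b] += k / itf.partition
        else:
            constraint_map[b] = (a, itf.partition)

    retained = np.array([i for i in range(n) if i not in constraint_map])
    pos = {g: r for r, g in enumerate(retained)}
    n_red = len(retained)

    s_mat = sp.lil_matrix((n_red, n))
    t_mat = sp.lil_matrix((n, n_red))
    for r, g in enumerate(retained):
        s_mat[r, g] = 1.0
        t_mat[g, r] = 1.0
    for slave, (master, p) in constraint_map.items():
        s_mat[pos[master], slave] = 1.0
        t_mat[slave, pos[master]] = p

    weights = np.zeros((len(config.layers), n))
    mass_csr = mass.tocsr()
    for i, sl in enumerate(mesh.layer_slices):
        ind = np.zeros(n)
        ind[sl] = 1.0
        weights[i] = mass_csr.T @ ind

    return DiscreteSystem(
        mesh=mesh,
        config=config,
        mass=mass_csr,
        transport=transport.tocsr(),
        constraint_map=constraint_map,
        restriction=s_mat.tocsr(),
        prolongation=t_mat.tocsr(),
        retained=retained,
        layer_mass_weights=weights,
        pinned=pinned,
    )


def step(system: DiscreteSystem, state: ConcentrationState, dt: float) -> ConcentrationState:
    """Advance one backward-Euler step of length ``dt`` (hours).

    The previous state may be any full-space field (it need not satisfy the
    interface constraints — e.g. the discontinuous initial condition); the
    returned state always does.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    values = np.asarray(state.values, dtype=float)
    if values.shape != (system.mesh.n_dof,):
        raise ValueError(
            f"state has {values.shape} values, system has {system.mesh.n_dof} DOFs"
        )
    sm, _, _ = system.reduced_operators()
    rhs = sm @ values
    for reduced_idx, value in system._pinned_reduced():
        rhs[reduced_idx] = value
    new_reduced = system.step_solver(dt).solve(rhs)
    if not np.all(np.isfinite(new_reduced)):
        raise ArithmeticError("implicit step produced non-finite values")
    new_full = system.prolongation @ new_reduced
    return ConcentrationState(time=state.time + dt, values=new_full)


@dataclass
class SimulationResult:
    """Forward-simulation output: states and per-layer masses at output times."""

    times: np.ndarray
    states: list[ConcentrationState]
    layer_masses: np.ndarray  # (n_times, n_layers), mg
    layer_names: tuple[str, ...]
    mesh: Mesh
    config: ModelConfig

    def layer_mass(self, name: str) -> np.ndarray:
        """Mass trajectory (mg) of one layer over the output times."""
        try:
            return self.layer_masses[:, self.layer_names.index(name)]
        except ValueError:
            raise KeyError(
                f"unknown layer {name!r}; expected one of {self.layer_names}"
            ) from None

    def time_index(self, t: float) -> int:
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=1e-10, atol=1e-12))
        if idx.size == 0:
            raise KeyError(f"time {t} h is not an output time of this simulation")
        return int(idx[0])


def initial_state(system: DiscreteSystem) -> ConcentrationState:
    """Per-layer uniform initial condition (all drug in the donor by default)."""
    values = np.zeros(system.mesh.n_dof)
    for sl, layer in zip(system.mesh.layer_slices, system.config.layers):
        values[sl] = layer.initial_concentration
    return ConcentrationState(time=0.0, values=values)


def simulate(
    config: ModelConfig,
    output_times,
    dt: float = 0.01,
    refinement: float = 1,
    lumped: bool = False,
    pinned: tuple[float | None, float | None] = (None, None),
    system: DiscreteSystem | None = None,
) -> SimulationResult:
    """Integrate the four-layer system and record states at ``output_times``.

    Internal steps are uniform within each inter-output interval and no
    longer than ``dt``; each requested output time is hit exactly (the step
    is shortened, never interpolated).  Passing a pre-assembled ``system``
    skips re-assembly (the mesh must match ``config``).
    """
    times = np.asarray(output_times, dtype=float)
    if times.size == 0:
        raise ValueError("output_times must not be empty")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("output_times must be strictly increasing and >= 0")
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")

    if system is None:
        problems = validate_config(config)
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))
        mesh = build_mesh(config, refinement)
        system = assemble_system(mesh, config, lumped=lumped, pinned=pinned)

    state = initial_state(system)
    states: list[ConcentrationState] = []
    masses = np.zeros((times.size, len(config.layers)))

    for i, t_out in enumerate(times):
        if t_out > state.time:
            span = t_out - state.time
            n_sub = max(1, math.ceil(span / dt - 1e-9))
            h = span / n_sub
            for _ in range(n_sub):
                state = step(system, state, h)
            state = ConcentrationState(time=float(t_out), values=state.values)
        states.append(state)
        masses[i] = system.layer_mass_weights @ state.values

    return SimulationResult(
        times=times,
        states=states,
        layer_masses=masses,
        layer_names=tuple(layer.name for layer in config.layers),
        mesh=system.mesh,
        config=config,
    )
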