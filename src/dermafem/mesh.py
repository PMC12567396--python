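"""Mesh construction with duplicated degrees of freedom at layer interfaces.

Concentration may be discontinuous across an interface (partitioning), so
each interface position carries two coincident nodes: the last node of the
upstream layer and the first node of the downstream layer.  The solver
couples or constrains these pairs according to the interface mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, validate_config


@dataclass(frozen=True)
class Mesh:
    """Per-layer nodal coordinates and the global DOF bookkeeping.

    Attributes
    ----------
    node_positions : tuple of ndarray
        Strictly increasing coordinates per layer, cm; x = 0 at the donor
        outer wall.
    layer_slices : tuple of slice
        Global DOF range of each layer (layers are numbered 0..3).
    interface_pairs : tuple of (int, int)
        For interface i (1-based, element i-1 of the tuple): global indices
        of the coincident (upstream, downstream) nodes.
    """

    node_positions: tuple[np.ndarray, ...]
    layer_slices: tuple[slice, ...]
    interface_pairs: tuple[tuple[int, int], ...]

    @property
    def n_dof(self) -> int:
        return self.layer_slices[-1].stop

    @property
    def coordinates(self) -> np.ndarray:
        """All nodal coordinates as one array of length n_dof."""
        return np.concatenate(self.node_positions)


def build_mesh(config: ModelConfig, refinement: float = 1) -> Mesh:
    """Discretize each layer uniformly into ``refinement x n_elements`` elements.

    ``refinement`` must be >= 1; non-integer values are rounded per layer.
    Interface DOFs are duplicated so the total DOF count is
    ``sum(n_elements_layer + 1)``.
    """
    if refinement < 1:
        raise ValueError(f"refinement must be >= 1, got {refinement}")
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    positions: list[np.ndarray] = []
    slices: list[slice] = []
    offset = 0
    x_left = 0.0
    for layer in config.layers:
        n_el = int(round(layer.n_elements * refinement))
        nodes = np.linspace(x_left, x_left + layer.thickness, n_el + 1)
        positions.append(nodes)
        slices.append(slice(offset, offset + n_el + 1))
        offset += n_el + 1
        x_left += layer.thickness

    pairs = tuple(
        (slices[i].stop - 1, slices[i + 1].start) for i in range(len(slices) - 1)
    )
    return Mesh(
        node_positions=tuple(positions),
        layer_slices=tuple(slices),
        interface_pairs=pairs,
    )
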