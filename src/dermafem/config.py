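"""Domain types and validation for the four-layer Franz-cell diffusion model.

The model stacks four one-dimensional layers along ``x`` (donor-to-receptor):

* ``DC`` — donor compartment, a well-mixed drug reservoir,
* ``SC`` — stratum corneum, the principal diffusion barrier,
* ``RS`` — rest of skin (viable epidermis + dermis, lumped),
* ``RC`` — receptor compartment, a well-mixed stirred buffer.

Adjacent layers are coupled by interface conditions that allow a
concentration jump: a dimensionless partition coefficient ``P_i``
(downstream/upstream concentration ratio at equilibrium) and, optionally, a
finite mass-transfer coefficient ``K_i`` in cm/h.  ``K_i -> inf`` is the
instantaneous-partition (equilibrium) limit.

Validation is collected, not raised: :func:`validate_config` returns a list
of human-readable violations so callers can report all problems at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

LAYER_NAMES = ("DC", "SC", "RS", "RC")
INTERFACE_NAMES = {1: "DC-SC", 2: "SC-RS", 3: "RS-RC"}

#: relative tolerance for the donor/receptor thickness-volume consistency check
_GEOM_RTOL = 1e-12


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous diffusive layer.

    Parameters
    ----------
    name : str
        One of ``DC``, ``SC``, ``RS``, ``RC``.
    thickness : float
        Layer extent along x, cm.
    diffusivity : float
        Fickian diffusion coefficient, cm^2/h.
    initial_concentration : float
        Uniform initial concentration, mg/cm^3.
    n_elements : int
        Number of linear finite elements across the layer.
    """

    name: str
    thickness: float
    diffusivity: float
    initial_concentration: float = 0.0
    n_elements: int = 10


@dataclass(frozen=True)
class InterfaceSpec:
    """Coupling condition between layers ``index`` and ``index + 1``.

    ``partition`` is the downstream/upstream concentration ratio
    ``P_i = C_{i+1}(x_i) / C_i(x_i)`` at equilibrium, so ``P_i > 1`` means
    the drug prefers the downstream layer.  In ``finite`` mode the interface
    flux is ``K_i (C_i - C_{i+1}/P_i)``; ``equilibrium`` mode is the
    ``K_i -> inf`` limit where the jump condition holds exactly.
    """

    index: int
    partition: float
    mode: Literal["equilibrium", "finite"] = "equilibrium"
    transfer: float | None = None  # K_i, cm/h; required when mode == "finite"


@dataclass(frozen=True)
class CellGeometry:
    """Franz-cell geometry: exposure area (cm^2) and chamber volumes (cm^3).

    The donor and receptor layer thicknesses are derived quantities,
    ``volume / area``, so the 1D model holds exactly those fluid volumes.
    """

    area: float
    donor_volume: float
    receptor_volume: float

    @property
    def donor_thickness(self) -> float:
        return self.donor_volume / self.area

    @property
    def receptor_thickness(self) -> float:
        return self.receptor_volume / self.area


@dataclass(frozen=True)
class ModelConfig:
    """Complete specification of one simulation: geometry, layers, interfaces.

    Layers are ordered DC, SC, RS, RC; interface ``i`` couples layers ``i``
    and ``i+1`` (1-based).  The donor and receptor are modelled as layers
    with a very large diffusivity (``well_mixed_diffusivity``) so they stay
    spatially uniform, which is the well-mixed-compartment assumption.
    """

    geometry: CellGeometry
    layers: tuple[LayerSpec, ...]
    interfaces: tuple[InterfaceSpec, ...]
    well_mixed_diffusivity: float = 1e4

    @property
    def total_thickness(self) -> float:
        return sum(layer.thickness for layer in self.layers)

    def layer(self, name: str) -> LayerSpec:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(f"unknown layer {name!r}; expected one of {LAYER_NAMES}")

    def interface(self, index: int) -> InterfaceSpec:
        for itf in self.interfaces:
            if itf.index == index:
                return itf
        raise KeyError(f"unknown interface index {index}; expected 1, 2 or 3")

    def total_initial_mass(self) -> float:
        """Initial drug load in mg, summed over layers (usually all in DC)."""
        return sum(
            layer.initial_concentration * layer_volume(self.geometry, layer)
            for layer in self.layers
        )


def layer_volume(geometry: CellGeometry, layer: LayerSpec) -> float:
    """Volume of a layer in cm^3 (area x thickness; chamber volume for DC/RC)."""
    if layer.name == "DC":
        return geometry.donor_volume
    if layer.name == "RC":
        return geometry.receptor_volume
    return geometry.area * layer.thickness


def validate_config(config: ModelConfig) -> list[str]:
    """Check every structural invariant; return one message per violation.

    An empty list means the configuration is usable by the mesh builder,
    the solver and the estimation layer.  Violations are returned as data
    rather than raised so a caller (e.g. the CLI ``validate`` command) can
    report them all at once.
    """
    problems: list[str] = []
    geo = config.geometry
    for fname in ("area", "donor_volume", "receptor_volume"):
        value = getattr(geo, fname)
        if not value > 0:
            problems.append(f"geometry.{fname} must be > 0, got {value}")

    names = tuple(layer.name for layer in config.layers)
    if names != LAYER_NAMES:
        problems.append(f"layer order must be {LAYER_NAMES}, got {names}")

    for layer in config.layers:
        tag = f"layer {layer.name}"
        if not layer.thickness > 0:
            problems.append(f"{tag}: thickness must be > 0, got {layer.thickness}")
        if not layer.diffusivity > 0:
            problems.append(f"{tag}: diffusivity must be > 0, got {layer.diffusivity}")
        if layer.initial_concentration < 0:
            problems.append(
                f"{tag}: initial_concentration must be >= 0, "
                f"got {layer.initial_concentration}"
            )
        if layer.n_elements < 1:
            problems.append(f"{tag}: n_elements must be >= 1, got {layer.n_elements}")

    indices = tuple(itf.index for itf in config.interfaces)
    if indices != (1, 2, 3):
        problems.append(f"interface indices must be (1, 2, 3), got {indices}")
    for itf in config.interfaces:
        tag = f"interface {itf.index} ({INTERFACE_NAMES.get(itf.index, '?')})"
        if not itf.partition > 0:
            problems.append(
                f"{tag}: partition P_{itf.index} must be > 0, got {itf.partition}"
            )
        if itf.mode not in ("equilibrium", "finite"):
            problems.append(f"{tag}: mode must be 'equilibrium' or 'finite'")
        elif itf.mode == "finite":
            if itf.transfer is None or not itf.transfer > 0:
                problems.append(
                    f"{tag}: transfer K_{itf.index} must be > 0 in finite mode, "
                    f"got {itf.transfer}"
                )

    if not config.well_mixed_diffusivity > 0:
        problems.append(
            "well_mixed_diffusivity must be > 0, "
            f"got {config.well_mixed_diffusivity}"
        )

    # well-mixed compartments must actually carry the well-mixed diffusivity
    if names == LAYER_NAMES:
        for name in ("DC", "RC"):
            lay = config.layer(name)
            if lay.diffusivity != config.well_mixed_diffusivity:
                problems.append(
                    f"layer {name}: diffusivity must equal well_mixed_diffusivity "
                    f"({config.well_mixed_diffusivity}), got {lay.diffusivity}"
                )
        if geo.area > 0:
            dc, rc = config.layer("DC"), config.layer("RC")
            for lay, vol, label in (
                (dc, geo.donor_volume, "donor_volume"),
                (rc, geo.receptor_volume, "receptor_volume"),
            ):
                if vol > 0 and abs(lay.thickness * geo.area - vol) > _GEOM_RTOL * vol:
                    problems.append(
                        f"layer {lay.name}: thickness x area = "
                        f"{lay.thickness * geo.area} must equal {label} = {vol}"
                    )
    return problems


# Names of the five permeation parameters the inverse problem can free.
PARAMETER_NAMES = ("D_SC", "P_1", "P_2", "P_3", "K_3")


def apply_parameters(config: ModelConfig, params: Mapping[str, float]) -> ModelConfig:
    """Return a copy of ``config`` with permeation parameters overridden.

    Recognised keys: ``D_SC``, ``D_RS``, ``P_1``, ``P_2``, ``P_3``, ``K_3``.
    ``K_3`` implies a finite RS-RC interface.
    """
    known = set(PARAMETER_NAMES) | {"D_RS"}
    unknown = set(params) - known
    if unknown:
        raise KeyError(f"unknown parameter(s) {sorted(unknown)}; expected {sorted(known)}")

    layers = list(config.layers)
    for key, layer_name in (("D_SC", "SC"), ("D_RS", "RS")):
        if key in params:
            idx = LAYER_NAMES.index(layer_name)
            layers[idx] = replace(layers[idx], diffusivity=float(params[key]))

    interfaces = list(config.interfaces)
    for i, itf in enumerate(interfaces):
        pkey, kkey = f"P_{itf.index}", f"K_{itf.index}"
        changes: dict = {}
        if pkey in params:
            changes["partition"] = float(params[pkey])
        if kkey in params:
            changes["transfer"] = float(params[kkey])
            changes["mode"] = "finite"
        if changes:
            interfaces[i] = replace(itf, **changes)

    return replace(config, layers=tuple(layers), interfaces=tuple(interfaces))


def extract_parameters(config: ModelConfig) -> dict[str, float]:
    """Read the five permeation parameters (plus D_RS) out of a config."""
    out = {
        "D_SC": config.layer("SC").diffusivity,
        "D_RS": config.layer("RS").diffusivity,
    }
    for itf in config.interfaces:
        out[f"P_{itf.index}"] = itf.partition
        if itf.mode == "finite":
            out[f"K_{itf.index}"] = itf.transfer
    return out
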