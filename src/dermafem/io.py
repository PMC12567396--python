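"""File formats: YAML configurations, CSV observations, run manifests.

Units are embedded in every column and key name (``time_h``, ``mass_mg``,
``conc_mg_per_cm3``) because the model mixes mg, mg/cm^3 and mL; silent
unit drift is the classic failure mode of permeation data handling.
Unknown configuration keys are errors, not warnings.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import datetime
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import (
    CellGeometry,
    InterfaceSpec,
    LayerSpec,
    ModelConfig,
    validate_config,
)
from .estimation import DEFAULT_BOUNDS, FitSpec, ObservationSet, Weighting

__all__ = [
    "load_config",
    "save_config",
    "read_observations",
    "write_observations",
    "write_manifest",
    "config_digest",
]

_FLOAT_FMT = "%.12g"


class ConfigFileError(ValueError):
    """Raised for parse errors, unknown keys, or invalid configurations."""


def _check_keys(mapping: dict, allowed: set[str], context: str, path) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigFileError(
            f"{path}: unknown key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(allowed)}"
        )


_GEOMETRY_KEYS = {"area_cm2", "donor_volume_ml", "receptor_volume_ml"}
_LAYER_KEYS = {
    "name", "thickness_cm", "diffusivity_cm2_per_h",
    "initial_concentration_mg_per_cm3", "n_elements",
}
_INTERFACE_KEYS = {"index", "partition", "mode", "transfer_cm_per_h"}
_TOP_KEYS = {"geometry", "layers", "interfaces", "well_mixed_diffusivity_cm2_per_h", "fit"}
_FIT_KEYS = {
    "free_parameters", "initial_guesses", "fixed_values", "bounds",
    "step_tolerance", "function_tolerance", "weighting",
}
_WEIGHTING_KEYS = {"kind", "factor", "fraction"}


def load_config(path) -> tuple[ModelConfig, FitSpec | None]:
    """Parse a YAML model configuration (and optional fit block).

    Donor/receptor layer thickness and diffusivity may be omitted; they are
    derived from the geometry and the well-mixed diffusivity.  Every
    violation is reported with the file path for context.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigFileError(f"{path}: YAML parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigFileError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level", path)
    for key in ("geometry", "layers", "interfaces"):
        if key not in raw:
            raise ConfigFileError(f"{path}: missing required section {key!r}")

    geo_raw = raw["geometry"]
    _check_keys(geo_raw, _GEOMETRY_KEYS, "geometry", path)
    try:
        geometry = CellGeometry(
            area=float(geo_raw["area_cm2"]),
            donor_volume=float(geo_raw["donor_volume_ml"]),
            receptor_volume=float(geo_raw["receptor_volume_ml"]),
        )
    except KeyError as exc:
        raise ConfigFileError(f"{path}: geometry missing {exc}") from exc

    well_mixed = float(raw.get("well_mixed_diffusivity_cm2_per_h", 1e4))
    derived_thickness = {
        "DC": geometry.donor_thickness, "RC": geometry.receptor_thickness,
    }
    layers = []
    for entry in raw["layers"]:
        _check_keys(entry, _LAYER_KEYS, f"layer {entry.get('name')!r}", path)
        name = entry.get("name")
        thickness = entry.get("thickness_cm", derived_thickness.get(name))
        if thickness is None:
            raise ConfigFileError(f"{path}: layer {name!r} needs thickness_cm")
        diffusivity = entry.get(
            "diffusivity_cm2_per_h", well_mixed if name in ("DC", "RC") else None
        )
        if diffusivity is None:
            raise ConfigFileError(f"{path}: layer {name!r} needs diffusivity_cm2_per_h")
        layers.append(LayerSpec(
            name=name,
            thickness=float(thickness),
            diffusivity=float(diffusivity),
            initial_concentration=float(entry.get("initial_concentration_mg_per_cm3", 0.0)),
            n_elements=int(entry.get("n_elements", 10)),
        ))

    interfaces = []
    for entry in raw["interfaces"]:
        _check_keys(entry, _INTERFACE_KEYS, f"interface {entry.get('index')}", path)
        transfer = entry.get("transfer_cm_per_h")
        interfaces.append(InterfaceSpec(
            index=int(entry["index"]),
            partition=float(entry["partition"]),
            mode=entry.get("mode", "finite" if transfer is not None else "equilibrium"),
            transfer=None if transfer is None else float(transfer),
        ))

    config = ModelConfig(
        geometry=geometry,
        layers=tuple(layers),
        interfaces=tuple(interfaces),
        well_mixed_diffusivity=well_mixed,
    )
    problems = validate_config(config)
    if problems:
        raise ConfigFileError(f"{path}: invalid configuration: " + "; ".join(problems))

    fitspec = _parse_fit(raw.get("fit"), path)
    return config, fitspec


def _parse_fit(raw, path) -> FitSpec | None:
    if raw is None:
        return None
    _check_keys(raw, _FIT_KEYS, "fit", path)
    weighting = Weighting()
    if "weighting" in raw:
        _check_keys(raw["weighting"], _WEIGHTING_KEYS, "fit.weighting", path)
        weighting = Weighting(**raw["weighting"])
    bounds = dict(DEFAULT_BOUNDS)
    for name, pair in raw.get("bounds", {}).items():
        bounds[name] = (float(pair[0]), float(pair[1]))
    return FitSpec(
        free_parameters=tuple(raw["free_parameters"]),
        initial_guesses={k: float(v) for k, v in raw["initial_guesses"].items()},
        fixed_values={k: float(v) for k, v in raw.get("fixed_values", {}).items()},
        bounds=bounds,
        step_tolerance=float(raw.get("step_tolerance", 1e-5)),
        function_tolerance=float(raw.get("function_tolerance", 1e-5)),
        weighting=weighting,
    )


def _config_mapping(config: ModelConfig, fitspec: FitSpec | None = None) -> dict:
    out = {
        "geometry": {
            "area_cm2": config.geometry.area,
            "donor_volume_ml": config.geometry.donor_volume,
            "receptor_volume_ml": config.geometry.receptor_volume,
        },
        "well_mixed_diffusivity_cm2_per_h": config.well_mixed_diffusivity,
        "layers": [
            {
                "name": lay.name,
                "thickness_cm": lay.thickness,
                "diffusivity_cm2_per_h": lay.diffusivity,
                "initial_concentration_mg_per_cm3": lay.initial_concentration,
                "n_elements": lay.n_elements,
            }
            for lay in config.layers
        ],
        "interfaces": [
            {
                "index": itf.index,
                "partition": itf.partition,
                "mode": itf.mode,
                **({"transfer_cm_per_h": itf.transfer} if itf.transfer is not None else {}),
            }
            for itf in config.interfaces
        ],
    }
    if fitspec is not None:
        out["fit"] = {
            "free_parameters": list(fitspec.free_parameters),
            "initial_guesses": dict(fitspec.initial_guesses),
            "fixed_values": dict(fitspec.fixed_values),
            "bounds": {k: list(v) for k, v in fitspec.bounds.items()},
            "step_tolerance": fitspec.step_tolerance,
            "function_tolerance": fitspec.function_tolerance,
            "weighting": asdict(fitspec.weighting),
        }
    return out


def save_config(config: ModelConfig, path, fitspec: FitSpec | None = None) -> None:
    """Write a configuration (with optional fit block) as YAML."""
    Path(path).write_text(
        yaml.safe_dump(_config_mapping(config, fitspec), sort_keys=False)
    )


def config_digest(config: ModelConfig) -> str:
    """Stable sha256 digest of the canonical YAML serialization."""
    text = yaml.safe_dump(_config_mapping(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Observations CSV: two RFC-4180 tables separated by one blank line.
# Block 1: time_h,receiver_mass_mg[,weight];  block 2: compartment,mass_mg[,weight]
# with the endpoint time carried in a leading '# endpoint_time_h = ...' comment.

def write_observations(obs: ObservationSet, path) -> None:
    problems = obs.validate()
    if problems:
        raise ValueError("invalid observations: " + "; ".join(problems))
    n = obs.times.size
    weights = np.ones(obs.n_residuals) if obs.weights is None else np.asarray(obs.weights)
    series = pd.DataFrame({
        "time_h": obs.times,
        "receiver_mass_mg": obs.receiver_mass,
        "weight": weights[:n],
    })
    endpoint = pd.DataFrame({
        "compartment": ["DC", "SC", "RS"],
        "mass_mg": [obs.endpoint_masses[k] for k in ("DC", "SC", "RS")],
        "weight": weights[n:],
    })
    buf = _io.StringIO()
    buf.write(f"# endpoint_time_h = {_FLOAT_FMT % obs.endpoint_time}\n")
    series.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    buf.write("\n")
    endpoint.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def read_observations(path) -> ObservationSet:
    """Read the two-block observations CSV written by :func:`write_observations`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    endpoint_time = None
    body = []
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("#"):
            if "endpoint_time_h" in stripped:
                endpoint_time = float(stripped.split("=", 1)[1])
            continue
        body.append(line)
    blocks, current = [], []
    for line in body:
        if line.strip() == "":
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(line)
    if current:
        blocks.append(current)
    if len(blocks) != 2:
        raise ValueError(
            f"{path}: expected a receiver-series block and an endpoint block "
            f"separated by a blank line, found {len(blocks)} block(s)"
        )
    series = pd.read_csv(_io.StringIO("\n".join(blocks[0])))
    endpoint = pd.read_csv(_io.StringIO("\n".join(blocks[1])))

    for col in ("time_h", "receiver_mass_mg"):
        if col not in series.columns:
            raise ValueError(f"{path}: receiver series is missing column {col!r}")
    for col in ("compartment", "mass_mg"):
        if col not in endpoint.columns:
            raise ValueError(f"{path}: endpoint block is missing column {col!r}")

    times = series["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: series times must be strictly increasing")
    masses = series["receiver_mass_mg"].to_numpy(dtype=float)
    if np.any(masses < 0):
        raise ValueError(f"{path}: receiver masses must be >= 0")
    endpoint_masses = dict(zip(endpoint["compartment"], endpoint["mass_mg"].astype(float)))
    if any(v < 0 for v in endpoint_masses.values()):
        raise ValueError(f"{path}: endpoint masses must be >= 0")
    if endpoint_time is None:
        endpoint_time = float(times[-1])

    weights = None
    if "weight" in series.columns and "weight" in endpoint.columns:
        weights = np.concatenate([
            series["weight"].to_numpy(dtype=float),
            endpoint["weight"].to_numpy(dtype=float),
        ])
    obs = ObservationSet(
        times=times,
        receiver_mass=masses,
        endpoint_time=endpoint_time,
        endpoint_masses=endpoint_masses,
        weights=weights,
    )
    problems = obs.validate()
    if problems:
        raise ValueError(f"{path}: invalid observations: " + "; ".join(problems))
    return obs


def write_manifest(
    path,
    command: str,
    config: ModelConfig,
    parameters: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Record what produced a set of outputs; returns the manifest mapping."""
    from . import __version__

    manifest = {
        "command": command,
        "config_sha256": config_digest(config),
        "parameters": parameters or {},
        "seed": seed,
        "software": {"name": "dermafem", "version": __version__},
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
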