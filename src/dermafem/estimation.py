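"""Inverse problem: bounded nonlinear least squares for permeation parameters.

The observables are a cumulative receiver-mass time series plus endpoint
drug content of the donor, stratum corneum and rest-of-skin compartments.
The free parameters are any subset of {D_SC, P_1, P_2, P_3, K_3}; D_RS is
measured and stays fixed unless explicitly freed.  Two presets mirror the
study: Case 1 pins P_2 = 1 (three-layer reduction), Case 2 frees all five.

Optimization runs in log10 parameter space — the parameters are positive
and span orders of magnitude, so log-space makes the box bounds natural and
the trust-region scaling uniform — via ``scipy.optimize.least_squares``
(trust-region reflective), with step and residual-change tolerances of
1e-5 by default.

Residual convention: receiver residuals are cumulative mass (mg),
``observed - simulated``; endpoint residuals are concentrations (mg/cm^3),
model median nodal concentration minus experimental mass / layer volume,
which keeps units commensurate across compartments of very different
volumes.  Optional late-time weighting up-weights the tail of the receiver
series where small deviations matter most for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import ModelConfig, PARAMETER_NAMES, apply_parameters, layer_volume
from .fem import simulate
from .observables import median_concentration

__all__ = [
    "ObservationSet",
    "Weighting",
    "FitSpec",
    "FitResult",
    "DEFAULT_BOUNDS",
    "residual_vector",
    "fit_parameters",
    "case1_fitspec",
    "case2_fitspec",
]

ENDPOINT_LAYERS = ("DC", "SC", "RS")


@dataclass(frozen=True)
class ObservationSet:
    """Franz-cell observations: receiver series + endpoint compartment masses.

    ``times`` (h) are strictly increasing; ``receiver_mass`` (mg) is the
    cumulative drug mass in the receptor at those times (the endpoint value
    is the last series point, never duplicated).  ``endpoint_masses`` holds
    DC/SC/RS drug content (mg) at ``endpoint_time``.  ``weights`` is one
    non-negative multiplier per residual entry (series entries first, then
    DC, SC, RS); ``None`` means uniform.
    """

    times: np.ndarray
    receiver_mass: np.ndarray
    endpoint_time: float
    endpoint_masses: dict[str, float]
    weights: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "receiver_mass", np.asarray(self.receiver_mass, dtype=float)
        )

    def validate(self) -> list[str]:
        problems = []
        if self.times.size == 0:
            problems.append("receiver series is empty")
        if np.any(np.diff(self.times) <= 0):
            problems.append("series times must be strictly increasing")
        if self.times.size != self.receiver_mass.size:
            problems.append("times and receiver_mass lengths differ")
        if np.any(self.receiver_mass < 0):
            problems.append("receiver masses must be >= 0")
        missing = [k for k in ENDPOINT_LAYERS if k not in self.endpoint_masses]
        if missing:
            problems.append(f"endpoint_masses missing {missing}")
        if any(v < 0 for v in self.endpoint_masses.values()):
            problems.append("endpoint masses must be >= 0")
        if self.times.size and self.endpoint_time < self.times[-1]:
            problems.append("endpoint_time must be >= the last series time")
        n_res = self.times.size + len(ENDPOINT_LAYERS)
        if self.weights is not None and len(self.weights) != n_res:
            problems.append(f"weights must have {n_res} entries")
        return problems

    @property
    def n_residuals(self) -> int:
        return self.times.size + len(ENDPOINT_LAYERS)


@dataclass(frozen=True)
class Weighting:
    """Residual weighting scheme: uniform, or late-time emphasis.

    ``late_time`` multiplies the last ``ceil(fraction * n_series)`` receiver
    residuals by ``factor``; endpoint residuals are never re-weighted.
    """

    kind: Literal["uniform", "late_time"] = "uniform"
    factor: float = 4.0
    fraction: float = 0.25

    def pattern(self, n_series: int) -> np.ndarray:
        w = np.ones(n_series + len(ENDPOINT_LAYERS))
        if self.kind == "late_time":
            n_late = int(np.ceil(self.fraction * n_series))
            if n_late > 0:
                w[n_series - n_late:n_series] = self.factor
        elif self.kind != "uniform":
            raise ValueError(f"unknown weighting kind {self.kind!r}")
        return w


#: Physiologically plausible box bounds for the free parameters.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "D_SC": (1e-7, 1e-1),   # cm^2/h
    "P_1": (1e-3, 1e3),
    "P_2": (1e-3, 1e3),
    "P_3": (1e-3, 1e3),
    "K_3": (1e-4, 1e2),     # cm/h
}


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``fixed_values`` completes the parameter set for entries not in
    ``free_parameters`` (D_RS may be included to override the measured
    value).  Initial guesses must lie strictly inside the bounds.
    """

    free_parameters: tuple[str, ...]
    initial_guesses: dict[str, float]
    fixed_values: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    step_tolerance: float = 1e-5
    function_tolerance: float = 1e-5
    weighting: Weighting = Weighting("uniform")
    max_evaluations: int = 1000

    def validate(self) -> list[str]:
        problems = []
        for name in self.free_parameters:
            if name not in PARAMETER_NAMES:
                problems.append(f"unknown free parameter {name!r}")
                continue
            lo, hi = self.bounds.get(name, (None, None))
            if lo is None or not (0 < lo < hi):
                problems.append(f"{name}: bounds must be a positive interval")
                continue
            guess = self.initial_guesses.get(name)
            if guess is None:
                problems.append(f"{name}: missing initial guess")
            elif not (lo < guess < hi):
                problems.append(
                    f"{name}: initial guess {guess} not strictly inside ({lo}, {hi})"
                )
        if self.step_tolerance <= 0 or self.function_tolerance <= 0:
            problems.append("tolerances must be > 0")
        return problems


@dataclass
class FitResult:
    """Fitted parameters plus convergence diagnostics."""

    estimates: dict[str, float]
    residual_norm: float     # final sum of squared weighted residuals
    n_iterations: int
    converged: bool
    reason: str
    history: list[float]     # best-so-far residual norms per evaluation
    fitspec: FitSpec
    n_evaluations: int = 0


def residual_vector(
    params: Mapping[str, float] | Sequence[float],
    fitspec: FitSpec,
    obs: ObservationSet,
    config: ModelConfig,
    dt: float = 0.01,
    refinement: float = 1,
) -> np.ndarray:
    """Weighted residuals at one parameter point.

    ``params`` is a mapping, or a sequence ordered like
    ``fitspec.free_parameters``.  The simulation's output grid is aligned to
    the observation times, so no interpolation enters the residuals.
    """
    if not isinstance(params, Mapping):
        params = dict(zip(fitspec.free_parameters, params))
    full = {**fitspec.fixed_values, **params}
    trial = apply_parameters(config, full)

    output_times = np.unique(np.concatenate([obs.times, [obs.endpoint_time]]))
    try:
        result = simulate(trial, output_times, dt=dt, refinement=refinement)
    except Exception as exc:
        raise RuntimeError(f"simulation failed at parameters {full}") from exc

    model_receiver = np.array(
        [result.layer_mass("RC")[result.time_index(t)] for t in obs.times]
    )
    series_res = obs.receiver_mass - model_receiver

    endpoint_res = np.empty(len(ENDPOINT_LAYERS))
    for i, name in enumerate(ENDPOINT_LAYERS):
        volume = layer_volume(config.geometry, config.layer(name))
        model_median = median_concentration(result, name, obs.endpoint_time)
        endpoint_res[i] = model_median - obs.endpoint_masses[name] / volume

    res = np.concatenate([series_res, endpoint_res])
    weights = fitspec.weighting.pattern(obs.times.size)
    if obs.weights is not None:
        weights = weights * np.asarray(obs.weights, dtype=float)
    return res * weights


def fit_parameters(
    fitspec: FitSpec,
    obs: ObservationSet,
    config: ModelConfig,
    dt: float = 0.01,
    refinement: float = 1,
) -> FitResult:
    """Bounded trust-region least squares in log10 parameter space.

    Deterministic given identical inputs.  Non-convergence within the
    evaluation cap is reported in ``converged``/``reason``, not raised.
    """
    problems = fitspec.validate() + obs.validate()
    if problems:
        raise ValueError("invalid fit inputs: " + "; ".join(problems))

    names = fitspec.free_parameters
    x0 = np.log10([fitspec.initial_guesses[n] for n in names])
    lb = np.log10([fitspec.bounds[n][0] for n in names])
    ub = np.log10([fitspec.bounds[n][1] for n in names])

    history: list[float] = []

    def fun(x: np.ndarray) -> np.ndarray:
        res = residual_vector(
            dict(zip(names, 10.0 ** x)), fitspec, obs, config,
            dt=dt, refinement=refinement,
        )
        norm = float(res @ res)
        history.append(min(norm, history[-1]) if history else norm)
        return res

    sol = least_squares(
        fun,
        x0,
        bounds=(lb, ub),
        method="trf",
        xtol=fitspec.step_tolerance,
        ftol=fitspec.function_tolerance,
        gtol=None,
        max_nfev=fitspec.max_evaluations,
    )

    estimates = dict(zip(names, 10.0 ** sol.x))
    return FitResult(
        estimates=estimates,
        residual_norm=float(2.0 * sol.cost),
        n_iterations=int(getattr(sol, "njev", 0) or 0),
        converged=bool(sol.success),
        reason=str(sol.message),
        history=history,
        fitspec=fitspec,
        n_evaluations=int(sol.nfev),
    )


def _preset(
    truth: Mapping[str, float],
    free: tuple[str, ...],
    fixed: Mapping[str, float],
    initial_scale: float,
    weighting: Weighting,
) -> FitSpec:
    return FitSpec(
        free_parameters=free,
        initial_guesses={n: truth[n] * initial_scale for n in free},
        fixed_values=dict(fixed),
        weighting=weighting,
    )


def case1_fitspec(
    generating_params: Mapping[str, float],
    initial_scale: float = 1.3,
    weighting: Weighting = Weighting("late_time"),
) -> FitSpec:
    """Three-layer reduction: P_2 pinned at 1, four free parameters."""
    free = ("D_SC", "P_1", "P_3", "K_3")
    fixed = {"P_2": 1.0}
    return _preset(generating_params, free, fixed, initial_scale, weighting)


def case2_fitspec(
    generating_params: Mapping[str, float],
    initial_scale: float = 1.3,
    weighting: Weighting = Weighting("late_time"),
) -> FitSpec:
    """Full four-layer fit: all five permeation parameters free."""
    free = ("D_SC", "P_1", "P_2", "P_3", "K_3")
    return _preset(generating_params, free, {}, initial_scale, weighting)
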