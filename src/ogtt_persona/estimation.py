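"""Weighted least-squares fitting of a parameter subset to one OGTT response.

The objective is the combined sum of squared residuals over both metabolites,

    SSR = sum_j sum_i ( gamma_j * (y_ij - d_ij) )^2

with weight ``gamma = 1`` for glucose and ``gamma = 0.1`` for insulin, which
compensates the unit difference between mmol/L and mU/L.  Minimization uses
bounded trust-region-reflective nonlinear least squares, restarted from
multiple randomly perturbed initializations (default fifty starts with 25%
multiplicative uniform noise around the reference value of each free
parameter) to avoid erroneous local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model import (
    PARAMETER_NAMES,
    MealInput,
    ModelConstants,
    ModelParameters,
    SimulatedResponse,
    SimulationError,
    simulate,
)

__all__ = [
    "OGTT_TIMES",
    "OgttResponse",
    "FitConfig",
    "FitResult",
    "FitError",
    "StartRecord",
    "weighted_ssr",
    "residual_vector",
    "fit_individual",
]

#: canonical OGTT sampling grid, minutes post-load
OGTT_TIMES = (0.0, 30.0, 60.0, 90.0, 120.0)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class OgttResponse:
    """One individual's measured five-point glucose and insulin curves."""

    individual_id: str
    times: tuple[float, ...]
    glucose: tuple[float, ...]   # mmol/L
    insulin: tuple[float, ...]   # mU/L

    def __post_init__(self):
        if len(self.times) != len(self.glucose) or len(self.times) != len(self.insulin):
            raise ValueError("times/glucose/insulin lengths differ")
        if len(self.times) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        vals = np.concatenate([self.glucose, self.insulin])
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(
                f"individual {self.individual_id}: concentrations must be positive and finite"
            )

    @classmethod
    def from_arrays(cls, individual_id, times, glucose, insulin) -> "OgttResponse":
        return cls(
            str(individual_id),
            tuple(float(t) for t in times),
            tuple(float(g) for g in glucose),
            tuple(float(i) for i in insulin),
        )

    @property
    def fasting_glucose(self) -> float:
        return self.glucose[0]

    @property
    def fasting_insulin(self) -> float:
        return self.insulin[0]

    @property
    def two_hour_glucose(self) -> float:
        return self.glucose[-1]


@dataclass(frozen=True)
class FitConfig:
    """Settings of the multi-start weighted least-squares fit."""

    free_parameter_names: tuple[str, ...] = ("k1", "k5", "k6", "k8")
    n_starts: int = 50
    start_noise: float = 0.25
    gamma: float = 0.1
    bounds: Mapping[str, tuple[float, float]] | None = None
    seed: int = 0
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-8
    solver_tol: float = 1e-10
    max_nfev: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "free_parameter_names", tuple(self.free_parameter_names))
        if len(self.free_parameter_names) == 0:
            raise ValueError("free parameter set must be non-empty")
        bad = set(self.free_parameter_names) - set(PARAMETER_NAMES)
        if bad:
            raise ValueError(f"unknown free parameters: {sorted(bad)}")
        if len(set(self.free_parameter_names)) != len(self.free_parameter_names):
            raise ValueError("duplicate free parameter names")
        if not (0 < self.gamma <= 1):
            raise ValueError("insulin weight gamma must lie in (0, 1]")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.start_noise < 0:
            raise ValueError("start_noise must be >= 0")
        if self.bounds is not None:
            for name, (lo, hi) in self.bounds.items():
                if lo <= 0 or hi <= lo:
                    raise ValueError(f"bounds for {name} must satisfy 0 < low < high")

    def replace(self, **kw) -> "FitConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass
class StartRecord:
    start_values: np.ndarray
    converged: bool
    ssr: float
    n_fev: int
    message: str = ""


@dataclass
class FitResult:
    """Outcome of a multi-start fit for one individual."""

    individual_id: str
    free_parameter_names: tuple[str, ...]
    best_parameters: ModelParameters
    ssr: float
    residuals: np.ndarray
    per_start: list[StartRecord]
    n_function_evals: int

    @property
    def best_free_values(self) -> np.ndarray:
        return np.array([getattr(self.best_parameters, n) for n in self.free_parameter_names])


def _check_grids(sim: SimulatedResponse, obs: OgttResponse) -> None:
    if len(sim.times) != len(obs.times) or not np.allclose(
        sim.times, obs.times, rtol=0, atol=1e-9
    ):
        raise ValueError("simulation and observation time grids differ; no interpolation")


def weighted_ssr(sim: SimulatedResponse, obs: OgttResponse, gamma: float = 0.1) -> float:
    """Combined weighted sum of squared residuals (glucose weight 1,
    insulin weight ``gamma``)."""
    r = residual_vector(sim, obs, gamma)
    return float(r @ r)


def residual_vector(sim: SimulatedResponse, obs: OgttResponse, gamma: float = 0.1) -> np.ndarray:
    """Weighted residuals, glucose block then insulin block; the squared norm
    equals :func:`weighted_ssr` to machine precision."""
    _check_grids(sim, obs)
    g = sim.glucose - np.asarray(obs.glucose)
    i = gamma * (sim.insulin - np.asarray(obs.insulin))
    return np.concatenate([g, i])


def _default_bounds(
    names: Sequence[str], reference: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([getattr(reference, n) for n in names])
    return 1e-4 * ref, 1e3 * ref


def fit_individual(
    obs: OgttResponse,
    config: FitConfig,
    constants: ModelConstants,
    reference: ModelParameters | None = None,
    meal: MealInput = MealInput(),
) -> FitResult:
    """Fit the configured free parameter subset to one individual's data.

    Fixed parameters stay at ``reference`` values (packaged reference if not
    given).  Start 0 is the unperturbed reference; each further start
    multiplies every free parameter by an independent uniform draw from
    ``[1 - noise, 1 + noise]``.  Returns the lowest-SSR converged solution;
    deterministic given ``config.seed``.
    """
    if reference is None:
        from .constants import reference_parameters

        reference = reference_parameters()

    names = config.free_parameter_names
    ref_free = np.array([getattr(reference, n) for n in names])
    if config.bounds is not None:
        lo = np.array([config.bounds.get(n, (1e-4 * r, 1e3 * r))[0] for n, r in zip(names, ref_free)])
        hi = np.array([config.bounds.get(n, (1e-4 * r, 1e3 * r))[1] for n, r in zip(names, ref_free)])
    else:
        lo, hi = _default_bounds(names, reference)

    times = obs.times
    obs_g = np.asarray(obs.glucose)
    obs_i = np.asarray(obs.insulin)
    gamma = config.gamma
    n_eval = [0]

    def residuals(x: np.ndarray) -> np.ndarray:
        n_eval[0] += 1
        p = reference.with_subset(names, x)
        try:
            sim = simulate(
                p, constants, meal, times, rtol=config.sim_rtol, atol=config.sim_atol
            )
        except (SimulationError, ValueError):
            return np.full(2 * len(times), 1e6)
        g = sim.glucose - obs_g
        i = gamma * (sim.insulin - obs_i)
        return np.concatenate([g, i])

    rng = np.random.default_rng(config.seed)
    starts = [ref_free.copy()]
    for _ in range(config.n_starts - 1):
        factors = rng.uniform(1.0 - config.start_noise, 1.0 + config.start_noise, len(names))
        starts.append(ref_free * factors)

    records: list[StartRecord] = []
    best: tuple[float, np.ndarray] | None = None
    for x0 in starts:
        x0c = np.clip(x0, lo, hi)
        r0 = residuals(x0c)
        if not np.all(np.isfinite(r0)):
            records.append(StartRecord(x0c, False, np.inf, 1, "non-finite objective at start"))
            continue
        try:
            sol = least_squares(
                residuals,
                x0c,
                bounds=(lo, hi),
                method="trf",
                x_scale=ref_free,
                ftol=config.solver_tol,
                xtol=config.solver_tol,
                gtol=config.solver_tol,
                max_nfev=config.max_nfev,
            )
        except Exception as exc:  # pragma: no cover - solver-internal failure
            records.append(StartRecord(x0c, False, np.inf, 0, f"solver error: {exc}"))
            continue
        ssr = float(2 * sol.cost)
        records.append(StartRecord(x0c, bool(sol.success), ssr, int(sol.nfev), sol.message))
        if sol.success and (best is None or ssr < best[0]):
            best = (ssr, sol.x.copy())

    if best is None:
        lines = "; ".join(f"start {i}: {r.message}" for i, r in enumerate(records))
        raise FitError(f"all {config.n_starts} starts failed for {obs.individual_id}: {lines}")

    best_p = reference.with_subset(names, best[1])
    sim = simulate(best_p, constants, meal, times, rtol=config.sim_rtol, atol=config.sim_atol)
    res = residual_vector(sim, obs, gamma)
    return FitResult(
        individual_id=obs.individual_id,
        free_parameter_names=tuple(names),
        best_parameters=best_p,
        ssr=float(res @ res),
        residuals=res,
        per_start=records,
        n_function_evals=n_eval[0],
    )
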