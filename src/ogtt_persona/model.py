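"""Two-compartment glucose-insulin ODE model of a 75 g oral glucose challenge.

The model tracks four states after an oral glucose load: glucose mass in the
gut, plasma glucose, plasma insulin, and the accumulated glucose elevation
driving the integral branch of pancreatic insulin secretion.  Physiological
processes, each governed by one of the rate constants ``k1``..``k9``:

* gastric emptying of the ingested dose into the gut (``k1``, with a fixed
  dimensionless shape factor ``sigma``; ``sigma = 1`` is pure exponential
  decay),
* first-order glucose transfer from gut to plasma (``k2``),
* endogenous glucose production by the liver, suppressed proportionally to
  glucose elevation (``k3``) and to insulin elevation (``k4``),
* insulin-dependent glucose uptake into peripheral tissue, saturating in
  glucose through a Michaelis-Menten factor with fixed constant ``km``
  (``k5``),
* pancreatic insulin secretion as a PID controller on glucose elevation:
  proportional (``k6``), integral (``k7``) and derivative (``k8``) branches,
* first-order insulin transfer/degradation in the interstitial fluid
  (``k9``); hepatic insulin clearance uses the fixed rate ``c_liv``.

In addition the plasma compartment loses glucose at a constant basal rate to
obligate glucose oxidizers (brain, red blood cells; Michaelis-Menten
normalized to the basal operating point) and, above the renal threshold, to
urinary excretion.

Units repo-wide: glucose mmol/L, insulin mU/L, time minutes, dose grams;
glucose gram-to-mmol conversion 1000/180.16.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Sequence

import numpy as np

from . import _kernel

__all__ = [
    "GLUCOSE_MMOL_PER_G",
    "PARAMETER_NAMES",
    "ModelParameters",
    "ModelConstants",
    "MealInput",
    "ModelState",
    "SimulatedResponse",
    "GlucoseFluxes",
    "InsulinFluxes",
    "SimulationError",
    "glucose_fluxes",
    "insulin_fluxes",
    "rhs",
    "basal_steady_state",
    "simulate",
]

#: mmol of glucose per gram (molar mass 180.16 g/mol)
GLUCOSE_MMOL_PER_G = 1000.0 / 180.16

#: the nine estimable physiological rate constants, in canonical order
PARAMETER_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9")


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries the offending parameters."""

    def __init__(self, message: str, parameters: "ModelParameters | None" = None):
        super().__init__(message)
        self.parameters = parameters


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants ``k1``..``k9`` plus the two fixed shape constants.

    ``sigma`` (gastric emptying shape) and ``km`` (Michaelis-Menten constant,
    mmol/L) are never estimated; they stay at population values in every fit.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    sigma: float = 1.34
    km: float = 5.0

    #: names that are fixed to population values in every fit
    FIXED = ("sigma", "km")

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {f.name} must be a positive finite number, got {v!r}")
        if self.sigma < 1.0:
            raise ValueError("sigma must be >= 1 (emptying rate finite at t=0)")

    def free_array(self) -> np.ndarray:
        """The nine rate constants as an array in ``PARAMETER_NAMES`` order."""
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])

    def with_values(self, **updates: float) -> "ModelParameters":
        return replace(self, **updates)

    def with_subset(self, names: Sequence[str], values: Sequence[float]) -> "ModelParameters":
        """Copy with the named rate constants replaced by ``values``."""
        bad = set(names) - set(PARAMETER_NAMES)
        if bad:
            raise ValueError(f"not estimable rate constants: {sorted(bad)}")
        return replace(self, **dict(zip(names, values)))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ModelConstants:
    """Individual-level and population-level constants of the flux equations.

    ``Gb``/``Ib`` default to population fasting values but are set to each
    individual's measured fasting glucose/insulin during personalization.
    The basal endogenous glucose production flux is not stored: it is the
    balance term that makes the basal state an exact equilibrium (see
    :func:`basal_egp_flux`).
    """

    Gb: float = 5.0        # basal plasma glucose, mmol/L
    Ib: float = 8.0        # basal plasma insulin, mU/L
    BW: float = 70.0       # body weight, kg
    vG: float = 0.17       # glucose distribution volume fraction, L/kg
    vI: float = 0.13       # insulin distribution volume fraction, L/kg
    f: float = 0.9         # oral glucose bioavailability, dimensionless
    Gth: float = 11.0      # renal glucose threshold, mmol/L
    c1: float = 0.1        # renal clearance above threshold, L/min
    tau_i: float = 100.0   # PID integral time constant, min
    tau_d: float = 10.0    # PID derivative time constant, min
    beta: float = 1.0      # insulin/glucose distribution factor
    c_liv: float = 0.03    # hepatic insulin clearance rate, 1/min
    uii_b_flux: float = 0.55  # basal insulin-independent uptake, mmol/min

    def __post_init__(self):
        for name in ("Gb", "Ib", "BW", "vG", "vI", "tau_i", "tau_d", "beta",
                     "c_liv", "uii_b_flux", "c1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be > 0")
        if not (0 < self.f <= 1):
            raise ValueError("bioavailability f must lie in (0, 1]")
        if self.Gth <= self.Gb:
            raise ValueError("renal threshold Gth must exceed basal glucose Gb")

    @property
    def glucose_volume(self) -> float:
        """Glucose distribution volume, L."""
        return self.vG * self.BW

    def with_fasting(self, Gb: float, Ib: float) -> "ModelConstants":
        return replace(self, Gb=Gb, Ib=Ib)

    def basal_uii(self) -> float:
        """Basal insulin-independent uptake, mmol/L/min."""
        return self.uii_b_flux / self.glucose_volume

    def basal_egp(self, p: ModelParameters) -> float:
        """Basal hepatic glucose production (mmol/L/min), the balance term
        that exactly offsets both uptake fluxes at (Gb, Ib)."""
        uid_b = p.k5 * self.beta * self.Ib * self.Gb / (p.km + self.Gb)
        return self.basal_uii() + uid_b

    def basal_egp_flux(self, p: ModelParameters) -> float:
        """Basal hepatic glucose production, mmol/min."""
        return self.basal_egp(p) * self.glucose_volume


@dataclass(frozen=True)
class MealInput:
    """An oral glucose load."""

    glucose_dose: float = 75.0   # g
    ingestion_time: float = 0.0  # min

    def __post_init__(self):
        if self.glucose_dose < 0:
            raise ValueError("glucose dose must be >= 0")

    @property
    def dose_mmol(self) -> float:
        return self.glucose_dose * GLUCOSE_MMOL_PER_G


@dataclass(frozen=True)
class ModelState:
    gut_glucose_mass: float   # mmol
    plasma_glucose: float     # mmol/L
    plasma_insulin: float     # mU/L
    pid_integral: float       # mmol*min/L

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.gut_glucose_mass, self.plasma_glucose, self.plasma_insulin, self.pid_integral]
        )

    def validate(self) -> None:
        a = self.as_array()
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite model state: {self}")


@dataclass(frozen=True)
class GlucoseFluxes:
    """Glucose fluxes, mmol/L/min in plasma units ('into plasma' positive);
    ``gut_appearance`` is the meal-to-gut emptying rate in mmol/min."""

    gut_appearance: float
    gut_to_plasma: float
    hepatic: float
    insulin_independent_uptake: float
    insulin_dependent_uptake: float
    renal: float

    @property
    def net_plasma(self) -> float:
        return (
            self.gut_to_plasma
            + self.hepatic
            - self.insulin_independent_uptake
            - self.insulin_dependent_uptake
            - self.renal
        )


@dataclass(frozen=True)
class InsulinFluxes:
    """Insulin fluxes, mU/L/min ('into plasma' positive for secretion)."""

    pancreatic_secretion: float
    liver_clearance: float
    interstitial_transfer: float

    @property
    def net(self) -> float:
        return self.pancreatic_secretion - self.liver_clearance - self.interstitial_transfer


@dataclass
class SimulatedResponse:
    """Glucose/insulin trajectories at requested times, with an optional
    dense fine-grid trajectory for plotting and peak detection."""

    times: np.ndarray     # min
    glucose: np.ndarray   # mmol/L
    insulin: np.ndarray   # mU/L
    dense_times: np.ndarray | None = None
    dense_glucose: np.ndarray | None = None
    dense_insulin: np.ndarray | None = None
    dense_gut_mass: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        if not (len(self.times) == len(self.glucose) == len(self.insulin)):
            raise ValueError("times/glucose/insulin lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.glucose)) and np.all(np.isfinite(self.insulin))):
            raise ValueError("non-finite simulated values")


def pack_kernel_params(
    p: ModelParameters, c: ModelConstants, meal: MealInput
) -> np.ndarray:
    """Flatten parameters/constants/meal into the kernel layout."""
    pk = np.empty(_kernel.N_PACKED)
    pk[0:9] = p.free_array()
    pk[9] = p.sigma
    pk[10] = p.km
    pk[11] = c.Gb
    pk[12] = c.Ib
    pk[13] = c.glucose_volume
    pk[14] = c.f * meal.dose_mmol
    pk[15] = c.Gth
    pk[16] = c.c1
    pk[17] = c.tau_i
    pk[18] = c.tau_d
    pk[19] = c.beta
    pk[20] = c.c_liv
    pk[21] = c.basal_uii()
    pk[22] = c.basal_egp(p)
    pk[23] = meal.ingestion_time
    return pk


def glucose_fluxes(
    state: ModelState,
    t: float,
    p: ModelParameters,
    c: ModelConstants,
    meal: MealInput,
) -> GlucoseFluxes:
    """All glucose fluxes at one instant.  Reference (unjitted) algebra; the
    integration kernel mirrors it exactly and the test-suite asserts so."""
    state.validate()
    if meal.glucose_dose < 0:
        raise ValueError("negative glucose dose")
    M, G, I = state.gut_glucose_mass, state.plasma_glucose, state.plasma_insulin

    tm = t - meal.ingestion_time
    fD = c.f * meal.dose_mmol
    if tm > 0 and fD > 0:
        z = p.k1 * tm
        ra = fD * p.sigma * p.k1 * z ** (p.sigma - 1.0) * np.exp(-(z**p.sigma))
    else:
        ra = 0.0

    gut_to_plasma = p.k2 * M / c.glucose_volume
    # net hepatic balance; negative values mean net hepatic uptake
    egp = c.basal_egp(p) - p.k3 * (G - c.Gb) - p.k4 * c.beta * (I - c.Ib)
    sat = G / (p.km + G)
    uii = c.basal_uii() * sat / (c.Gb / (p.km + c.Gb))
    uid = p.k5 * c.beta * I * sat
    ren = c.c1 * max(G - c.Gth, 0.0) / c.glucose_volume
    return GlucoseFluxes(ra, gut_to_plasma, egp, uii, uid, ren)


def insulin_fluxes(
    state: ModelState,
    dGdt: float,
    p: ModelParameters,
    c: ModelConstants,
) -> InsulinFluxes:
    """Insulin fluxes given the instantaneous glucose derivative.

    The PID secretion combines a proportional branch ``k6 (G - Gb)``, an
    integral branch ``(k7 / tau_i) J`` and a derivative branch
    ``k8 tau_d dG/dt``, scaled by the distribution factor ``beta`` and
    clamped at zero (secretion cannot reverse).  Both clearance terms are
    linear in the insulin elevation ``I - Ib``, so the basal state carries no
    net insulin flux.
    """
    if not np.isfinite(dGdt):
        raise ValueError("non-finite glucose derivative")
    state.validate()
    G, I, J = state.plasma_glucose, state.plasma_insulin, state.pid_integral
    sec = (p.k6 * (G - c.Gb) + (p.k7 / c.tau_i) * J + p.k8 * c.tau_d * dGdt) / c.beta
    sec = max(sec, 0.0)
    return InsulinFluxes(
        pancreatic_secretion=sec,
        liver_clearance=c.c_liv * (I - c.Ib),
        interstitial_transfer=p.k9 * (I - c.Ib),
    )


def rhs(
    state: ModelState,
    t: float,
    p: ModelParameters,
    c: ModelConstants,
    meal: MealInput,
) -> np.ndarray:
    """State derivative [dM, dG, dI, dJ].  The PID derivative branch uses the
    algebraically computed glucose derivative from the same call."""
    gf = glucose_fluxes(state, t, p, c, meal)
    dG = gf.net_plasma
    dM = gf.gut_appearance - p.k2 * state.gut_glucose_mass
    inf = insulin_fluxes(state, dG, p, c)
    return np.array([dM, dG, inf.net, state.plasma_glucose - c.Gb])


def basal_steady_state(p: ModelParameters, c: ModelConstants) -> ModelState:
    """Pre-load equilibrium: empty gut, fasting glucose/insulin, zero PID
    integral.  Exact by construction of the basal EGP balance term."""
    return ModelState(0.0, c.Gb, c.Ib, 0.0)


def simulate(
    p: ModelParameters,
    c: ModelConstants,
    meal: MealInput = MealInput(),
    times: Sequence[float] = (0.0, 30.0, 60.0, 90.0, 120.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dense: bool = False,
    dense_step: float = 1.0,
) -> SimulatedResponse:
    """Simulate plasma glucose/insulin from the basal steady state.

    Trajectories are reported at ``times`` (minutes, within [0, 1440]).
    ``dense=True`` additionally stores a fine-grid trajectory.  Raises
    :class:`SimulationError` if the adaptive integrator fails.
    """
    t_req = np.asarray(times, dtype=float)
    if t_req.ndim != 1 or len(t_req) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t_req) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_req[0] < 0 or t_req[-1] > 1440:
        raise ValueError("times must lie within [0, 1440] minutes")

    pk = pack_kernel_params(p, c, meal)
    y0 = basal_steady_state(p, c).as_array()

    t_end = t_req[-1]
    if dense:
        grid = np.arange(0.0, t_end + 0.5 * dense_step, dense_step)
        t_all = np.union1d(grid, t_req)
    else:
        t_all = t_req if t_req[0] == 0.0 else np.concatenate(([0.0], t_req))

    ys, status = _kernel.integrate(pk, y0, t_all, rtol, atol, 5.0)
    if status != 0 or not np.all(np.isfinite(ys)):
        raise SimulationError(
            f"integration failed (status={status}) for parameters {p.as_dict()}", p
        )

    idx = np.searchsorted(t_all, t_req)
    resp = SimulatedResponse(t_req, ys[idx, 1], ys[idx, 2])
    if dense:
        resp.dense_times = t_all
        resp.dense_glucose = ys[:, 1]
        resp.dense_insulin = ys[:, 2]
        resp.dense_gut_mass = ys[:, 0]
    return resp
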