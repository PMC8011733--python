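"""Cohort-scale personalization and downstream analyses.

ADA phenotype classification from fasting and 2-hour glucose, trapezoidal
AUC, the Matsuda and insulinogenic surrogate indices, per-individual fitting
of the selected parameter subset, the group-median versus individual
simulation comparison, and PCA of the personalized parameter space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .estimation import FitConfig, FitError, FitResult, OgttResponse, fit_individual, weighted_ssr
from .model import MealInput, ModelConstants, ModelParameters, simulate

__all__ = [
    "ADA_LABELS",
    "MMOL_L_TO_MG_DL",
    "ada_classify",
    "auc_trapezoid",
    "matsuda_index",
    "insulinogenic_index",
    "PersonalizedIndividual",
    "PersonalizedCohort",
    "personalize_cohort",
    "GroupComparison",
    "compare_group_vs_individual",
    "PcaEmbedding",
    "pca_embed",
]

logger = logging.getLogger(__name__)

ADA_LABELS = ("NGT", "IFG", "IGT", "IFG&IGT", "T2DM")

#: mg/dL per mmol/L of glucose
MMOL_L_TO_MG_DL = 18.016

# standard two-hour OGTT thresholds, mmol/L; boundary values fall in the
# impaired class (>= convention)
_IFG_LO, _DM_FASTING = 5.6, 7.0
_IGT_LO, _DM_2H = 7.8, 11.1


def ada_classify(fasting_glucose: float, two_hour_glucose: float) -> str:
    """ADA phenotype from fasting and 2-hour plasma glucose (mmol/L):
    T2DM if fasting >= 7.0 or 2h >= 11.1; otherwise IFG for fasting in
    [5.6, 7.0), IGT for 2h in [7.8, 11.1), IFG&IGT when both hold, else NGT."""
    if not (np.isfinite(fasting_glucose) and np.isfinite(two_hour_glucose)):
        raise ValueError("non-finite glucose value")
    if fasting_glucose <= 0 or two_hour_glucose <= 0:
        raise ValueError("glucose values must be > 0")
    if fasting_glucose >= _DM_FASTING or two_hour_glucose >= _DM_2H:
        return "T2DM"
    ifg = fasting_glucose >= _IFG_LO
    igt = two_hour_glucose >= _IGT_LO
    if ifg and igt:
        return "IFG&IGT"
    if ifg:
        return "IFG"
    if igt:
        return "IGT"
    return "NGT"


def auc_trapezoid(times, values) -> float:
    """Trapezoidal area under the curve (value * min); exact for
    piecewise-linear input."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def matsuda_index(obs: OgttResponse) -> float:
    """Composite whole-body insulin sensitivity index:
    10000 / sqrt(G0 * I0 * Gmean * Imean) with glucose in mg/dL and insulin
    in uU/mL, means taken over all five OGTT points."""
    g = np.asarray(obs.glucose) * MMOL_L_TO_MG_DL
    i = np.asarray(obs.insulin)  # mU/L == uU/mL
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("concentrations must be positive")
    return float(10000.0 / math.sqrt(g[0] * i[0] * g.mean() * i.mean()))


def insulinogenic_index(obs: OgttResponse) -> float:
    """First-phase secretion surrogate (I30 - I0)/(G30 - G0), mU/L per
    mmol/L; undefined (raises) when G30 equals G0."""
    try:
        i30 = obs.insulin[obs.times.index(30.0)]
        g30 = obs.glucose[obs.times.index(30.0)]
    except ValueError as exc:
        raise ValueError("response has no 30-minute sample") from exc
    dg = g30 - obs.fasting_glucose
    if dg == 0:
        raise ZeroDivisionError(
            f"individual {obs.individual_id}: G30 equals G0, insulinogenic index undefined"
        )
    return float((i30 - obs.fasting_insulin) / dg)


@dataclass
class PersonalizedIndividual:
    response: OgttResponse
    label: str
    fit: FitResult | None
    matsuda: float
    insulinogenic: float | None
    error: str | None = None


@dataclass
class PersonalizedCohort:
    """One fitted model per retained individual plus phenotype labels and
    OGTT-derived indices."""

    individuals: list[PersonalizedIndividual]
    subset: tuple[str, ...]

    @property
    def fitted(self) -> list[PersonalizedIndividual]:
        return [m for m in self.individuals if m.fit is not None]

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        for m in self.fitted:
            row = {
                "individual_id": m.response.individual_id,
                "label": m.label,
                "ssr": m.fit.ssr,
                "matsuda": m.matsuda,
                "insulinogenic": m.insulinogenic,
            }
            row.update(dict(zip(self.subset, m.fit.best_free_values)))
            rows.append(row)
        return pd.DataFrame(rows)


def personalize_cohort(
    cohort: list[OgttResponse],
    config: FitConfig,
    constants: ModelConstants,
    reference: ModelParameters | None = None,
    progress: bool = False,
) -> PersonalizedCohort:
    """Fit the selected subset to every individual.

    Basal Gb/Ib are set to each individual's measured fasting values.  Fit
    failures are recorded on the individual, never silently dropped.
    """
    out: list[PersonalizedIndividual] = []
    for i, resp in enumerate(cohort):
        if progress and i % 25 == 0:
            logger.info("personalizing %d/%d", i, len(cohort))
        label = ada_classify(resp.fasting_glucose, resp.two_hour_glucose)
        cons = constants.with_fasting(resp.fasting_glucose, resp.fasting_insulin)
        try:
            igi = insulinogenic_index(resp)
        except ZeroDivisionError:
            logger.warning("insulinogenic index undefined for %s", resp.individual_id)
            igi = None
        try:
            fit = fit_individual(resp, config, cons, reference=reference)
            err = None
        except FitError as exc:
            logger.warning("fit failed for %s: %s", resp.individual_id, exc)
            fit, err = None, str(exc)
        out.append(
            PersonalizedIndividual(resp, label, fit, matsuda_index(resp), igi, err)
        )
    return PersonalizedCohort(out, tuple(config.free_parameter_names))


@dataclass
class GroupComparison:
    label: str
    n: int
    group_ssr_mean: float
    group_ssr_sd: float
    individual_ssr_mean: float
    individual_ssr_sd: float

    @property
    def fold_decrease(self) -> float:
        return self.group_ssr_mean / self.individual_ssr_mean


def compare_group_vs_individual(
    personalized: PersonalizedCohort,
    config: FitConfig,
    constants: ModelConstants,
    reference: ModelParameters | None = None,
) -> dict[str, GroupComparison]:
    """Discrepancy of group-median simulations versus personalized ones.

    For each phenotype group the per-time-point median curve is fitted with
    the same subset; the fitted median model is then simulated against every
    group member's data and the weighted SSR distribution is compared with
    the members' own personalized-fit SSRs.
    """
    from .selection import REPRESENTATIVE_LABELS  # label order only

    groups: dict[str, list[PersonalizedIndividual]] = {}
    for m in personalized.fitted:
        groups.setdefault(m.label, []).append(m)

    out: dict[str, GroupComparison] = {}
    for label in REPRESENTATIVE_LABELS[:5]:
        members = groups.get(label, [])
        if not members:
            logger.warning("group %s has no fitted individuals; omitted", label)
            continue
        times = members[0].response.times
        med_g = np.median([m.response.glucose for m in members], axis=0)
        med_i = np.median([m.response.insulin for m in members], axis=0)
        median_resp = OgttResponse.from_arrays(f"median_{label}", times, med_g, med_i)
        cons = constants.with_fasting(median_resp.fasting_glucose, median_resp.fasting_insulin)
        med_fit = fit_individual(median_resp, config, cons, reference=reference)
        med_sim = simulate(
            med_fit.best_parameters, cons, MealInput(), times,
            rtol=config.sim_rtol, atol=config.sim_atol,
        )
        group_ssrs = np.array(
            [weighted_ssr(med_sim, m.response, config.gamma) for m in members]
        )
        ind_ssrs = np.array([m.fit.ssr for m in members])
        out[label] = GroupComparison(
            label,
            len(members),
            float(group_ssrs.mean()),
            float(group_ssrs.std(ddof=1)) if len(members) > 1 else 0.0,
            float(ind_ssrs.mean()),
            float(ind_ssrs.std(ddof=1)) if len(members) > 1 else 0.0,
        )
    return out


@dataclass
class PcaEmbedding:
    scores: np.ndarray                 # (n_individuals, 2)
    loadings: np.ndarray               # (2, n_parameters), orthonormal rows
    explained_variance_fraction: np.ndarray
    parameter_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray


def pca_embed(table: pd.DataFrame, parameter_names=None) -> PcaEmbedding:
    """Two-component PCA of the standardized personalized parameters.

    Columns are normalized to zero mean and unit standard deviation.  Sign
    convention: the largest-magnitude loading of each component is positive.
    """
    if parameter_names is None:
        parameter_names = [c for c in table.columns if c.startswith("k")]
    X = table[list(parameter_names)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 individuals for PCA")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing or non-finite parameter values")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = np.where(scale == 0)[0]
    if len(zero):
        raise ValueError(f"zero-variance parameter column: {parameter_names[zero[0]]}")
    Z = (X - mean) / scale
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return PcaEmbedding(
        scores,
        loadings,
        pca.explained_variance_ratio_,
        tuple(parameter_names),
        mean,
        scale,
    )
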