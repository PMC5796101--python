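"""Leaf photosynthesis models and whole-plant integration.

The leaf model is the empirical two-variable light x CO2 response for young
'Irwin' mango leaves: the product of two negative-exponential saturation
curves minus a dark-respiration offset,

    P(I, C) = P_max * (1 - exp(-k_I * I)) * (1 - exp(-k_C * C)) - R_d

with P in umolCO2 m^-2 s^-1, I the incident PPFD (umol m^-2 s^-1) and C the
CO2 mole fraction (umol mol^-1). At I = 0 the model returns -R_d for any C;
for I, C -> infinity it saturates at P_max - R_d. The whole-plant rate is the
leaf-area-weighted mean of per-leaf rates, i.e. total canopy CO2 flux divided
by total one-sided leaf area — the same normalization the closed-chamber
measurement uses.

Temperature, humidity and stomatal conductance are deliberately outside the
model; single saturation curves in either variable (rectangular hyperbola or
negative exponential) are provided for light- or CO2-response fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SaturationCurveParams",
    "TwoVariableModel",
    "WholePlantRate",
    "FitResult",
    "IRWIN_MODEL",
    "saturation_response",
    "leaf_net_photosynthesis",
    "whole_plant_rate",
    "fit_two_variable_model",
]


@dataclass(frozen=True)
class SaturationCurveParams:
    """Single-variable saturation curve P = f(X).

    ``rectangular_hyperbola``: P = a*X/(X + b) + c
    ``negative_exponential``:  P = a*(1 - exp(-b*X)) + c
    """

    form: str
    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.form not in ("rectangular_hyperbola", "negative_exponential"):
            raise ValueError(f"unknown saturation form '{self.form}'")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")


@dataclass(frozen=True)
class TwoVariableModel:
    p_max: float   # asymptotic gross rate, umolCO2 m^-2 s^-1
    k_I: float     # light curvature, (umol m^-2 s^-1)^-1
    k_C: float     # CO2 curvature, (umol mol^-1)^-1
    r_d: float     # dark respiration offset, umolCO2 m^-2 s^-1

    def __post_init__(self):
        if min(self.p_max, self.k_I, self.k_C, self.r_d) <= 0:
            raise ValueError("all model parameters must be positive")


#: Fitted parameters for newly matured 'Irwin' mango leaves.
IRWIN_MODEL = TwoVariableModel(p_max=12.928, k_I=0.014, k_C=0.001, r_d=0.889)


@dataclass
class WholePlantRate:
    """Whole-plant CO2 uptake and its per-leaf decomposition."""

    rate_per_leaf_area: float   # umolCO2 m^-2(leaf) s^-1
    total_flux: float           # umolCO2 s^-1
    per_leaf: pd.DataFrame      # leaf_id, ppfd, rate, area(m^2)


def saturation_response(X, params: SaturationCurveParams):
    """Evaluate a single-variable saturation curve at X >= 0."""
    X = np.asarray(X, float)
    if np.any(X < 0):
        raise ValueError("X must be >= 0")
    if params.form == "rectangular_hyperbola":
        out = params.a * X / (X + params.b) + params.c
    else:
        out = params.a * (1.0 - np.exp(-params.b * X)) + params.c
    return out if out.ndim else float(out)


def leaf_net_photosynthesis(I, C, model: TwoVariableModel = IRWIN_MODEL):
    """Net leaf photosynthetic rate (umolCO2 m^-2 s^-1) at PPFD I and CO2 C."""
    I = np.asarray(I, float)
    C = np.asarray(C, float)
    if np.any(I < 0) or np.any(C < 0):
        raise ValueError("PPFD and CO2 must be >= 0")
    out = (model.p_max
           * (1.0 - np.exp(-model.k_I * I))
           * (1.0 - np.exp(-model.k_C * C))
           - model.r_d)
    return out if out.ndim else float(out)


def whole_plant_rate(leaf_ppfd_table: pd.DataFrame, leaf_areas: dict,
                     C: float, model: TwoVariableModel = IRWIN_MODEL,
                     ) -> WholePlantRate:
    """Area-weighted whole-plant net photosynthesis at CO2 concentration C.

    ``leaf_ppfd_table`` needs columns ``leaf_id`` and ``ppfd`` (leaf-mean
    incident PPFD); ``leaf_areas`` maps leaf_id -> one-sided area in m^2.
    Every table row must have an area and vice versa.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    ids = [int(i) for i in leaf_ppfd_table["leaf_id"]]
    if set(ids) != set(int(k) for k in leaf_areas):
        raise KeyError("leaf ids of PPFD table and area map do not match")
    ppfd = np.asarray(leaf_ppfd_table["ppfd"], float)
    areas = np.array([leaf_areas[i] for i in ids], float)
    rates = leaf_net_photosynthesis(ppfd, np.full_like(ppfd, C), model)
    total_flux = float(np.sum(rates * areas))
    table = pd.DataFrame({"leaf_id": ids, "ppfd": ppfd, "rate": rates,
                          "area": areas})
    return WholePlantRate(rate_per_leaf_area=total_flux / areas.sum(),
                          total_flux=total_flux, per_leaf=table)


# ----------------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------------

@dataclass
class FitResult:
    success: bool
    model: TwoVariableModel | None
    rmse: float
    message: str = ""


def _residuals(theta, I, C, P):
    pmax, ki, kc, rd = theta
    return pmax * (1 - np.exp(-ki * I)) * (1 - np.exp(-kc * C)) - rd - P


def _jacobian(theta, I, C, P):
    pmax, ki, kc, rd = theta
    eI = np.exp(-ki * I)
    eC = np.exp(-kc * C)
    J = np.empty((len(I), 4))
    J[:, 0] = (1 - eI) * (1 - eC)
    J[:, 1] = pmax * I * eI * (1 - eC)
    J[:, 2] = pmax * (1 - eI) * C * eC
    J[:, 3] = -1.0
    return J


def fit_two_variable_model(observations, initial_guess=None,
                           n_starts: int = 5, rng_seed: int = 0) -> FitResult:
    """Recover two-variable model parameters by nonlinear least squares.

    ``observations`` is an iterable of (I, C, P) triples spanning both axes
    (>= 8 points). Trust-region least squares with the analytic Jacobian and
    all-positive bounds; a seeded multi-start (perturbed initial guesses)
    guards against local minima. Returns a :class:`FitResult` whose
    ``success`` is False when the data cannot identify the parameters.
    """
    obs = np.asarray(list(observations), float)
    if obs.ndim != 2 or obs.shape[0] < 8 or obs.shape[1] != 3:
        raise ValueError("need >= 8 (I, C, P) observations")
    I, C, P = obs.T
    if np.ptp(I) <= 0 or np.ptp(C) <= 0:
        return FitResult(False, None, math.nan, "observations span a single axis")
    if np.ptp(P) < 1e-12:
        return FitResult(False, None, math.nan,
                         "constant response: parameters unidentifiable")

    if initial_guess is None:
        p0 = np.array([max(P.max() - P.min(), 1.0) * 1.5,
                       2.0 / max(I.max(), 1.0),
                       2.0 / max(C.max(), 1.0),
                       max(-P.min(), 0.1)])
    else:
        p0 = np.asarray(initial_guess, float)

    rng = np.random.default_rng(rng_seed)
    lb = np.array([1e-6, 1e-8, 1e-8, 1e-6])
    ub = np.array([1e3, 1.0, 1.0, 1e2])
    best = None
    for s in range(n_starts):
        start = p0 if s == 0 else np.clip(
            p0 * rng.lognormal(0.0, 0.4, size=4), lb, ub)
        try:
            res = least_squares(_residuals, start, jac=_jacobian,
                                bounds=(lb, ub), args=(I, C, P),
                                method="trf", xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return FitResult(False, None, math.nan, "optimizer failed to converge")
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    model = TwoVariableModel(*[float(x) for x in best.x])
    return FitResult(True, model, rmse, "converged")
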