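"""Model fitting, goodness-of-fit metrics, enthalpies and crossover pressure.

Fitting minimizes, by default, the average absolute relative deviation

    AARD% = (100/N) * sum_i |y_pred_i - y_meas_i| / y_meas_i,

the headline metric by which density-based solubility correlations are
ranked.  Squared-error objectives on y and on ln y are available as
alternatives.

The optimizer is deterministic: every model is linear in its parameters in
a suitable transformed coordinate system once the association number kappa
is fixed, so ordinary least squares on that linearization (profiled over
kappa where needed) provides warm starts, which Nelder-Mead then refines on
the chosen objective.  A fixed grid of kappa starting values guards against
local minima.  Two runs with the same inputs produce bit-identical results.

Temperature coefficients of the fitted models carry enthalpies: the
Chrastil-family B constant gives the total enthalpy of dissolution
(|B| * R), the Bartle B4 constant the sublimation enthalpy (-B4 * R), and
their difference the (negative) solvation enthalpy.

The crossover pressure — where solubility isotherms at two temperatures
intersect, separating the density-dominated from the sublimation-pressure-
dominated regime — is located by bracketing and bisection on a fitted
model over a density surface interpolated from tabulated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import lstsq
from scipy.optimize import brentq, minimize, minimize_scalar

from .data import SITAGLIPTIN, SolubilityDataset, SubstanceInfo, convert_y_to_c
from .models import (
    GAS_CONSTANT_ATM,
    MODELS,
    P_STAR_BAR,
    get_model,
    model_predict,
    params_to_vector,
    vector_to_params,
)

__all__ = [
    "GAS_CONSTANT",
    "OBJECTIVES",
    "FitError",
    "FitResult",
    "EnthalpySet",
    "aard",
    "goodness_of_fit",
    "fit_model",
    "evaluate_model",
    "derive_enthalpies",
    "find_crossover",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
OBJECTIVES = ("aard", "sse_log", "sse")

_KAPPA_GRID = (1.0, 2.0, 4.0, 8.0)
_NM_OPTS = dict(xatol=1e-10, fatol=1e-10, maxiter=20000, maxfev=40000)
_PENALTY = 1e10


class FitError(RuntimeError):
    """All optimizer starts failed to produce a finite objective."""


def aard(y_measured, y_predicted) -> float:
    """Average absolute relative deviation, in percent."""
    y_m = np.asarray(y_measured, dtype=float)
    y_p = np.asarray(y_predicted, dtype=float)
    if y_m.shape != y_p.shape or y_m.size == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    if np.any(y_m <= 0):
        raise ValueError("measured values must be positive")
    return float(100.0 * np.mean(np.abs(y_p - y_m) / y_m))


def goodness_of_fit(y_measured, y_predicted, n_params: int) -> tuple[float, float]:
    """Coefficient of determination and its adjusted form.

    R^2 = 1 - SS_res/SS_tot; R^2_adj = 1 - (1 - R^2)(n-1)/(n-p-1) with p
    the number of fitted parameters.
    """
    y_m = np.asarray(y_measured, dtype=float)
    y_p = np.asarray(y_predicted, dtype=float)
    n = y_m.size
    if y_m.shape != y_p.shape:
        raise ValueError("length mismatch")
    if n <= n_params + 1:
        raise ValueError(f"need more than p+1 = {n_params + 1} points, got {n}")
    ss_res = float(np.sum((y_m - y_p) ** 2))
    ss_tot = float(np.sum((y_m - np.mean(y_m)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    return r2, r2_adj


def _objective_value(kind: str, y_meas: np.ndarray, y_pred: np.ndarray) -> float:
    if np.any(~np.isfinite(y_pred)) or np.any(y_pred <= 0):
        return _PENALTY
    if kind == "aard":
        return float(100.0 * np.mean(np.abs(y_pred - y_meas) / y_meas))
    if kind == "sse_log":
        return float(np.sum((np.log(y_pred) - np.log(y_meas)) ** 2))
    if kind == "sse":
        # scaled so tolerances behave sensibly for y ~ 1e-5
        scale = float(np.mean(y_meas)) ** 2
        return float(np.sum((y_pred - y_meas) ** 2) / scale)
    raise ValueError(f"unknown objective {kind!r}; choose from {OBJECTIVES}")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus per-point predictions and metrics."""

    model_id: str
    params: dict[str, float]
    aard_percent: float
    r2: float
    r2_adj: float
    predictions: tuple[float, ...]
    residuals: tuple[float, ...]
    objective: str
    objective_value: float
    n_starts: int
    converged: bool

    @property
    def param_vector(self) -> np.ndarray:
        return params_to_vector(self.model_id, self.params)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "aard_percent": self.aard_percent,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "objective": self.objective,
            "objective_value": self.objective_value,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "predictions": list(self.predictions),
            "residuals": list(self.residuals),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def _target_values(model_id: str, dataset: SolubilityDataset) -> np.ndarray:
    """The measured quantity the model predicts (y2, or c for chrastil_c)."""
    y = dataset.mole_fractions
    if model_id == "chrastil_c":
        return convert_y_to_c(
            y,
            dataset.densities,
            dataset.substance.model_molar_mass,
            dataset.substance.molar_mass_solvent,
        )
    return y


def _predict_dataset(model_id, vec, dataset, p_star_bar):
    return np.asarray(
        model_predict(
            model_id,
            vec,
            dataset.temperatures,
            dataset.pressures,
            dataset.densities,
            dataset.substance,
            p_star_bar=p_star_bar,
        )
    )


# ---------------------------------------------------------------------------
# linearized warm starts
#
# Exact linearizations (no dilute approximation):
#   chrastil / chrastil_c: ln(y/(1-y)) = ln(M1/M2) + (k-1) ln rho + A + B/T
#   reformulated_chrastil: ln y = (k-1) ln(R T rho / M1) + A + B/T
#   mst:    T ln(y P) = A + B rho + C T
#   bartle: ln(y P)   = A + B/T + C (rho - rho_ref)
#   kj:     ln y      = A + B rho + C/T
#   association (k fixed): ln(y/(1-k y)) - (k-1) ln P = A/T + B ln T + C rho + D
# ---------------------------------------------------------------------------


def _ols(X: np.ndarray, b: np.ndarray) -> np.ndarray:
    coef, *_ = lstsq(X, b)
    return coef


def _linear_start(model_id, dataset, p_star_bar, kappa=None) -> np.ndarray:
    T = dataset.temperatures
    p_bar = dataset.pressures * 10.0
    rho = dataset.densities
    y = dataset.mole_fractions
    one = np.ones_like(T)
    sub = dataset.substance

    if model_id in ("chrastil", "chrastil_c"):
        b = np.log(y / (1.0 - y)) - np.log(sub.molar_mass_solvent / sub.model_molar_mass)
        if kappa is None:
            c = _ols(np.column_stack([np.log(rho), one, 1.0 / T]), b)
            return np.array([c[0] + 1.0, c[1], c[2]])
        c = _ols(np.column_stack([one, 1.0 / T]), b - (kappa - 1.0) * np.log(rho))
        return np.array([kappa, c[0], c[1]])
    if model_id == "reformulated_chrastil":
        x = np.log(GAS_CONSTANT_ATM * T * rho / sub.molar_mass_solvent)
        if kappa is None:
            c = _ols(np.column_stack([x, one, 1.0 / T]), np.log(y))
            return np.array([c[0] + 1.0, c[1], c[2]])
        c = _ols(np.column_stack([one, 1.0 / T]), np.log(y) - (kappa - 1.0) * x)
        return np.array([kappa, c[0], c[1]])
    if model_id == "mst":
        return _ols(np.column_stack([one, rho, T]), T * np.log(y * p_bar))
    if model_id == "bartle":
        return _ols(np.column_stack([one, 1.0 / T, rho - 700.0]), np.log(y * p_bar))
    if model_id == "kj":
        return _ols(np.column_stack([one, rho, 1.0 / T]), np.log(y))
    if model_id == "association":
        k = 1.0 if kappa is None else kappa
        b = np.log(y / (1.0 - k * y)) - (k - 1.0) * np.log(p_bar / p_star_bar)
        c = _ols(np.column_stack([1.0 / T, np.log(T), rho, one]), b)
        return np.array([k, c[0], c[1], c[2], c[3]])
    raise KeyError(model_id)


def _profile_kappa_start(model_id, dataset, objective, p_star_bar) -> np.ndarray:
    """Concentrate the fit onto kappa: inner OLS, outer 1-d search."""
    y_meas = _target_values(model_id, dataset)

    def score(k):
        vec = _linear_start(model_id, dataset, p_star_bar, kappa=k)
        y_pred = _predict_dataset(model_id, vec, dataset, p_star_bar)
        return _objective_value(objective, y_meas, y_pred)

    res = minimize_scalar(
        score, bounds=(1e-3, 20.0), method="bounded",
        options=dict(xatol=1e-9, maxiter=500),
    )
    return _linear_start(model_id, dataset, p_star_bar, kappa=float(res.x))


def fit_model(
    model_id: str,
    dataset: SolubilityDataset,
    objective: str = "aard",
    kappa_grid: Sequence[float] = _KAPPA_GRID,
    p_star_bar: float = P_STAR_BAR,
) -> FitResult:
    """Fit a model to a dataset by multistart derivative-free minimization.

    Warm starts come from exact ordinary-least-squares linearizations
    (profiled over the association number for models that have one, plus a
    fixed kappa grid); each start is refined with Nelder-Mead on the chosen
    objective and the best refined candidate wins (ties broken by start
    order).  Deterministic: identical inputs give bit-identical results.
    """
    spec = get_model(model_id)
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}; choose from {OBJECTIVES}")
    dataset.require_fittable()
    y_meas = _target_values(model_id, dataset)

    def fun(vec):
        if spec.parameter_names[0] == "kappa" and vec[0] <= 0:
            return _PENALTY
        with np.errstate(all="ignore"):
            y_pred = _predict_dataset(model_id, vec, dataset, p_star_bar)
        return _objective_value(objective, y_meas, np.asarray(y_pred))

    starts = [_linear_start(model_id, dataset, p_star_bar)]
    if spec.parameter_names[0] == "kappa":
        starts.append(_profile_kappa_start(model_id, dataset, objective, p_star_bar))
        for k in kappa_grid:
            starts.append(_linear_start(model_id, dataset, p_star_bar, kappa=float(k)))

    candidates: list[tuple[float, np.ndarray, bool]] = []
    for s in starts:
        candidates.append((fun(s), s, True))
        res = minimize(fun, s, method="Nelder-Mead", options=_NM_OPTS)
        # restart once with a fresh simplex; helps collapsed simplexes
        res = minimize(fun, res.x, method="Nelder-Mead", options=_NM_OPTS)
        candidates.append((res.fun, res.x, bool(res.success)))

    best_val, best_vec, best_ok = min(candidates, key=lambda c: c[0])
    if not np.isfinite(best_val) or best_val >= _PENALTY:
        raise FitError(
            f"{model_id}: no start converged to a finite {objective} "
            f"({len(starts)} starts tried)"
        )
    return _make_result(
        model_id, best_vec, dataset, objective, best_val, y_meas,
        n_starts=len(starts), converged=best_ok, p_star_bar=p_star_bar,
    )


def evaluate_model(
    model_id: str,
    params,
    dataset: SolubilityDataset,
    objective: str = "aard",
    p_star_bar: float = P_STAR_BAR,
) -> FitResult:
    """Metrics of a model at fixed parameters (no fitting)."""
    vec = params_to_vector(model_id, params)
    y_meas = _target_values(model_id, dataset)
    y_pred = _predict_dataset(model_id, vec, dataset, p_star_bar)
    val = _objective_value(objective, y_meas, np.asarray(y_pred))
    return _make_result(
        model_id, vec, dataset, objective, val, y_meas,
        n_starts=0, converged=True, p_star_bar=p_star_bar,
    )


def _make_result(model_id, vec, dataset, objective, value, y_meas,
                 n_starts, converged, p_star_bar) -> FitResult:
    y_pred = np.asarray(_predict_dataset(model_id, vec, dataset, p_star_bar))
    r2, r2_adj = goodness_of_fit(y_meas, y_pred, get_model(model_id).n_params)
    return FitResult(
        model_id=model_id,
        params=vector_to_params(model_id, vec),
        aard_percent=aard(y_meas, y_pred),
        r2=r2,
        r2_adj=r2_adj,
        predictions=tuple(float(v) for v in y_pred),
        residuals=tuple(float(v) for v in (y_pred - y_meas)),
        objective=objective,
        objective_value=float(value),
        n_starts=n_starts,
        converged=converged,
    )


@dataclass(frozen=True)
class EnthalpySet:
    """Dissolution enthalpies in kJ mol^-1, with the models that produced them.

    ``total`` is the enthalpy of dissolution in scCO2 (endothermic, reported
    positive), ``sublimation`` the solid->vapor enthalpy, and ``solvation``
    their difference (exothermic, negative) -- an identity by construction.
    """

    total_kJ_mol: float
    sublimation_kJ_mol: float
    solvation_kJ_mol: float
    total_source: str
    sublimation_source: str


_TOTAL_B = {"chrastil": "B1", "chrastil_c": "B1", "reformulated_chrastil": "B2"}


def derive_enthalpies(chrastil_fit: FitResult, bartle_fit: FitResult) -> EnthalpySet:
    """Enthalpies from the fitted temperature coefficients.

    total = |B| * R / 1000 from a Chrastil-family fit, sublimation =
    -B4 * R / 1000 from the Bartle fit, solvation = total - sublimation,
    with R = 8.314 J mol^-1 K^-1.
    """
    if chrastil_fit.model_id not in _TOTAL_B:
        raise ValueError(
            f"total enthalpy needs a Chrastil-family fit, got {chrastil_fit.model_id!r}"
        )
    if bartle_fit.model_id != "bartle":
        raise ValueError(f"sublimation enthalpy needs a bartle fit, got {bartle_fit.model_id!r}")
    b_total = chrastil_fit.params[_TOTAL_B[chrastil_fit.model_id]]
    b4 = bartle_fit.params["B4"]
    total = abs(b_total) * GAS_CONSTANT / 1000.0
    sublimation = -b4 * GAS_CONSTANT / 1000.0
    return EnthalpySet(
        total_kJ_mol=total,
        sublimation_kJ_mol=sublimation,
        solvation_kJ_mol=total - sublimation,
        total_source=chrastil_fit.model_id,
        sublimation_source=bartle_fit.model_id,
    )


def find_crossover(
    model_id: str,
    params,
    T_low: float,
    T_high: float,
    p_range: tuple[float, float],
    density_surface: Callable[[float, float], float],
    substance: SubstanceInfo = SITAGLIPTIN,
    p_star_bar: float = P_STAR_BAR,
    n_scan: int = 200,
) -> float | None:
    """Pressure (MPa) at which two isotherms of a fitted model intersect.

    Scans ``p_range`` for a sign change of y2(T_low, P) - y2(T_high, P)
    with densities from ``density_surface`` and refines it by bisection to
    well below 0.01 MPa.  Returns None when the isotherms do not cross in
    the range (including the degenerate T_low == T_high case).
    """
    if T_low == T_high:
        return None
    vec = params_to_vector(model_id, params)

    def diff(p):
        y_lo = model_predict(model_id, vec, T_low, p, density_surface(T_low, p),
                             substance, p_star_bar=p_star_bar)
        y_hi = model_predict(model_id, vec, T_high, p, density_surface(T_high, p),
                             substance, p_star_bar=p_star_bar)
        return y_lo - y_hi

    p_grid = np.linspace(p_range[0], p_range[1], n_scan)
    vals = np.array([diff(p) for p in p_grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return None
    i = int(sign_change[0])
    return float(brentq(diff, p_grid[i], p_grid[i + 1], xtol=1e-4))
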