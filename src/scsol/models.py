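"""The six density-based solubility correlation models.

Each model expresses the mole-fraction solubility y2 of a solid in
supercritical CO2 as a function of temperature T (K), pressure P and
solvent density rho1 (kg m^-3) with a small set of empirical constants
fitted per solute:

* ``chrastil`` — solvato-complex model, mole-fraction form; also exposed in
  its native concentration form as ``chrastil_c``
  (c = rho1^kappa * exp(A1 + B1/T)).
* ``reformulated_chrastil`` — dimensionally consistent restatement with an
  explicit reference fugacity (R = 0.082057 atm m^3 kgmol^-1 K^-1, f* = 1 atm).
* ``mst`` — Mendez-Santiago & Teja: T ln(y2 P/bar) = A3 + B3 rho1 + C3 T,
  the classical self-consistency check (all isotherms collapse onto one
  line in the transformed coordinates).
* ``bartle`` — ln(y2 P/Pref) = A4 + B4/T + C4 (rho1 - 700), Pref = 1 bar;
  B4 carries the sublimation enthalpy.
* ``kj`` — Kumar & Johnston: ln y2 = A5 + B5 rho1 + C5/T.
* ``association`` — solvato-complex association model in which one solute
  molecule binds kappa'' solvent molecules: with
  y_AB = (P/P*)^(kappa''-1) exp(A6/T + B6 ln T + C6 rho1 + D6) the
  solubility is y2 = y_AB / (1 + kappa'' y_AB).  The reference pressure P*
  is 1 bar.

Pressure enters the mst/bartle/association equations in bar; the public
interface takes MPa throughout and converts internally.  chrastil,
reformulated_chrastil and kj ignore pressure (density/temperature only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import SITAGLIPTIN, SolubilityDataset, SubstanceInfo, convert_y_to_c

__all__ = [
    "ModelSpec",
    "MODELS",
    "MODEL_IDS",
    "get_model",
    "model_predict",
    "params_to_vector",
    "vector_to_params",
    "consistency_transform",
    "ConsistencyResult",
    "GAS_CONSTANT_ATM",
    "P_STAR_BAR",
    "BARTLE_RHO_REF",
]

GAS_CONSTANT_ATM = 0.082057  # atm m^3 kgmol^-1 K^-1 (reformulated Chrastil)
P_STAR_BAR = 1.0  # association-model reference pressure, bar
BARTLE_RHO_REF = 700.0  # kg m^-3
_MPA_TO_BAR = 10.0


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    parameter_names: tuple[str, ...]
    pressure_needed: bool
    description: str

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


MODELS: dict[str, ModelSpec] = {
    s.model_id: s
    for s in (
        ModelSpec("chrastil", ("kappa", "A1", "B1"), False,
                  "Chrastil solvato-complex model, mole-fraction form"),
        ModelSpec("chrastil_c", ("kappa", "A1", "B1"), False,
                  "Chrastil model, native concentration form (predicts c in kg m^-3)"),
        ModelSpec("reformulated_chrastil", ("kappa", "A2", "B2"), False,
                  "Reformulated (dimensionally consistent) Chrastil model"),
        ModelSpec("mst", ("A3", "B3", "C3"), True,
                  "Mendez-Santiago & Teja model"),
        ModelSpec("bartle", ("A4", "B4", "C4"), True,
                  "Bartle et al. model"),
        ModelSpec("kj", ("A5", "B5", "C5"), False,
                  "Kumar & Johnston model"),
        ModelSpec("association", ("kappa", "A6", "B6", "C6", "D6"), True,
                  "Solvato-complex association model"),
    )
}

#: The six models compared on the y2 scale (chrastil_c predicts c, not y2).
MODEL_IDS = (
    "chrastil",
    "reformulated_chrastil",
    "mst",
    "bartle",
    "kj",
    "association",
)


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {sorted(MODELS)}"
        ) from None


def params_to_vector(model_id: str, params: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Coerce a {name: value} mapping or ordered sequence to the model's order."""
    spec = get_model(model_id)
    if isinstance(params, Mapping):
        missing = [n for n in spec.parameter_names if n not in params]
        if missing:
            raise ValueError(f"{model_id}: missing parameter(s) {missing}")
        return np.array([float(params[n]) for n in spec.parameter_names])
    vec = np.asarray(params, dtype=float)
    if vec.shape != (spec.n_params,):
        raise ValueError(
            f"{model_id} expects {spec.n_params} parameters "
            f"{spec.parameter_names}, got shape {vec.shape}"
        )
    return vec


def vector_to_params(model_id: str, vector: Sequence[float]) -> dict[str, float]:
    spec = get_model(model_id)
    vec = params_to_vector(model_id, vector)
    return dict(zip(spec.parameter_names, (float(v) for v in vec)))


def _chrastil_y(vec, T, rho, m_ratio):
    kappa, A, B = vec
    x = m_ratio * rho ** (kappa - 1.0) * np.exp(A + B / T)
    return x / (1.0 + x)


def model_predict(
    model_id: str,
    params,
    T,
    P,
    density,
    substance: SubstanceInfo = SITAGLIPTIN,
    p_star_bar: float = P_STAR_BAR,
):
    """Predict the solubility at (T/K, P/MPa, rho/kg m^-3).

    Returns the mole fraction y2 for every model except ``chrastil_c``,
    which returns the Chrastil concentration c in kg m^-3.  ``p_star_bar``
    overrides the association-model reference pressure (units audit only).
    """
    vec = params_to_vector(model_id, params)
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho = np.asarray(density, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0) or np.any(rho <= 0):
        raise ValueError("T, P and density must be positive")
    p_bar = P * _MPA_TO_BAR

    if model_id == "chrastil":
        out = _chrastil_y(vec, T, rho, substance.molar_mass_solvent / substance.model_molar_mass)
    elif model_id == "chrastil_c":
        kappa, A, B = vec
        out = rho ** kappa * np.exp(A + B / T)
    elif model_id == "reformulated_chrastil":
        kappa, A, B = vec
        # (R T rho / (M_ScF f*))^(kappa-1) is dimensionless with f* = 1 atm
        out = (GAS_CONSTANT_ATM * T * rho / substance.molar_mass_solvent) ** (kappa - 1.0) * np.exp(A + B / T)
    elif model_id == "mst":
        A, B, C = vec
        out = np.exp((A + B * rho) / T + C) / p_bar
    elif model_id == "bartle":
        A, B, C = vec
        out = np.exp(A + B / T + C * (rho - BARTLE_RHO_REF)) / p_bar
    elif model_id == "kj":
        A, B, C = vec
        out = np.exp(A + B * rho + C / T)
    elif model_id == "association":
        kappa, A, B, C, D = vec
        y_ab = (p_bar / p_star_bar) ** (kappa - 1.0) * np.exp(A / T + B * np.log(T) + C * rho + D)
        out = y_ab / (1.0 + kappa * y_ab)
    else:  # pragma: no cover - get_model already rejects unknown ids
        raise KeyError(model_id)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConsistencyResult:
    """Linearized coordinates plus the least-squares line through them."""

    model_id: str
    abscissa: np.ndarray
    ordinate: np.ndarray
    slope: float
    intercept: float
    r2: float


def consistency_transform(
    model_id: str,
    params,
    dataset: SolubilityDataset,
    p_star_bar: float = P_STAR_BAR,
) -> ConsistencyResult:
    """Self-consistency linearization of a fitted model.

    Maps every record to model-specific coordinates in which the model
    equation is a single straight line for all isotherms; data measured
    consistently should collapse onto that line.  The slope recovers the
    model's density coefficient (kappa for Chrastil-type, B3/C4/B5/C6 for
    mst/bartle/kj/association).
    """
    vec = params_to_vector(model_id, params)
    T = dataset.temperatures
    p_bar = dataset.pressures * _MPA_TO_BAR
    rho = dataset.densities
    y = dataset.mole_fractions
    if np.any(y <= 0):
        raise ValueError("all mole fractions must be positive")

    if model_id in ("chrastil", "chrastil_c"):
        kappa, A, B = vec
        c = convert_y_to_c(
            y, rho, dataset.substance.model_molar_mass, dataset.substance.molar_mass_solvent
        )
        x, z = np.log(rho), np.log(c) - B / T
    elif model_id == "reformulated_chrastil":
        kappa, A, B = vec
        x, z = np.log(rho), np.log(y) - (kappa - 1.0) * np.log(T) - B / T
    elif model_id == "mst":
        A, B, C = vec
        x, z = rho, T * np.log(y * p_bar) - C * T
    elif model_id == "bartle":
        A, B, C = vec
        x, z = rho - BARTLE_RHO_REF, np.log(y * p_bar) - B / T
    elif model_id == "kj":
        A, B, C = vec
        x, z = rho, np.log(y) - C / T
    elif model_id == "association":
        kappa, A, B, C, D = vec
        z = (
            np.log(y / (1.0 - kappa * y))
            - (kappa - 1.0) * np.log(p_bar / p_star_bar)
            - A / T
            - B * np.log(T)
            - D
        )
        x = rho
    else:
        get_model(model_id)  # raises for unknown ids
        raise KeyError(model_id)

    fit = stats.linregress(x, z)
    return ConsistencyResult(
        model_id=model_id,
        abscissa=x,
        ordinate=z,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
    )
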