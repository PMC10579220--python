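"""Domain types, unit conversions and dataset I/O for scCO2 solubility data.

A solubility measurement of a solid in supercritical CO2 is a tuple
(T, P, rho1, y2[, S]): temperature in K, pressure in MPa, solvent (CO2)
density in kg m^-3, equilibrium mole-fraction solubility y2, and optionally
the equilibrium mass solubility S in g L^-1.  Densities are treated as
inputs (typically from a reference equation of state); this package never
computes them.

Two solubility representations besides the mole fraction are used by the
density-based correlation models:

* the Chrastil concentration ``c`` (solute mass per volume of the fluid
  phase, kg m^-3), related to y2 through the mole ratio
  ``r = (c/M2)/(rho1/M1)`` and ``y2 = r/(1+r)``;
* the mass solubility ``S`` (g L^-1), the same relation expressed with the
  molar mass the source publication used for its S column.

All conversions are bijective on y in [0, 1) at fixed density and exact to
machine precision under round-tripping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "ValidationError",
    "FormatError",
    "SolubilityRecord",
    "SubstanceInfo",
    "SolubilityDataset",
    "convert_y_to_S",
    "convert_y_to_c",
    "convert_c_to_y",
    "load_dataset",
    "write_dataset",
    "load_sitagliptin",
    "load_published_params",
    "density_interpolator",
    "SITAGLIPTIN",
    "CO2_MOLAR_MASS",
    "REQUIRED_COLUMNS",
]

CO2_MOLAR_MASS = 44.01  # kg kgmol^-1

REQUIRED_COLUMNS = ("T_K", "P_MPa", "rho_kg_m3", "y_molefrac")
OPTIONAL_COLUMNS = ("S_g_L",)


class ValidationError(ValueError):
    """A record or dataset violates a physical or structural invariant."""


class FormatError(ValueError):
    """An input file does not conform to the expected CSV layout."""


def convert_y_to_c(y, density, molar_mass_solute, molar_mass_solvent=CO2_MOLAR_MASS):
    """Mole-fraction solubility -> Chrastil concentration c (kg m^-3).

    c = (rho1 / M_solvent) * y/(1-y) * M_solute, i.e. moles of solvent per
    volume times the solute/solvent mole ratio times the solute molar mass.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y >= 1):
        raise ValidationError("mole fraction must lie in [0, 1)")
    c = np.asarray(density, dtype=float) / molar_mass_solvent * y / (1.0 - y) * molar_mass_solute
    return c if c.ndim else float(c)


def convert_c_to_y(c, density, molar_mass_solute, molar_mass_solvent=CO2_MOLAR_MASS):
    """Inverse of :func:`convert_y_to_c`: r = (c/M2)/(rho1/M1), y = r/(1+r)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be non-negative")
    r = c / molar_mass_solute * molar_mass_solvent / np.asarray(density, dtype=float)
    y = r / (1.0 + r)
    return y if y.ndim else float(y)


def convert_y_to_S(y, density, molar_mass_solute, molar_mass_solvent=CO2_MOLAR_MASS):
    """Mole-fraction solubility -> mass solubility S (g L^-1).

    Numerically identical to :func:`convert_y_to_c` since kg m^-3 = g L^-1;
    kept as a separate name because S is conventionally reported with the
    molar mass of the solid as charged (for a phosphate salt, the salt mass),
    which may differ from the mass entering the correlation models.
    """
    return convert_y_to_c(y, density, molar_mass_solute, molar_mass_solvent)


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium observation (T/K, P/MPa, rho/kg m^-3, y2, S/g L^-1)."""

    temperature: float
    pressure: float
    density: float
    mole_fraction: float
    mass_solubility: float | None = None

    def __post_init__(self):
        for name in ("temperature", "pressure", "density"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be positive and finite, got {v!r}")
        y = self.mole_fraction
        if not np.isfinite(y) or not (0.0 < y < 1.0):
            raise ValidationError(f"mole_fraction must lie in (0, 1), got {y!r}")
        if self.mass_solubility is not None and (
            not np.isfinite(self.mass_solubility) or self.mass_solubility <= 0
        ):
            raise ValidationError("mass_solubility must be positive if present")


@dataclass(frozen=True)
class SubstanceInfo:
    """Molar masses of the solute/solvent pair.

    ``molar_mass_solute`` is the mass that reproduces the reported mass
    solubility S (for a salt: the full salt mass).  ``molar_mass_solute_reported``
    is the molar mass as listed in the source for the compound, which is the
    one entering the Chrastil mole-fraction form; when absent it defaults to
    ``molar_mass_solute``.  Units: kg kgmol^-1 (= g mol^-1).
    """

    name: str
    molar_mass_solute: float
    molar_mass_solvent: float = CO2_MOLAR_MASS
    molar_mass_solute_reported: float | None = None

    def __post_init__(self):
        for name in ("molar_mass_solute", "molar_mass_solvent"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.molar_mass_solute_reported is not None and self.molar_mass_solute_reported <= 0:
            raise ValidationError("molar_mass_solute_reported must be positive")

    @property
    def model_molar_mass(self) -> float:
        """Solute molar mass used inside the correlation models."""
        if self.molar_mass_solute_reported is not None:
            return self.molar_mass_solute_reported
        return self.molar_mass_solute


#: Sitagliptin phosphate dissolved in CO2. The mass solubility column of the
#: packaged dataset is reproduced by the anhydrous phosphate-salt molar mass
#: (407.31 + 98.00 g/mol); the published compound molar mass 407.31 g/mol is
#: the one used in the correlation models.
SITAGLIPTIN = SubstanceInfo(
    name="sitagliptin phosphate",
    molar_mass_solute=505.31,
    molar_mass_solvent=CO2_MOLAR_MASS,
    molar_mass_solute_reported=407.31,
)


@dataclass(frozen=True)
class SolubilityDataset:
    """A validated, (T, P)-sorted collection of solubility records."""

    records: tuple[SolubilityRecord, ...]
    substance: SubstanceInfo

    def __post_init__(self):
        if not self.records:
            raise ValidationError("no records")
        recs = tuple(
            sorted(self.records, key=lambda r: (r.temperature, r.pressure))
        )
        object.__setattr__(self, "records", recs)
        seen = set()
        for r in recs:
            key = (r.temperature, r.pressure)
            if key in seen:
                raise ValidationError(f"duplicate (temperature, pressure) pair {key}")
            seen.add(key)
        # an S column, when present, must agree with y within 1% relative
        for i, r in enumerate(recs):
            if r.mass_solubility is None:
                continue
            s_calc = convert_y_to_S(
                r.mole_fraction,
                r.density,
                self.substance.molar_mass_solute,
                self.substance.molar_mass_solvent,
            )
            if abs(s_calc - r.mass_solubility) / r.mass_solubility > 0.01:
                raise ValidationError(
                    f"record {i}: mass solubility {r.mass_solubility} inconsistent "
                    f"with mole fraction (expected {s_calc:.4g} g/L)"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([r.temperature for r in self.records])

    @property
    def pressures(self) -> np.ndarray:
        return np.array([r.pressure for r in self.records])

    @property
    def densities(self) -> np.ndarray:
        return np.array([r.density for r in self.records])

    @property
    def mole_fractions(self) -> np.ndarray:
        return np.array([r.mole_fraction for r in self.records])

    @property
    def isotherms(self) -> dict[float, tuple[SolubilityRecord, ...]]:
        """Records grouped by temperature, insertion-ordered by T."""
        groups: dict[float, list[SolubilityRecord]] = {}
        for r in self.records:
            groups.setdefault(r.temperature, []).append(r)
        return {t: tuple(rs) for t, rs in groups.items()}

    def require_fittable(self) -> None:
        """Check preconditions for fitting a model with a temperature term."""
        iso = self.isotherms
        if len(iso) < 2:
            raise ValidationError(
                "at least 2 distinct temperatures are required to fit a model "
                "with a temperature term"
            )
        for t, rs in iso.items():
            if len(rs) < 3:
                raise ValidationError(
                    f"isotherm {t} K has {len(rs)} record(s); at least 3 required"
                )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "T_K": self.temperatures,
                "P_MPa": self.pressures,
                "rho_kg_m3": self.densities,
                "y_molefrac": self.mole_fractions,
            }
        )
        s = [r.mass_solubility for r in self.records]
        if all(v is not None for v in s):
            df["S_g_L"] = s
        return df


def _dataset_from_frame(df: pd.DataFrame, substance: SubstanceInfo) -> SolubilityDataset:
    records = []
    has_s = "S_g_L" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        vals = [row.T_K, row.P_MPa, row.rho_kg_m3, row.y_molefrac]
        if any(not np.isfinite(v) for v in vals):
            raise ValidationError(f"row {i}: non-finite value")
        try:
            records.append(
                SolubilityRecord(
                    temperature=float(row.T_K),
                    pressure=float(row.P_MPa),
                    density=float(row.rho_kg_m3),
                    mole_fraction=float(row.y_molefrac),
                    mass_solubility=float(row.S_g_L) if has_s else None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return SolubilityDataset(records=tuple(records), substance=substance)


def load_dataset(path: str | Path, substance: SubstanceInfo) -> SolubilityDataset:
    """Read a solubility CSV (`T_K,P_MPa,rho_kg_m3,y_molefrac[,S_g_L]`)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise ValidationError("no records")
    for c in REQUIRED_COLUMNS + tuple(c for c in OPTIONAL_COLUMNS if c in df.columns):
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValidationError(f"column {c} is not numeric")
    return _dataset_from_frame(df, substance)


def write_dataset(dataset: SolubilityDataset, path: str | Path) -> None:
    """Write a dataset back to the standard CSV layout."""
    dataset.to_frame().to_csv(path, index=False)


def _fixture_path(name: str):
    return resources.files("scsol.fixtures").joinpath(name)


def load_sitagliptin() -> SolubilityDataset:
    """The packaged 28-point sitagliptin phosphate / scCO2 dataset.

    Four isotherms (308, 318, 328, 338 K) at seven pressures (12-30 MPa),
    with CO2 densities from a reference equation of state.
    """
    with resources.as_file(_fixture_path("sitagliptin_table3.csv")) as p:
        return load_dataset(p, SITAGLIPTIN)


def load_published_params() -> dict:
    """Published fitted parameters (and metrics) per model for regression tests.

    Returns a mapping {model_id: {param_name: value}} plus a ``"metrics"``
    entry holding the published R^2 / R^2_adj / AARD%.
    """
    return json.loads(_fixture_path("table4_params.json").read_text())


def density_interpolator(dataset: SolubilityDataset) -> Callable[[float, float], float]:
    """Build a rho(T, P) surface from a dataset's printed densities.

    Cubic-spline interpolation in pressure along each isotherm, linear
    interpolation across temperature.  Only interpolation is intended;
    extrapolation beyond the tabulated grid is not checked.
    """
    iso = dataset.isotherms
    temps = sorted(iso)
    splines = {}
    for t in temps:
        rs = sorted(iso[t], key=lambda r: r.pressure)
        p = np.array([r.pressure for r in rs])
        d = np.array([r.density for r in rs])
        splines[t] = CubicSpline(p, d)

    def rho(T: float, P: float) -> float:
        if T in splines:
            return float(splines[T](P))
        if T < temps[0] or T > temps[-1]:
            raise ValidationError(f"temperature {T} outside tabulated range")
        hi = next(i for i, t in enumerate(temps) if t >= T)
        t0, t1 = temps[hi - 1], temps[hi]
        w = (T - t0) / (t1 - t0)
        return float((1 - w) * splines[t0](P) + w * splines[t1](P))

    return rho
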