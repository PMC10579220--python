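"""Synthetic solubility datasets with known ground truth.

The generator evaluates one of the correlation models on a (T, P, rho)
grid — by default the 28 experimental conditions of the packaged
sitagliptin dataset — and perturbs the resulting mole fractions with
multiplicative lognormal noise of unit median, mirroring how solubility
measurement uncertainty is stated (relatively, a few percent).  Every
fitting and consistency operation is therefore testable end to end
without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import (
    SITAGLIPTIN,
    SolubilityDataset,
    SolubilityRecord,
    SubstanceInfo,
    convert_y_to_S,
)
from .models import get_model, model_predict, params_to_vector

__all__ = ["SyntheticConfig", "generate_dataset", "default_grid"]


def default_grid() -> tuple[tuple[float, float, float], ...]:
    """The 28 (T/K, P/MPa, rho/kg m^-3) conditions of the packaged dataset."""
    from .data import load_sitagliptin

    ds = load_sitagliptin()
    return tuple(
        (r.temperature, r.pressure, r.density) for r in ds.records
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth model, grid and noise model for a synthetic dataset.

    ``noise_level`` is the relative standard deviation of the multiplicative
    lognormal noise factor exp(sigma * Z), Z ~ N(0, 1), sigma = noise_level;
    the factor has unit median, so the generator is median-unbiased.
    """

    model_id: str
    true_params: dict[str, float]
    grid: tuple[tuple[float, float, float], ...] | None = None
    noise_level: float = 0.0
    seed: int = 0
    substance: SubstanceInfo = SITAGLIPTIN

    def __post_init__(self):
        get_model(self.model_id)
        params_to_vector(self.model_id, self.true_params)
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")


def generate_dataset(config: SyntheticConfig) -> tuple[SolubilityDataset, dict]:
    """Simulate a dataset; returns it with a ground-truth record.

    The ground-truth dict carries the generating model, parameters, noise
    level and seed, suitable for a JSON sidecar next to the CSV.
    """
    grid = config.grid if config.grid is not None else default_grid()
    if len(grid) == 0:
        raise ValueError("grid is empty")
    T = np.array([g[0] for g in grid])
    P = np.array([g[1] for g in grid])
    rho = np.array([g[2] for g in grid])
    y_true = np.asarray(
        model_predict(config.model_id, config.true_params, T, P, rho, config.substance)
    )
    if config.model_id == "chrastil_c":
        raise ValueError("generate mole-fraction data with 'chrastil' instead of 'chrastil_c'")
    rng = np.random.default_rng(config.seed)
    noise = np.exp(config.noise_level * rng.standard_normal(len(grid)))
    y = y_true * noise
    records = tuple(
        SolubilityRecord(
            temperature=float(t),
            pressure=float(p),
            density=float(d),
            mole_fraction=float(yi),
            mass_solubility=float(
                convert_y_to_S(yi, d, config.substance.molar_mass_solute,
                               config.substance.molar_mass_solvent)
            ),
        )
        for t, p, d, yi in zip(T, P, rho, y)
    )
    dataset = SolubilityDataset(records=records, substance=config.substance)
    truth = {
        "model_id": config.model_id,
        "true_params": dict(config.true_params),
        "noise_level": config.noise_level,
        "seed": config.seed,
        "n": len(grid),
    }
    return dataset, truth
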