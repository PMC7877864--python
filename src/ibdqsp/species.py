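"""Species registry for the Crohn's disease immune-network model.

The model tracks 11 cell populations (arbitrary consistent density units),
9 soluble cytokines (pg/mL serum-equivalent), and the two clinical
inflammation markers CRP (mg/L serum) and FCP (mg/kg stool).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CELLS: tuple[str, ...] = (
    "Th0", "Th1", "Th17", "Treg", "NK1",
    "iDC", "eDC", "M0", "M1", "Neu", "Neu_a",
)
CYTOKINES: tuple[str, ...] = (
    "TNFa", "IL6", "IL8", "IL12", "IL17", "IL22", "IL23", "IFNg", "GMCSF",
)
MARKERS: tuple[str, ...] = ("CRP", "FCP")

SPECIES: tuple[str, ...] = CELLS + CYTOKINES + MARKERS
N_SPECIES = len(SPECIES)
IDX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: cytokines that can be neutralised by a therapeutic antibody in this model
TARGETABLE: tuple[str, ...] = ("TNFa", "IL6", "IL12", "IL23")

#: approximate molecular weights (g/mol) of the bioactive circulating forms,
#: used to convert pg/mL cytokine concentrations to nM for binding calculations
CYTOKINE_MW: dict[str, float] = {
    "TNFa": 52_000.0,   # homotrimer
    "IL6": 21_000.0,
    "IL8": 8_400.0,
    "IL12": 70_000.0,   # p35/p40 heterodimer
    "IL17": 35_000.0,   # homodimer
    "IL22": 17_000.0,
    "IL23": 55_000.0,   # p19/p40 heterodimer
    "IFNg": 34_000.0,   # homodimer
    "GMCSF": 14_000.0,
}


class SpeciesState:
    """Concentrations of every model species at one time point.

    Thin wrapper over a float64 vector ordered as :data:`SPECIES`; values
    must be finite and non-negative.
    """

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (N_SPECIES,):
            raise ValueError(
                f"expected {N_SPECIES} species values, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("species state contains non-finite values")
        if np.any(arr < 0):
            raise ValueError("species state contains negative concentrations")
        self.values = arr

    @classmethod
    def from_dict(cls, mapping: dict[str, float]) -> "SpeciesState":
        arr = np.zeros(N_SPECIES)
        for name, value in mapping.items():
            arr[IDX[name]] = value
        return cls(arr)

    def __getitem__(self, name: str) -> float:
        return float(self.values[IDX[name]])

    def __len__(self) -> int:
        return N_SPECIES

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(SPECIES), name="concentration")

    def as_dict(self) -> dict[str, float]:
        return {name: float(self.values[i]) for i, name in enumerate(SPECIES)}

    def __repr__(self) -> str:  # pragma: no cover
        crp, fcp = self["CRP"], self["FCP"]
        return f"SpeciesState(CRP={crp:.3g} mg/L, FCP={fcp:.3g} mg/kg, ...)"


def as_state_array(state) -> np.ndarray:
    """Coerce a SpeciesState / mapping / array to a plain species vector."""
    if isinstance(state, SpeciesState):
        return state.values
    if isinstance(state, dict):
        return SpeciesState.from_dict(state).values
    arr = np.asarray(state, dtype=float)
    if arr.shape != (N_SPECIES,):
        raise ValueError(f"expected {N_SPECIES} species values")
    return arr
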