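"""Mechanistic parameter sets and the nominal (reference-patient) values.

The original training of this network against literature steady-state data is
not reproducible here, so nominal parameters are *designed*: we fix turnover
rates, half-maximum (Km) constants, basal-production fractions and pathway
weights to physiologically sensible values, pick a typical active-disease
steady state (CRP 10 mg/L, FCP 600 mg/kg, cytokines at low-pg/mL levels), and
solve the remaining production/influx constants in closed form so that the
design state is an exact equilibrium of the rate equations. Inter-patient
variability and calibration then move a designated subset of these constants.
"""

from __future__ import annotations

from collections.abc import Mapping
from typing import Iterator

from .species import SPECIES

__all__ = [
    "ParameterSet",
    "nominal_parameters",
    "design_state",
    "VARIABILITY_SUBSET",
]

#: parameters sampled per-patient when generating virtual populations:
#: TNF turnover and TNF->IL6 coupling, marker production gains, cytokine
#: production rates, and innate/adaptive activation rates. The hepatic CRP
#: response curve (Km, floor, half-life) is kept common across patients —
#: inter-subject variability lives in the inflammatory drive upstream.
VARIABILITY_SUBSET: tuple[str, ...] = (
    "kdeg_TNF",
    "Km_TNF_IL6",
    "p_CRP",
    "p_FCP",
    "p_IL6",
    "p_IL8",
    "p_TNF",
    "s_Neu",
    "k_aN",
    "k_aDC",
    "p_IL17",
    "k_Th17",
    "k_Th1",
    "p_IL12",
    "p_IL23",
)

# prefix -> validation class
_STRICT_POS_PREFIXES = ("Km_", "kdeg_", "kd_")
_NONNEG_PREFIXES = ("s_", "b_", "p_", "k_", "alpha_", "w_")


class ParameterSet(Mapping):
    """Immutable mapping of named rate constants with domain validation.

    Rate constants are per day; Km values share units with the modifier
    species they gate; ``hill_n`` is the (global) Hill coefficient applied
    to every saturating modifier arrow and must lie in [1, 4].
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        vals = {k: float(v) for k, v in values.items()}
        self._validate(vals)
        self._values = vals

    @staticmethod
    def _validate(vals: dict[str, float]) -> None:
        for name, v in vals.items():
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"parameter {name} is not finite")
            if name == "hill_n":
                if not 1.0 <= v <= 4.0:
                    raise ValueError(f"hill_n must be in [1, 4], got {v}")
            elif name.startswith(_STRICT_POS_PREFIXES):
                if v <= 0:
                    raise ValueError(f"parameter {name} must be > 0, got {v}")
            elif name.startswith(_NONNEG_PREFIXES):
                if v < 0:
                    raise ValueError(f"parameter {name} must be >= 0, got {v}")
            else:
                raise ValueError(f"unknown parameter name: {name}")

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    def __hash__(self):  # pragma: no cover - identity-ish hashing
        return hash(tuple(sorted(self._values.items())))

    # convenience ----------------------------------------------------------
    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def updated(self, **changes: float) -> "ParameterSet":
        vals = dict(self._values)
        for k, v in changes.items():
            if k not in vals:
                raise KeyError(f"unknown parameter: {k}")
            vals[k] = v
        return ParameterSet(vals)

    def perturbed(self, factors: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with ``factors`` applied multiplicatively."""
        vals = dict(self._values)
        for k, f in factors.items():
            if k not in vals:
                raise KeyError(f"unknown parameter: {k}")
            vals[k] = vals[k] * f
        return ParameterSet(vals)


def design_state() -> dict[str, float]:
    """The typical active-Crohn's steady state the nominal model is solved for.

    Cell densities are in an arbitrary consistent tissue unit; cytokines in
    pg/mL; CRP in mg/L; FCP in mg/kg stool.
    """
    return {
        "Th0": 100.0, "Th1": 20.0, "Th17": 15.0, "Treg": 10.0, "NK1": 5.0,
        "iDC": 50.0, "eDC": 25.0, "M0": 50.0, "M1": 25.0,
        "Neu": 100.0, "Neu_a": 50.0,
        "TNFa": 15.0, "IL6": 8.0, "IL8": 30.0, "IL12": 2.0, "IL17": 6.0,
        "IL22": 20.0, "IL23": 4.0, "IFNg": 10.0, "GMCSF": 3.0,
        "CRP": 10.0, "FCP": 600.0,
    }


def _H(x: float, km: float) -> float:
    return x / (km + x)


def nominal_parameters(**design_overrides: float) -> ParameterSet:
    """Solve the nominal parameter set so ``design_state`` is an equilibrium.

    Fixed design constants (turnovers, Kms, basal fractions, weights) are set
    here; influx and production gains follow algebraically from the design
    state, so overriding a design constant (keyword arguments) re-solves the
    production side and the design state remains an exact equilibrium. See
    docs/methods.md for the rationale behind each choice.
    """
    st = design_state()

    p: dict[str, float] = {
        "hill_n": 1.0,
        # --- cell turnover (1/day) ---
        "kd_Th0": 0.1, "kd_Th1": 0.3, "kd_Th17": 0.3, "kd_Treg": 0.2,
        "kd_NK": 0.3, "kd_iDC": 1.0, "kd_eDC": 0.5, "kd_M0": 1.0,
        "kd_M1": 0.5, "kd_Neu": 1.0, "kd_Neu_a": 0.5,
        # --- soluble-species turnover (1/day) ---
        "kdeg_TNF": 5.0, "kdeg_IL6": 4.0, "kdeg_IL8": 4.0, "kdeg_IL12": 2.0,
        "kdeg_IL17": 2.0, "kdeg_IL22": 2.0, "kdeg_IL23": 2.0,
        "kdeg_IFN": 2.0, "kdeg_GMCSF": 2.0,
        "kdeg_CRP": 0.9,   # serum CRP half-life ~19 h
        "kdeg_FCP": 0.5,   # stool marker washout
        # --- half-maximum constants (units of the modifier) ---
        "Km_IL12_Th1": 2.0, "Km_IL23_Th17": 4.0, "Km_IL6_Th17": 8.0,
        "Km_Treg": 10.0, "Km_IL12_NK": 2.0,
        "Km_TNF_DC": 15.0, "Km_IL6_DC": 8.0,
        "Km_TNF_M": 15.0, "Km_IFN_M": 10.0,
        "Km_TNF_Neu": 15.0, "Km_IL17_Neu": 6.0,
        "Km_TNF_IL6": 15.0, "Km_IL6_CRP": 8.0,
        "Km_Neu_FCP": 1000.0, "Km_IL8_FCP": 600.0,
        # --- secondary-pathway weights (dimensionless) ---
        "alpha_IL6_Th17": 0.5, "alpha_IL6_DC": 0.3,
        "alpha_IFN_M": 0.7, "alpha_IL17_Neu": 0.7,
        "w_IL8_FCP": 1.0, "w_Neu_cyt": 0.5,
        # --- cytokine-independent activation floors (dimensionless) ---
        "b_DC": 0.05, "b_M": 0.05, "b_Neu": 0.05, "b_NK": 0.3,
        "b_IL6_TNF": 0.08,
    }
    for name, value in design_overrides.items():
        if name not in p:
            raise KeyError(f"unknown design constant {name!r}")
        p[name] = float(value)

    def H(mod: str, km_name: str) -> float:
        return _H(st[mod], p[km_name])

    i_treg = p["Km_Treg"] / (p["Km_Treg"] + st["Treg"])

    # --- T helper differentiation ---
    # the naive pool is homeostatic: differentiation reads Th0 but does not
    # deplete it, so blocking one branch cannot boost the other
    r_th1 = st["Th1"] * p["kd_Th1"] / st["Th0"]
    p["k_Th1"] = r_th1 / (H("IL12", "Km_IL12_Th1") * i_treg)
    th17_drive = H("IL23", "Km_IL23_Th17") + p["alpha_IL6_Th17"] * H("IL6", "Km_IL6_Th17")
    r_th17 = st["Th17"] * p["kd_Th17"] / st["Th0"]
    p["k_Th17"] = r_th17 / (th17_drive * i_treg)
    p["s_Th0"] = st["Th0"] * p["kd_Th0"]
    p["s_Treg"] = st["Treg"] * p["kd_Treg"]
    p["s_NK"] = st["NK1"] * p["kd_NK"] / (p["b_NK"] + H("IL12", "Km_IL12_NK"))

    # --- innate activation cascades (pool -> activated form) ---
    a_dc = p["b_DC"] + H("TNFa", "Km_TNF_DC") + p["alpha_IL6_DC"] * H("IL6", "Km_IL6_DC")
    p["k_aDC"] = st["eDC"] * p["kd_eDC"] / (st["iDC"] * a_dc)
    p["s_iDC"] = st["iDC"] * (p["kd_iDC"] + p["k_aDC"] * a_dc)
    a_m = p["b_M"] + H("TNFa", "Km_TNF_M") + p["alpha_IFN_M"] * H("IFNg", "Km_IFN_M")
    p["k_aM"] = st["M1"] * p["kd_M1"] / (st["M0"] * a_m)
    p["s_M0"] = st["M0"] * (p["kd_M0"] + p["k_aM"] * a_m)
    a_n = p["b_Neu"] + H("TNFa", "Km_TNF_Neu") + p["alpha_IL17_Neu"] * H("IL17", "Km_IL17_Neu")
    p["k_aN"] = st["Neu_a"] * p["kd_Neu_a"] / (st["Neu"] * a_n)
    p["s_Neu"] = st["Neu"] * (p["kd_Neu"] + p["k_aN"] * a_n)

    # --- cytokine production (gain solved from steady state) ---
    w_myeloid = st["eDC"] + st["M1"] + p["w_Neu_cyt"] * st["Neu_a"]
    w_apc = st["eDC"] + st["M1"]

    def solve_gain(species: str, kdeg: str, basal_frac: float, driver: float,
                   gain: str, basal: str) -> None:
        total = st[species] * p[kdeg]
        p[basal] = basal_frac * total
        p[gain] = (total - p[basal]) / driver

    solve_gain("TNFa", "kdeg_TNF", 0.05, w_myeloid, "p_TNF", "b_TNF")
    il6_mod = p["b_IL6_TNF"] + H("TNFa", "Km_TNF_IL6")
    solve_gain("IL6", "kdeg_IL6", 0.03, w_myeloid * il6_mod, "p_IL6", "b_IL6")
    solve_gain("IL8", "kdeg_IL8", 0.03, w_myeloid, "p_IL8", "b_IL8")
    solve_gain("IL12", "kdeg_IL12", 0.05, w_apc, "p_IL12", "b_IL12")
    solve_gain("IL23", "kdeg_IL23", 0.05, w_apc, "p_IL23", "b_IL23")
    # IL-17 keeps a visible IL-23-independent source (basal fraction 25%)
    solve_gain("IL17", "kdeg_IL17", 0.25, st["Th17"], "p_IL17", "b_IL17")
    solve_gain("IL22", "kdeg_IL22", 0.05, st["Th17"], "p_IL22", "b_IL22")
    solve_gain("GMCSF", "kdeg_GMCSF", 0.05, w_myeloid, "p_GMCSF", "b_GMCSF")

    # IFNg: produced by Th1 (70% of flux) and NK1 (30%)
    ifn_total = st["IFNg"] * p["kdeg_IFN"]
    p["b_IFN"] = 0.05 * ifn_total
    p["p_IFN_Th1"] = 0.70 * (ifn_total - p["b_IFN"]) / st["Th1"]
    p["p_IFN_NK"] = 0.30 * (ifn_total - p["b_IFN"]) / st["NK1"]

    # --- clinical markers ---
    solve_gain("CRP", "kdeg_CRP", 0.05, H("IL6", "Km_IL6_CRP"), "p_CRP", "b_CRP")
    fcp_drive = _H(st["Neu_a"], p["Km_Neu_FCP"]) + p["w_IL8_FCP"] * _H(st["IL8"], p["Km_IL8_FCP"])
    solve_gain("FCP", "kdeg_FCP", 0.03, fcp_drive, "p_FCP", "b_FCP")

    ps = ParameterSet(p)
    missing = [name for name in VARIABILITY_SUBSET if name not in ps]
    if missing:  # defensive: keep the variability axes in sync with the set
        raise RuntimeError(f"variability parameters missing: {missing}")
    return ps


def design_state_vector():
    import numpy as np

    st = design_state()
    return np.array([st[name] for name in SPECIES])
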