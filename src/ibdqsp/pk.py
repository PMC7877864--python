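"""Closed-form two-compartment antibody pharmacokinetics.

Serum concentrations follow linear two-compartment kinetics: biexponential
decline after an IV bolus, and an additional first-order absorption phase
for subcutaneous dosing. Multiple doses superpose. All subjects in a trial
arm share one concentration-time profile — inter-subject variability in this
framework is purely pharmacodynamic (system parameters), never PK.

Per-drug PK parameters are repository defaults chosen in the range typical
for therapeutic IgG monoclonal antibodies (CL ~0.2-0.4 L/day, V1 ~3-4 L);
they can be overridden from configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PKParameters",
    "DoseEvent",
    "Regimen",
    "resolve_doses",
    "concentration",
    "to_molar",
    "from_molar",
    "ConcentrationProfile",
    "default_pk_parameters",
    "load_regimen_csv",
]

DEFAULT_BODY_WEIGHT_KG = 70.0


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment PK constants for one drug.

    CL (L/day) clearance; V1/V2 (L) central/peripheral volumes; Q (L/day)
    inter-compartment flow; ka (1/day) and F only apply to SC dosing;
    molecular_weight in g/mol.
    """

    CL: float
    V1: float
    V2: float
    Q: float
    ka: float = 0.25
    F: float = 0.7
    molecular_weight: float = 150_000.0

    def __post_init__(self):
        for name in ("CL", "V1", "V2", "Q", "ka", "molecular_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PK parameter {name} must be positive")
        if not 0 < self.F <= 1:
            raise ValueError("bioavailability F must be in (0, 1]")

    @property
    def micro_constants(self) -> tuple[float, float, float]:
        """(k10, k12, k21) elimination and distribution micro-rates, 1/day."""
        return self.CL / self.V1, self.Q / self.V1, self.Q / self.V2

    @property
    def hybrid_constants(self) -> tuple[float, float]:
        """(alpha, beta) biexponential disposition rates, alpha > beta."""
        k10, k12, k21 = self.micro_constants
        s = k10 + k12 + k21
        disc = math.sqrt(s * s - 4.0 * k10 * k21)
        return (s + disc) / 2.0, (s - disc) / 2.0


@dataclass(frozen=True)
class DoseEvent:
    """One administration: time in days, amount in mg or mg/kg, route iv|sc."""

    time: float
    amount: float | None = None
    amount_per_kg: float | None = None
    route: str = "iv"

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if (self.amount is None) == (self.amount_per_kg is None):
            raise ValueError("exactly one of amount / amount_per_kg must be set")
        value = self.amount if self.amount is not None else self.amount_per_kg
        if value <= 0:
            raise ValueError("dose amount must be positive")
        if self.route not in ("iv", "sc"):
            raise ValueError(f"unknown route: {self.route}")


@dataclass(frozen=True)
class Regimen:
    """A drug's timed dose events for one arm, with the standard body weight."""

    drug: str
    events: tuple[DoseEvent, ...] = ()
    body_weight: float = DEFAULT_BODY_WEIGHT_KG

    def __post_init__(self):
        times = [e.time for e in self.events]
        if times != sorted(times):
            object.__setattr__(self, "events",
                               tuple(sorted(self.events, key=lambda e: e.time)))

    def dose_times(self) -> tuple[float, ...]:
        return tuple(e.time for e in self.events)

    @property
    def is_empty(self) -> bool:
        return len(self.events) == 0


def resolve_doses(regimen: Regimen) -> Regimen:
    """Convert all weight-based doses to absolute mg using the body weight."""
    if regimen.body_weight <= 0:
        raise ValueError("body weight must be positive")
    events = tuple(
        e if e.amount is not None
        else replace(e, amount=e.amount_per_kg * regimen.body_weight,
                     amount_per_kg=None)
        for e in regimen.events
    )
    return replace(regimen, events=events)


def _iv_unit(t, params: PKParameters):
    """Central concentration per mg after an IV bolus at t=0 (mg/L/mg)."""
    _, _, k21 = params.micro_constants
    alpha, beta = params.hybrid_constants
    A = (alpha - k21) / (alpha - beta) / params.V1
    B = (k21 - beta) / (alpha - beta) / params.V1
    return A * np.exp(-alpha * t) + B * np.exp(-beta * t)


def _sc_unit(t, params: PKParameters):
    """Central concentration per mg after an SC dose at t=0 (mg/L/mg)."""
    _, _, k21 = params.micro_constants
    alpha, beta = params.hybrid_constants
    ka = params.ka
    pref = params.F * ka / params.V1
    A = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    B = (k21 - beta) / ((ka - beta) * (alpha - beta))
    C = (k21 - ka) / ((alpha - ka) * (beta - ka))
    return pref * (A * np.exp(-alpha * t) + B * np.exp(-beta * t)
                   + C * np.exp(-ka * t))


def concentration(params: PKParameters, regimen: Regimen, t):
    """Serum drug concentration (mg/L) at time(s) ``t`` (days).

    Superposes the closed-form single-dose solutions of every dose event with
    event time <= t. Doses must be resolved to absolute mg first.
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros_like(t_arr, dtype=float)
    for e in regimen.events:
        if e.amount is None:
            raise ValueError("regimen has unresolved mg/kg doses; "
                             "call resolve_doses first")
        dt = t_arr - e.time
        active = dt >= 0
        if not np.any(active):
            continue
        unit = _iv_unit(dt, params) if e.route == "iv" else _sc_unit(dt, params)
        out = out + np.where(active, e.amount * unit, 0.0)
    out = np.maximum(out, 0.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def to_molar(conc_mg_per_L: float, params: PKParameters):
    """Convert a serum concentration in mg/L to nM."""
    if params.molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    return np.asarray(conc_mg_per_L, dtype=float) / params.molecular_weight * 1e6


def from_molar(conc_nM: float, params: PKParameters):
    """Convert nM back to mg/L (inverse of :func:`to_molar`)."""
    return np.asarray(conc_nM, dtype=float) * params.molecular_weight / 1e6


class ConcentrationProfile:
    """Callable ``t -> mg/L`` for one resolved regimen (shared by an arm).

    Precomputes the exponential coefficients of every dose event so that
    scalar evaluation (one call per ODE right-hand-side evaluation) costs a
    few microseconds.
    """

    def __init__(self, params: PKParameters, regimen: Regimen):
        self.params = params
        self.regimen = resolve_doses(regimen)
        _, _, k21 = params.micro_constants
        alpha, beta = params.hybrid_constants
        terms: list[tuple[float, tuple[tuple[float, float], ...]]] = []
        for e in self.regimen.events:
            if e.route == "iv":
                A = e.amount * (alpha - k21) / (alpha - beta) / params.V1
                B = e.amount * (k21 - beta) / (alpha - beta) / params.V1
                terms.append((e.time, ((A, alpha), (B, beta))))
            else:
                ka = params.ka
                pref = e.amount * params.F * ka / params.V1
                A = pref * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
                B = pref * (k21 - beta) / ((ka - beta) * (alpha - beta))
                C = pref * (k21 - ka) / ((alpha - ka) * (beta - ka))
                terms.append((e.time, ((A, alpha), (B, beta), (C, ka))))
        self._terms = tuple(terms)
        self._to_nm = 1e6 / params.molecular_weight

    def __call__(self, t):
        if isinstance(t, (int, float)):
            total = 0.0
            for t_dose, coeffs in self._terms:
                dt = t - t_dose
                if dt < 0.0:
                    continue
                for coef, rate in coeffs:
                    total += coef * math.exp(-rate * dt)
            return total if total > 0.0 else 0.0
        return concentration(self.params, self.regimen, t)

    def molar(self, t):
        if isinstance(t, (int, float)):
            return self(t) * self._to_nm
        return to_molar(self(t), self.params)


def default_pk_parameters() -> dict[str, PKParameters]:
    """Repository-default PK constants per drug (literature-typical IgG mAb).

    These stand in for the cited-but-unprinted published values and are meant
    to be overridden from configuration when better estimates are available.
    """
    return {
        "infliximab": PKParameters(CL=0.30, V1=3.5, V2=3.0, Q=0.6,
                                   molecular_weight=149_000.0),
        "ustekinumab": PKParameters(CL=0.25, V1=3.0, V2=2.5, Q=0.4,
                                    molecular_weight=146_000.0),
        "brazikumab": PKParameters(CL=0.30, V1=3.5, V2=3.0, Q=0.5,
                                   ka=0.25, F=0.7,
                                   molecular_weight=147_000.0),
        "risankizumab": PKParameters(CL=0.30, V1=3.5, V2=3.0, Q=0.5,
                                     molecular_weight=149_000.0),
        "PF-04236921": PKParameters(CL=0.25, V1=3.5, V2=3.0, Q=0.5,
                                    ka=0.25, F=0.7,
                                    molecular_weight=150_000.0),
    }


def load_regimen_csv(path, body_weight: float = DEFAULT_BODY_WEIGHT_KG,
                     ) -> dict[str, Regimen]:
    """Read regimens from CSV (columns: drug, time_days, amount, unit, route)."""
    df = pd.read_csv(path)
    required = {"drug", "time_days", "amount", "unit", "route"}
    if not required.issubset(df.columns):
        raise ValueError(f"regimen CSV needs columns {sorted(required)}")
    regimens: dict[str, Regimen] = {}
    for drug, sub in df.groupby("drug", sort=False):
        events = []
        for _, row in sub.iterrows():
            if row["unit"] == "mg":
                events.append(DoseEvent(time=row["time_days"],
                                        amount=row["amount"],
                                        route=row["route"]))
            elif row["unit"] == "mg/kg":
                events.append(DoseEvent(time=row["time_days"],
                                        amount_per_kg=row["amount"],
                                        route=row["route"]))
            else:
                raise ValueError(f"unknown dose unit {row['unit']!r}")
        regimens[str(drug)] = Regimen(drug=str(drug), events=tuple(events),
                                      body_weight=body_weight)
    return regimens
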