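"""Declarative definition of the Crohn's disease immune-network reactions.

The network couples antigen-presenting cell, macrophage and neutrophil
activation (driven by TNFα, with IFNγ and IL-17 side inputs), T-helper
differentiation (driven by IL-12, IL-23 and IL-6, restrained by Treg), the
cytokines those cells secrete, and the two clinical readouts: CRP produced
under IL-6 drive and FCP produced by activated neutrophils and IL-8.

The module serves three purposes:

* :func:`build_network` is the single source of truth for the wiring —
  reactions, modifier arrows, and which parameter gates each arrow;
* :func:`evaluate_network` is a direct, interpretive evaluation of those
  rate laws, used as an independent cross-check of the optimised
  right-hand side in :mod:`ibdqsp.dynamics`;
* :meth:`NetworkDefinition.to_table` exports a human-readable reaction
  table (CSV) for review.

Rate-law expressions are small nested tuples:
``("param", name)``, ``("species", name)``, ``("const", x)``,
``("hill", species, km_param)`` (activating, Hill exponent ``hill_n``),
``("inh", species, km_param)`` (inhibitory), ``("sum", exprs)``,
``("prod", exprs)``. Wherever a drug-targetable cytokine appears inside a
``hill`` term, its concentration is multiplied by the supplied free
fraction — drug effect enters the model only through those arrows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet
from .species import IDX, N_SPECIES, SPECIES, TARGETABLE

__all__ = ["Reaction", "NetworkDefinition", "build_network", "evaluate_network"]


def _P(name):
    return ("param", name)


def _S(name):
    return ("species", name)


def _HILL(species, km):
    return ("hill", species, km)


def _INH(species, km):
    return ("inh", species, km)


def _SUM(*exprs):
    return ("sum", exprs)


def _PROD(*exprs):
    return ("prod", exprs)


@dataclass(frozen=True)
class Reaction:
    rid: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    modifiers: tuple[str, ...]
    kind: str  # constant | linear | saturating | hill-activated | hill-inhibited
    rate: tuple

    def parameters(self) -> tuple[str, ...]:
        """Names of every parameter referenced by this reaction's rate law."""
        found: list[str] = []

        def walk(expr):
            tag = expr[0]
            if tag == "param":
                found.append(expr[1])
            elif tag in ("hill", "inh"):
                found.append(expr[2])
            elif tag in ("sum", "prod"):
                for sub in expr[1]:
                    walk(sub)

        walk(self.rate)
        return tuple(dict.fromkeys(found))


@dataclass
class NetworkDefinition:
    species: tuple[str, ...]
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.rid for r in self.reactions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate reaction ids")

    def find(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.rid == rid:
                return r
        raise KeyError(rid)

    def modifier_edges(self) -> set[tuple[str, str]]:
        """Set of (modifier species, reaction id) pairs."""
        return {(m, r.rid) for r in self.reactions for m in r.modifiers}

    def validate(self, params: ParameterSet) -> None:
        """Check every parameter reference resolves and species names exist."""
        for r in self.reactions:
            for name in r.reactants + r.products + r.modifiers:
                if name not in IDX:
                    raise ValueError(f"{r.rid}: unknown species {name}")
            for pname in r.parameters():
                if pname not in params:
                    raise ValueError(f"{r.rid}: unresolved parameter {pname}")

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "reaction": r.rid,
                "reactants": "+".join(r.reactants) or "-",
                "products": "+".join(r.products) or "-",
                "modifiers": "+".join(r.modifiers) or "-",
                "rate_law": r.kind,
                "parameters": ";".join(r.parameters()),
            }
            for r in self.reactions
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_table().to_csv(path, index=False)


def _turnover(sp: str, kd: str) -> Reaction:
    return Reaction(f"{sp}_turnover", (sp,), (), (), "linear", _PROD(_P(kd), _S(sp)))


def _influx(sp: str, s: str) -> Reaction:
    return Reaction(f"{sp}_influx", (), (sp,), (), "constant", _P(s))


_MYELOID_SUM = _SUM(_S("eDC"), _S("M1"), _PROD(_P("w_Neu_cyt"), _S("Neu_a")))
_APC_SUM = _SUM(_S("eDC"), _S("M1"))


def build_network() -> NetworkDefinition:
    """Construct the full Crohn's disease network definition."""
    rxns: list[Reaction] = []

    # ----- T cell compartment -----
    rxns += [_influx("Th0", "s_Th0"), _turnover("Th0", "kd_Th0")]
    # differentiation reads the (homeostatic) naive pool without consuming it
    rxns.append(Reaction(
        "Th1_differentiation", (), ("Th1",), ("Th0", "IL12", "Treg"),
        "hill-activated",
        _PROD(_P("k_Th1"), _S("Th0"),
              _HILL("IL12", "Km_IL12_Th1"), _INH("Treg", "Km_Treg")),
    ))
    rxns.append(_turnover("Th1", "kd_Th1"))
    rxns.append(Reaction(
        "Th17_differentiation", (), ("Th17",), ("Th0", "IL23", "IL6", "Treg"),
        "hill-activated",
        _PROD(_P("k_Th17"), _S("Th0"),
              _SUM(_HILL("IL23", "Km_IL23_Th17"),
                   _PROD(_P("alpha_IL6_Th17"), _HILL("IL6", "Km_IL6_Th17"))),
              _INH("Treg", "Km_Treg")),
    ))
    rxns.append(_turnover("Th17", "kd_Th17"))
    rxns += [_influx("Treg", "s_Treg"), _turnover("Treg", "kd_Treg")]
    rxns.append(Reaction(
        "NK1_production", (), ("NK1",), ("IL12",), "hill-activated",
        _PROD(_P("s_NK"), _SUM(_P("b_NK"), _HILL("IL12", "Km_IL12_NK"))),
    ))
    rxns.append(_turnover("NK1", "kd_NK"))

    # ----- innate activation cascades -----
    rxns += [_influx("iDC", "s_iDC"), _turnover("iDC", "kd_iDC")]
    rxns.append(Reaction(
        "DC_activation", ("iDC",), ("eDC",), ("TNFa", "IL6"), "hill-activated",
        _PROD(_P("k_aDC"), _S("iDC"),
              _SUM(_P("b_DC"), _HILL("TNFa", "Km_TNF_DC"),
                   _PROD(_P("alpha_IL6_DC"), _HILL("IL6", "Km_IL6_DC")))),
    ))
    rxns.append(_turnover("eDC", "kd_eDC"))
    rxns += [_influx("M0", "s_M0"), _turnover("M0", "kd_M0")]
    rxns.append(Reaction(
        "M_activation", ("M0",), ("M1",), ("TNFa", "IFNg"), "hill-activated",
        _PROD(_P("k_aM"), _S("M0"),
              _SUM(_P("b_M"), _HILL("TNFa", "Km_TNF_M"),
                   _PROD(_P("alpha_IFN_M"), _HILL("IFNg", "Km_IFN_M")))),
    ))
    rxns.append(_turnover("M1", "kd_M1"))
    rxns += [_influx("Neu", "s_Neu"), _turnover("Neu", "kd_Neu")]
    rxns.append(Reaction(
        "Neu_activation", ("Neu",), ("Neu_a",), ("TNFa", "IL17"), "hill-activated",
        _PROD(_P("k_aN"), _S("Neu"),
              _SUM(_P("b_Neu"), _HILL("TNFa", "Km_TNF_Neu"),
                   _PROD(_P("alpha_IL17_Neu"), _HILL("IL17", "Km_IL17_Neu")))),
    ))
    rxns.append(_turnover("Neu_a", "kd_Neu_a"))

    # ----- cytokines -----
    def cytokine(sp, gain, basal, kdeg, driver, modifiers, kind="saturating",
                 extra=None):
        rate = _PROD(_P(gain), driver) if extra is None else \
            _PROD(_P(gain), driver, extra)
        rxns.append(Reaction(f"{sp}_production", (), (sp,), modifiers, kind, rate))
        rxns.append(Reaction(f"{sp}_basal", (), (sp,), (), "constant", _P(basal)))
        rxns.append(_turnover(sp, kdeg))

    cytokine("TNFa", "p_TNF", "b_TNF", "kdeg_TNF",
             _MYELOID_SUM, ("eDC", "M1", "Neu_a"), "linear")
    cytokine("IL6", "p_IL6", "b_IL6", "kdeg_IL6",
             _MYELOID_SUM, ("eDC", "M1", "Neu_a", "TNFa"), "hill-activated",
             extra=_SUM(_P("b_IL6_TNF"), _HILL("TNFa", "Km_TNF_IL6")))
    cytokine("IL8", "p_IL8", "b_IL8", "kdeg_IL8",
             _MYELOID_SUM, ("eDC", "M1", "Neu_a"), "linear")
    cytokine("IL12", "p_IL12", "b_IL12", "kdeg_IL12",
             _APC_SUM, ("eDC", "M1"), "linear")
    cytokine("IL23", "p_IL23", "b_IL23", "kdeg_IL23",
             _APC_SUM, ("eDC", "M1"), "linear")
    # IL17_basal is the IL-23-independent alternative IL-17 source
    cytokine("IL17", "p_IL17", "b_IL17", "kdeg_IL17",
             _S("Th17"), ("Th17",), "linear")
    cytokine("IL22", "p_IL22", "b_IL22", "kdeg_IL22",
             _S("Th17"), ("Th17",), "linear")
    rxns.append(Reaction(
        "IFNg_production_Th1", (), ("IFNg",), ("Th1",), "linear",
        _PROD(_P("p_IFN_Th1"), _S("Th1")),
    ))
    rxns.append(Reaction(
        "IFNg_production_NK", (), ("IFNg",), ("NK1",), "linear",
        _PROD(_P("p_IFN_NK"), _S("NK1")),
    ))
    rxns.append(Reaction("IFNg_basal", (), ("IFNg",), (), "constant", _P("b_IFN")))
    rxns.append(_turnover("IFNg", "kdeg_IFN"))
    cytokine("GMCSF", "p_GMCSF", "b_GMCSF", "kdeg_GMCSF",
             _MYELOID_SUM, ("eDC", "M1", "Neu_a"), "linear")

    # ----- clinical markers -----
    rxns.append(Reaction(
        "CRP_production", (), ("CRP",), ("IL6",), "hill-activated",
        _PROD(_P("p_CRP"), _HILL("IL6", "Km_IL6_CRP")),
    ))
    rxns.append(Reaction("CRP_basal", (), ("CRP",), (), "constant", _P("b_CRP")))
    rxns.append(_turnover("CRP", "kdeg_CRP"))
    rxns.append(Reaction(
        "FCP_production", (), ("FCP",), ("Neu_a", "IL8"), "hill-activated",
        _PROD(_P("p_FCP"),
              _SUM(_HILL("Neu_a", "Km_Neu_FCP"),
                   _PROD(_P("w_IL8_FCP"), _HILL("IL8", "Km_IL8_FCP")))),
    ))
    rxns.append(Reaction("FCP_basal", (), ("FCP",), (), "constant", _P("b_FCP")))
    rxns.append(_turnover("FCP", "kdeg_FCP"))

    return NetworkDefinition(species=SPECIES, reactions=rxns)


def _eval_expr(expr, y, params, free, hill_n) -> float:
    tag = expr[0]
    if tag == "param":
        return params[expr[1]]
    if tag == "species":
        return max(y[IDX[expr[1]]], 0.0)
    if tag == "const":
        return expr[1]
    if tag == "hill":
        sp, km_name = expr[1], expr[2]
        x = max(y[IDX[sp]], 0.0) * free.get(sp, 1.0)
        km = params[km_name]
        if x <= 0.0:
            return 0.0
        if hill_n == 1.0:
            return x / (km + x)
        xn = x ** hill_n
        return xn / (km ** hill_n + xn)
    if tag == "inh":
        sp, km_name = expr[1], expr[2]
        x = max(y[IDX[sp]], 0.0) * free.get(sp, 1.0)
        km = params[km_name]
        if hill_n == 1.0:
            return km / (km + x)
        kmn = km ** hill_n
        return kmn / (kmn + x ** hill_n)
    if tag == "sum":
        return sum(_eval_expr(sub, y, params, free, hill_n) for sub in expr[1])
    if tag == "prod":
        out = 1.0
        for sub in expr[1]:
            out *= _eval_expr(sub, y, params, free, hill_n)
        return out
    raise ValueError(f"unknown expression tag {tag}")  # pragma: no cover


def evaluate_network(network: NetworkDefinition, state, params: ParameterSet,
                     free_fraction: dict[str, float] | None = None) -> np.ndarray:
    """Interpretively evaluate d(state)/dt from the declarative reaction list.

    Slow but transparent; exists as the independent oracle against which the
    hand-written right-hand side in :mod:`ibdqsp.dynamics` is verified.
    """
    y = np.asarray(state, dtype=float)
    free = dict.fromkeys(TARGETABLE, 1.0)
    if free_fraction:
        free.update(free_fraction)
    hill_n = params["hill_n"]
    dydt = np.zeros(N_SPECIES)
    for r in network.reactions:
        rate = _eval_expr(r.rate, y, params, free, hill_n)
        for sp in r.reactants:
            dydt[IDX[sp]] -= rate
        for sp in r.products:
            dydt[IDX[sp]] += rate
    return dydt
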