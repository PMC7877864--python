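"""Drug mechanisms: antibody-cytokine binding at quasi-equilibrium.

Each therapeutic antibody neutralises one or two soluble cytokines. Binding
is treated as an instantaneous equilibrium between the circulating drug's
binding sites and the total cytokine pool, which is justified because
antibody-antigen association equilibrates within minutes while dosing and
disease dynamics play out over days to weeks. The unbound ("free") fraction
of each targeted cytokine then multiplies that cytokine's concentration in
every network rate law it modifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .species import CYTOKINE_MW, TARGETABLE

__all__ = [
    "DrugMechanism",
    "builtin_mechanisms",
    "free_fraction",
    "apply_mechanisms",
]

#: repository-default antibody affinity (nM); typical high-affinity
#: therapeutic mAb, overridable per drug from configuration
DEFAULT_KD_NM = 0.1


@dataclass(frozen=True)
class DrugMechanism:
    """Which cytokine(s) a drug neutralises and with what affinity."""

    drug: str
    targets: tuple[str, ...]
    Kd: float = DEFAULT_KD_NM          # nM
    stoichiometry: float = 2.0         # binding sites per antibody (IgG)

    def __post_init__(self):
        if not self.targets:
            raise ValueError("a drug mechanism needs at least one target")
        unknown = set(self.targets) - set(TARGETABLE)
        if unknown:
            raise ValueError(f"untargetable cytokines: {sorted(unknown)}")
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")
        if self.stoichiometry <= 0:
            raise ValueError("stoichiometry must be positive")


def builtin_mechanisms(kd_overrides: dict[str, float] | None = None,
                       ) -> dict[str, DrugMechanism]:
    """The five modelled antibodies and their cytokine targets.

    anti-IL-12p40 (ustekinumab) hits the shared p40 subunit and therefore
    neutralises both IL-12 and IL-23; the anti-p19 antibodies (brazikumab,
    risankizumab) are IL-23-selective; infliximab binds TNFα; PF-04236921
    binds IL-6.
    """
    kd = kd_overrides or {}
    mechanisms = {
        "ustekinumab": ("IL12", "IL23"),
        "brazikumab": ("IL23",),
        "risankizumab": ("IL23",),
        "infliximab": ("TNFa",),
        "PF-04236921": ("IL6",),
    }
    return {
        drug: DrugMechanism(drug=drug, targets=targets,
                            Kd=kd.get(drug, DEFAULT_KD_NM))
        for drug, targets in mechanisms.items()
    }


def free_fraction(total_ligand: float, drug: float, Kd: float,
                  stoichiometry: float = 2.0) -> float:
    """Unbound fraction of a cytokine at binding equilibrium.

    With T the total ligand, B = stoichiometry x drug the binding-site
    concentration (all nM), the free ligand L is the positive root of

        L^2 + (Kd + B - T) L - Kd T = 0,

    and the free fraction is L / T (1 when T = 0). Uses the
    cancellation-safe conjugate form of the quadratic root.
    """
    if total_ligand < 0 or drug < 0 or Kd <= 0 or stoichiometry <= 0:
        raise ValueError("binding inputs must be non-negative (Kd > 0)")
    T = total_ligand
    if T == 0.0 or drug == 0.0:
        return 1.0
    B = stoichiometry * drug
    b = Kd + B - T
    L = 2.0 * Kd * T / (b + math.sqrt(b * b + 4.0 * Kd * T))
    return min(L / T, 1.0)


def apply_mechanisms(mechanisms, pk_profiles, state, t: float,
                     cytokine_mw: dict[str, float] = CYTOKINE_MW,
                     ) -> dict[str, float]:
    """Per-cytokine free fractions at time ``t`` under the dosed drugs.

    Parameters
    ----------
    mechanisms
        Iterable of :class:`DrugMechanism` for the drugs in the arm.
    pk_profiles
        Mapping drug name -> profile whose ``.molar(t)`` gives the serum
        drug concentration in nM (see :class:`ibdqsp.pk.ConcentrationProfile`).
    state
        Species state providing total cytokine concentrations (pg/mL).

    When two drugs hit the same cytokine their free fractions combine
    multiplicatively; untargeted cytokines get 1.
    """
    from .species import IDX

    free = dict.fromkeys(TARGETABLE, 1.0)
    for mech in mechanisms:
        profile = pk_profiles.get(mech.drug)
        if profile is None:
            continue
        drug_nm = float(profile.molar(t))
        if drug_nm <= 0.0:
            continue
        for cyt in mech.targets:
            # pg/mL -> nM: (1e-9 g/L) / (MW g/mol) * 1e9
            total_nm = max(float(state[IDX[cyt]]), 0.0) / cytokine_mw[cyt]
            free[cyt] *= free_fraction(total_nm, drug_nm, mech.Kd,
                                       mech.stoichiometry)
    return free


def make_free_fraction_fn(mechanisms, pk_profiles,
                          cytokine_mw: dict[str, float] = CYTOKINE_MW):
    """Compile a fast ``(t, y) -> (f_TNF, f_IL6, f_IL12, f_IL23)`` closure."""
    from .species import IDX

    plan = []  # (target index in TARGETABLE, state index, MW, Kd, stoich, profile)
    for mech in mechanisms:
        profile = pk_profiles.get(mech.drug)
        if profile is None or getattr(profile, "regimen", None) is not None \
                and profile.regimen.is_empty:
            continue
        for cyt in mech.targets:
            plan.append((TARGETABLE.index(cyt), IDX[cyt], cytokine_mw[cyt],
                         mech.Kd, mech.stoichiometry, profile))
    if not plan:
        return None

    def ff(t, y):
        out = [1.0, 1.0, 1.0, 1.0]
        for k, yi, mw, kd, stoich, profile in plan:
            drug_nm = float(profile.molar(t))
            if drug_nm <= 0.0:
                continue
            total = y[yi]
            total_nm = (total if total > 0.0 else 0.0) / mw
            out[k] *= free_fraction(total_nm, drug_nm, kd, stoich)
        return out

    return ff
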