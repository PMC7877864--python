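"""Integration of the immune-network ODE system.

The right-hand side here is a hand-optimised closure over one patient's
parameter values; it must stay numerically identical (to ~1e-12) to the
interpretive evaluation of the declarative network in :mod:`ibdqsp.network`,
which the test suite enforces on random states.

Drug effect enters exclusively as a per-cytokine *free fraction*: every rate
term in which a drug-targetable cytokine acts as a modifier sees
``free_fraction * concentration`` instead of the total concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import ParameterSet, design_state_vector
from .species import N_SPECIES, SPECIES, TARGETABLE, as_state_array

__all__ = [
    "SolverSettings",
    "Trajectory",
    "IntegrationError",
    "SteadyStateError",
    "derivatives",
    "make_rhs",
    "simulate",
    "steady_state",
]


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the time at which integration stopped."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:.4g} d)")
        self.t_fail = t_fail


class SteadyStateError(RuntimeError):
    """No steady state found within tolerance (patient rejected)."""


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-capable solver configuration (defaults: LSODA, rtol 1e-8)."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf


DEFAULT_SOLVER = SolverSettings()

_ONES_FREE = (1.0, 1.0, 1.0, 1.0)  # (TNFa, IL6, IL12, IL23)


def _free_tuple(free_fraction) -> tuple[float, float, float, float]:
    if free_fraction is None:
        return _ONES_FREE
    if isinstance(free_fraction, dict):
        vals = tuple(float(free_fraction.get(c, 1.0)) for c in TARGETABLE)
    else:
        vals = tuple(float(v) for v in free_fraction)
        if len(vals) != 4:
            raise ValueError("free_fraction must give (TNFa, IL6, IL12, IL23)")
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"free fractions must lie in [0, 1], got {v}")
    return vals  # type: ignore[return-value]


def make_rhs(params: ParameterSet, free_fraction_fn=None):
    """Compile the ODE right-hand side for one parameter set.

    ``free_fraction_fn(t, y) -> (f_TNF, f_IL6, f_IL12, f_IL23)`` supplies the
    unbound fraction of each targetable cytokine; ``None`` means no drug.
    """
    p = params.as_dict()
    n = p["hill_n"]
    general_hill = n != 1.0

    (s_Th0, kd_Th0, k_Th1, Km_IL12_Th1, Km_Treg, kd_Th1, k_Th17,
     Km_IL23_Th17, alpha_IL6_Th17, Km_IL6_Th17, kd_Th17, s_Treg, kd_Treg,
     s_NK, b_NK, Km_IL12_NK, kd_NK, s_iDC, kd_iDC, k_aDC, b_DC, Km_TNF_DC,
     alpha_IL6_DC, Km_IL6_DC, kd_eDC, s_M0, kd_M0, k_aM, b_M, Km_TNF_M,
     alpha_IFN_M, Km_IFN_M, kd_M1, s_Neu, kd_Neu, k_aN, b_Neu, Km_TNF_Neu,
     alpha_IL17_Neu, Km_IL17_Neu, kd_Neu_a, p_TNF, b_TNF, kdeg_TNF, p_IL6,
     b_IL6, b_IL6_TNF, Km_TNF_IL6, kdeg_IL6, p_IL8, b_IL8, kdeg_IL8, p_IL12,
     b_IL12, kdeg_IL12, p_IL23, b_IL23, kdeg_IL23, p_IL17, b_IL17, kdeg_IL17,
     p_IL22, b_IL22, kdeg_IL22, p_IFN_Th1, p_IFN_NK, b_IFN, kdeg_IFN,
     p_GMCSF, b_GMCSF, kdeg_GMCSF, p_CRP, b_CRP, Km_IL6_CRP, kdeg_CRP,
     p_FCP, Km_Neu_FCP, w_IL8_FCP, Km_IL8_FCP, b_FCP, kdeg_FCP, w_Neu_cyt,
     ) = (
        p["s_Th0"], p["kd_Th0"], p["k_Th1"], p["Km_IL12_Th1"], p["Km_Treg"],
        p["kd_Th1"], p["k_Th17"], p["Km_IL23_Th17"], p["alpha_IL6_Th17"],
        p["Km_IL6_Th17"], p["kd_Th17"], p["s_Treg"], p["kd_Treg"], p["s_NK"],
        p["b_NK"], p["Km_IL12_NK"], p["kd_NK"], p["s_iDC"], p["kd_iDC"],
        p["k_aDC"], p["b_DC"], p["Km_TNF_DC"], p["alpha_IL6_DC"],
        p["Km_IL6_DC"], p["kd_eDC"], p["s_M0"], p["kd_M0"], p["k_aM"],
        p["b_M"], p["Km_TNF_M"], p["alpha_IFN_M"], p["Km_IFN_M"], p["kd_M1"],
        p["s_Neu"], p["kd_Neu"], p["k_aN"], p["b_Neu"], p["Km_TNF_Neu"],
        p["alpha_IL17_Neu"], p["Km_IL17_Neu"], p["kd_Neu_a"], p["p_TNF"],
        p["b_TNF"], p["kdeg_TNF"], p["p_IL6"], p["b_IL6"], p["b_IL6_TNF"],
        p["Km_TNF_IL6"], p["kdeg_IL6"], p["p_IL8"], p["b_IL8"], p["kdeg_IL8"],
        p["p_IL12"], p["b_IL12"], p["kdeg_IL12"], p["p_IL23"], p["b_IL23"],
        p["kdeg_IL23"], p["p_IL17"], p["b_IL17"], p["kdeg_IL17"], p["p_IL22"],
        p["b_IL22"], p["kdeg_IL22"], p["p_IFN_Th1"], p["p_IFN_NK"], p["b_IFN"],
        p["kdeg_IFN"], p["p_GMCSF"], p["b_GMCSF"], p["kdeg_GMCSF"], p["p_CRP"],
        p["b_CRP"], p["Km_IL6_CRP"], p["kdeg_CRP"], p["p_FCP"],
        p["Km_Neu_FCP"], p["w_IL8_FCP"], p["Km_IL8_FCP"], p["b_FCP"],
        p["kdeg_FCP"], p["w_Neu_cyt"],
    )

    if general_hill:
        def hill(x, km):
            if x <= 0.0:
                return 0.0
            xn = x ** n
            return xn / (km ** n + xn)

        def inh(x, km):
            kmn = km ** n
            return kmn / (kmn + (x if x > 0.0 else 0.0) ** n)
    else:
        def hill(x, km):
            return x / (km + x) if x > 0.0 else 0.0

        def inh(x, km):
            return km / (km + x) if x > 0.0 else 1.0

    def rhs(t, y):
        Th0 = y[0] if y[0] > 0.0 else 0.0
        Th1 = y[1] if y[1] > 0.0 else 0.0
        Th17 = y[2] if y[2] > 0.0 else 0.0
        Treg = y[3] if y[3] > 0.0 else 0.0
        NK1 = y[4] if y[4] > 0.0 else 0.0
        iDC = y[5] if y[5] > 0.0 else 0.0
        eDC = y[6] if y[6] > 0.0 else 0.0
        M0 = y[7] if y[7] > 0.0 else 0.0
        M1 = y[8] if y[8] > 0.0 else 0.0
        Neu = y[9] if y[9] > 0.0 else 0.0
        Neu_a = y[10] if y[10] > 0.0 else 0.0
        TNF = y[11] if y[11] > 0.0 else 0.0
        IL6 = y[12] if y[12] > 0.0 else 0.0
        IL8 = y[13] if y[13] > 0.0 else 0.0
        IL12 = y[14] if y[14] > 0.0 else 0.0
        IL17 = y[15] if y[15] > 0.0 else 0.0
        IL22 = y[16] if y[16] > 0.0 else 0.0
        IL23 = y[17] if y[17] > 0.0 else 0.0
        IFN = y[18] if y[18] > 0.0 else 0.0
        GM = y[19] if y[19] > 0.0 else 0.0
        CRP = y[20] if y[20] > 0.0 else 0.0
        FCP = y[21] if y[21] > 0.0 else 0.0

        if free_fraction_fn is None:
            fT = f6 = f12 = f23 = 1.0
        else:
            fT, f6, f12, f23 = free_fraction_fn(t, y)

        TNF_f = fT * TNF
        IL6_f = f6 * IL6
        IL12_f = f12 * IL12
        IL23_f = f23 * IL23

        i_treg = inh(Treg, Km_Treg)
        r_th1 = k_Th1 * Th0 * hill(IL12_f, Km_IL12_Th1) * i_treg
        r_th17 = (k_Th17 * Th0 * i_treg
                  * (hill(IL23_f, Km_IL23_Th17)
                     + alpha_IL6_Th17 * hill(IL6_f, Km_IL6_Th17)))
        r_dc = k_aDC * iDC * (b_DC + hill(TNF_f, Km_TNF_DC)
                              + alpha_IL6_DC * hill(IL6_f, Km_IL6_DC))
        r_m = k_aM * M0 * (b_M + hill(TNF_f, Km_TNF_M)
                           + alpha_IFN_M * hill(IFN, Km_IFN_M))
        r_n = k_aN * Neu * (b_Neu + hill(TNF_f, Km_TNF_Neu)
                            + alpha_IL17_Neu * hill(IL17, Km_IL17_Neu))

        w_myeloid = eDC + M1 + w_Neu_cyt * Neu_a
        w_apc = eDC + M1

        return (
            s_Th0 - kd_Th0 * Th0,
            r_th1 - kd_Th1 * Th1,
            r_th17 - kd_Th17 * Th17,
            s_Treg - kd_Treg * Treg,
            s_NK * (b_NK + hill(IL12_f, Km_IL12_NK)) - kd_NK * NK1,
            s_iDC - kd_iDC * iDC - r_dc,
            r_dc - kd_eDC * eDC,
            s_M0 - kd_M0 * M0 - r_m,
            r_m - kd_M1 * M1,
            s_Neu - kd_Neu * Neu - r_n,
            r_n - kd_Neu_a * Neu_a,
            p_TNF * w_myeloid + b_TNF - kdeg_TNF * TNF,
            p_IL6 * w_myeloid * (b_IL6_TNF + hill(TNF_f, Km_TNF_IL6))
            + b_IL6 - kdeg_IL6 * IL6,
            p_IL8 * w_myeloid + b_IL8 - kdeg_IL8 * IL8,
            p_IL12 * w_apc + b_IL12 - kdeg_IL12 * IL12,
            p_IL17 * Th17 + b_IL17 - kdeg_IL17 * IL17,
            p_IL22 * Th17 + b_IL22 - kdeg_IL22 * IL22,
            p_IL23 * w_apc + b_IL23 - kdeg_IL23 * IL23,
            p_IFN_Th1 * Th1 + p_IFN_NK * NK1 + b_IFN - kdeg_IFN * IFN,
            p_GMCSF * w_myeloid + b_GMCSF - kdeg_GMCSF * GM,
            p_CRP * hill(IL6_f, Km_IL6_CRP) + b_CRP - kdeg_CRP * CRP,
            p_FCP * (hill(Neu_a, Km_Neu_FCP)
                     + w_IL8_FCP * hill(IL8, Km_IL8_FCP))
            + b_FCP - kdeg_FCP * FCP,
        )

    return rhs


def derivatives(state, params: ParameterSet, free_fraction=None) -> np.ndarray:
    """Species rate vector (per day) at one state.

    ``free_fraction`` is a dict cytokine -> multiplier in [0, 1] (defaulting
    to 1 for every targetable cytokine) or a 4-tuple ordered as
    ``(TNFa, IL6, IL12, IL23)``. Negative state values are a domain error.
    """
    y = as_state_array(state)
    if np.any(y < 0):
        raise ValueError("negative concentrations in state")
    ff = _free_tuple(free_fraction)
    rhs = make_rhs(params, (lambda t, _y: ff) if ff != _ONES_FREE else None)
    return np.asarray(rhs(0.0, y))


@dataclass
class Trajectory:
    """Time-resolved species trajectory on the requested output grid."""

    times: np.ndarray              # (n_t,) days
    states: np.ndarray             # (n_t, n_species)

    def marker(self, name: str) -> np.ndarray:
        from .species import IDX

        return self.states[:, IDX[name]]

    def endpoint(self):
        from .species import SpeciesState

        return SpeciesState(np.maximum(self.states[-1], 0.0))

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, index=pd.Index(self.times, name="time_days"),
                            columns=list(SPECIES))


def simulate(patient_or_params, horizon_days: float,
             free_fraction_timecourse=None, grid=None,
             y0=None, breakpoints=(), solver: SolverSettings = DEFAULT_SOLVER,
             ) -> Trajectory:
    """Integrate one subject over ``[0, horizon_days]``.

    Parameters
    ----------
    patient_or_params
        A :class:`~ibdqsp.population.VirtualPatient` (its stored steady state
        is the initial condition) or a bare :class:`ParameterSet` (requires
        ``y0``, defaulting to the design state).
    free_fraction_timecourse
        ``None`` (drug-free), or a callable giving per-targetable-cytokine
        free fractions; called as ``f(t, y)`` and falling back to ``f(t)``.
        May return a dict or a 4-sequence ordered (TNFa, IL6, IL12, IL23).
    grid
        Output time points (sorted, within the horizon). Defaults to daily.
    breakpoints
        Interior times at which the forcing is discontinuous (dose events);
        integration is restarted there.
    """
    if hasattr(patient_or_params, "parameters") and hasattr(patient_or_params, "baseline"):
        params = patient_or_params.parameters
        if y0 is None:
            y0 = patient_or_params.baseline
    else:
        params = patient_or_params
    if y0 is None:
        y0 = design_state_vector()
    y0 = np.maximum(as_state_array(y0), 0.0)

    if horizon_days < 0:
        raise ValueError("horizon must be >= 0")
    if grid is None:
        grid = np.linspace(0.0, horizon_days, int(round(horizon_days)) + 1)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0) or grid[0] < 0 or grid[-1] > horizon_days + 1e-9:
        raise ValueError("grid must be sorted and within [0, horizon]")

    ff_fn = _wrap_ff(free_fraction_timecourse)
    rhs = make_rhs(params, ff_fn)

    seg_edges = np.unique(np.concatenate(
        [[0.0, horizon_days], np.asarray(breakpoints, dtype=float)]))
    seg_edges = seg_edges[(seg_edges >= 0) & (seg_edges <= horizon_days)]

    out_states = np.empty((len(grid), N_SPECIES))
    filled = np.zeros(len(grid), dtype=bool)
    if grid[0] == 0.0:
        out_states[0] = y0
        filled[0] = True

    y = y0.copy()
    for t0, t1 in zip(seg_edges[:-1], seg_edges[1:]):
        mask = (~filled) & (grid > t0 + 1e-12) & (grid <= t1 + 1e-12)
        t_eval = grid[mask]
        # always evaluate the segment end so the state carries across doses
        need_end = len(t_eval) == 0 or not np.isclose(t_eval[-1], t1)
        te = np.append(t_eval, t1) if need_end else t_eval
        sol = solve_ivp(rhs, (t0, t1), y, method=solver.method,
                        rtol=solver.rtol, atol=solver.atol,
                        max_step=solver.max_step, t_eval=te)
        if not sol.success:
            raise IntegrationError(sol.message, sol.t[-1] if len(sol.t) else t0)
        ys = sol.y.T
        if len(t_eval):
            out_states[mask] = ys[: len(t_eval)]
            filled[mask] = True
        y = ys[-1].copy()

    states = np.maximum(out_states, 0.0)
    return Trajectory(times=grid, states=states)


def _wrap_ff(fn):
    if fn is None:
        return None

    def wrapped(t, y):
        try:
            out = fn(t, y)
        except TypeError:
            out = fn(t)
        if isinstance(out, dict):
            return tuple(float(out.get(c, 1.0)) for c in TARGETABLE)
        return tuple(float(v) for v in out)

    return wrapped


def steady_state(params: ParameterSet, init=None,
                 solver: SolverSettings = DEFAULT_SOLVER,
                 settle_days: float = 600.0, tol: float = 1e-8,
                 max_restarts: int = 3):
    """Drug-free steady state of the network for one parameter set.

    Relaxes the system by integration from ``init`` (default: the design
    state), polishes with a Newton-type root find on the rate equations, and
    verifies the scaled residual ``|dy/dt| / (1 + |y|) < tol``. Raises
    :class:`SteadyStateError` if no non-negative converged state is found —
    virtual-population generation treats that subject as implausible.
    """
    rhs = make_rhs(params, None)
    y = design_state_vector() if init is None else np.maximum(as_state_array(init), 0.0)

    # the relaxation phase only needs to land in the fixed point's basin;
    # accuracy comes from the Newton polish and the residual check below
    settle_rtol = max(solver.rtol, 1e-6)
    settle_atol = max(solver.atol, 1e-8)
    horizon = settle_days
    for _ in range(max_restarts):
        sol = solve_ivp(rhs, (0.0, horizon), y, method=solver.method,
                        rtol=settle_rtol, atol=settle_atol)
        if not sol.success:
            raise SteadyStateError(f"relaxation failed: {sol.message}")
        y = np.maximum(sol.y[:, -1], 0.0)
        res = root(lambda v: np.asarray(rhs(0.0, v)), y, method="hybr",
                   options={"xtol": 1e-12})
        cand = res.x
        scaled = np.max(np.abs(np.asarray(rhs(0.0, cand)))
                        / (1.0 + np.abs(cand)))
        if scaled < tol and np.all(cand > -1e-9):
            from .species import SpeciesState

            return SpeciesState(np.maximum(cand, 0.0))
        horizon *= 2.0
    raise SteadyStateError(
        f"no steady state within tolerance {tol} after {max_restarts} restarts")
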