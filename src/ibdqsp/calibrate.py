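"""Calibration of nominal model parameters against clinical biomarker data.

The original steady-state training of the network is replaced here by a
small, reproducible calibration: a designated subset of nominal parameters
(and, where natural, a drug's binding affinity, addressed as ``"Kd:<drug>"``)
is fitted so that simulated trial arms reproduce printed clinical biomarker
outcomes — by default the week-12 median percent CRP reductions of the
anti-IL-6 (PF-04236921) induction dose arms, the most direct published
dose-response readout of the CRP axis.

The objective is a weighted sum of squared relative residuals between
simulated and observed target values, evaluated over a fixed surrogate
population whose variability factors are frozen at problem construction so
the loss surface is deterministic. Optimisation is derivative-free
(log-space Nelder-Mead with optional seeded multistart) because the
population-median objective is piecewise smooth at best.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dynamics import DEFAULT_SOLVER, SolverSettings, SteadyStateError, steady_state
from .params import ParameterSet
from .pk import DoseEvent, Regimen
from .population import Cohort, VirtualPatient
from .trial import ArmResult, TrialSpec, simulate_arm

__all__ = [
    "CalibrationTarget",
    "CalibrationProblem",
    "CalibrationResult",
    "FitResult",
    "default_anti_il6_targets",
    "calibrate",
]

_TRANSFORMS = ("absolute", "change", "percent_change", "percent_reduction")
_PENALTY = 1e6


@dataclass(frozen=True)
class CalibrationTarget:
    """One observed clinical quantity a simulated arm must reproduce."""

    description: str
    regimens: tuple[Regimen, ...]
    marker: str
    day: float
    value: float
    transform: str = "percent_reduction"
    statistic: str = "median"
    unit: str = ""
    weight: float = 1.0

    def __post_init__(self):
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.statistic not in ("median", "mean"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    def arm_key(self) -> tuple:
        return tuple((r.drug, r.dose_times(),
                      tuple((e.amount, e.amount_per_kg, e.route)
                            for e in r.events)) for r in self.regimens)

    def extract(self, result: ArmResult) -> float:
        """Pull this target's simulated value out of an arm result."""
        values = result.value_at(self.marker, self.day)
        base = result.baseline(self.marker)
        if self.transform == "absolute":
            per_patient = values
        elif self.transform == "change":
            per_patient = values - base
        elif self.transform == "percent_change":
            per_patient = 100.0 * (values - base) / base
        else:  # percent_reduction
            per_patient = 100.0 * (base - values) / base
        return float(per_patient.median() if self.statistic == "median"
                     else per_patient.mean())

    def residual(self, simulated: float) -> float:
        """Relative residual; log-scale for absolute concentrations."""
        if self.transform == "absolute":
            if simulated <= 0 or self.value <= 0:
                return _PENALTY
            return float(np.log(simulated / self.value))
        if self.transform in ("percent_change", "percent_reduction"):
            return (simulated - self.value) / 100.0
        return (simulated - self.value) / max(abs(self.value), 1e-9)


def default_anti_il6_targets(horizon_day: float = 84.0,
                             ) -> tuple[CalibrationTarget, ...]:
    """Week-12 median percent CRP reductions of the anti-IL-6 dose arms.

    The three induction arms dosed 10, 50 and 200 mg s.c. on days 1 and 28
    reported median CRP reductions of 65.6%, 86.3% and 95% at week 12.
    """
    def reg(dose):
        return Regimen("PF-04236921",
                       (DoseEvent(1.0, amount=dose, route="sc"),
                        DoseEvent(28.0, amount=dose, route="sc")))

    observed = {200.0: 95.0, 50.0: 86.3, 10.0: 65.6}
    return tuple(
        CalibrationTarget(
            description=f"anti-IL-6 {dose:g} mg: median % CRP reduction wk12",
            regimens=(reg(dose),), marker="CRP", day=horizon_day,
            value=value, transform="percent_reduction", statistic="median",
            unit="%")
        for dose, value in sorted(observed.items(), reverse=True))


def _split_names(param_names, base_params: ParameterSet):
    """Separate plain parameter names from ``Kd:<drug>`` affinity knobs."""
    plain, kd = [], []
    for name in param_names:
        if name.startswith("Kd:"):
            kd.append(name[3:])
        elif name in base_params:
            plain.append(name)
        else:
            raise KeyError(f"unknown calibration parameter {name!r}")
    return plain, kd


class CalibrationProblem:
    """Precomputed, deterministic objective for one set of targets.

    The surrogate population's variability factors are frozen when the
    problem is built; every objective evaluation recomputes each patient's
    steady state under the candidate nominal parameters (warm-started from
    the previous evaluation) and re-simulates every target arm.
    """

    def __init__(self, targets, base_params: ParameterSet,
                 population: Cohort, mechanisms=None, pk_library=None,
                 solver: SolverSettings = DEFAULT_SOLVER,
                 spec: TrialSpec | None = None):
        if not targets:
            raise ValueError("at least one calibration target is required")
        self.targets = tuple(targets)
        self.base_params = base_params
        self.factors = [dict(p.factors) for p in population]
        self.ids = list(population.ids)
        self.mechanisms = mechanisms
        self.pk_library = pk_library
        self.solver = solver
        horizon = max(t.day for t in self.targets)
        self.spec = spec or TrialSpec(horizon_days=horizon)
        # frozen warm starts: every evaluation relaxes from the *original*
        # baselines so the objective is a pure function of the parameters
        self._warm_start: dict[int, np.ndarray] = {
            pid: p.baseline.copy() for pid, p in zip(self.ids, population)}
        self.n_failures = 0

    def _population_for(self, params: ParameterSet) -> Cohort:
        patients = []
        for pid, factors in zip(self.ids, self.factors):
            pset = params.perturbed(factors)
            try:
                ss = steady_state(pset, init=self._warm_start[pid],
                                  solver=self.solver, settle_days=300.0)
            except SteadyStateError:
                self.n_failures += 1
                continue
            patients.append(VirtualPatient(id=pid, parameters=pset,
                                           baseline=ss.values,
                                           factors=factors))
        if not patients:
            raise SteadyStateError("no surrogate patient converged")
        return Cohort(patients=patients)

    def simulated_values(self, params: ParameterSet,
                         kd_overrides: dict[str, float] | None = None,
                         ) -> list[float]:
        from .binding import builtin_mechanisms

        mechanisms = self.mechanisms if self.mechanisms is not None \
            else builtin_mechanisms()
        if kd_overrides:
            mechanisms = {
                drug: (replace(m, Kd=kd_overrides[drug])
                       if drug in kd_overrides else m)
                for drug, m in mechanisms.items()}
        population = self._population_for(params)
        arm_cache: dict[tuple, ArmResult] = {}
        out = []
        for target in self.targets:
            key = target.arm_key()
            if key not in arm_cache:
                arm_cache[key] = simulate_arm(
                    population, list(target.regimens), spec=self.spec,
                    mechanisms=mechanisms, pk_library=self.pk_library,
                    solver=self.solver)
            out.append(target.extract(arm_cache[key]))
        return out

    def residuals(self, params: ParameterSet,
                  kd_overrides: dict[str, float] | None = None,
                  ) -> pd.DataFrame:
        sims = self.simulated_values(params, kd_overrides)
        rows = [{
            "description": t.description, "observed": t.value,
            "simulated": sim, "residual": t.residual(sim),
            "weight": t.weight,
        } for t, sim in zip(self.targets, sims)]
        return pd.DataFrame(rows)

    def objective(self, params: ParameterSet,
                  kd_overrides: dict[str, float] | None = None) -> float:
        """Weighted sum of squared relative residuals (lower is better)."""
        try:
            res = self.residuals(params, kd_overrides)
        except (SteadyStateError, RuntimeError):
            return _PENALTY
        loss = float((res["weight"] * res["residual"] ** 2).sum())
        return loss if np.isfinite(loss) else _PENALTY


@dataclass
class CalibrationResult:
    """Fitted parameters with residuals, optimiser trace and provenance."""

    params: ParameterSet
    kd_overrides: dict[str, float]
    param_names: tuple[str, ...]
    initial_values: dict[str, float]
    fitted_values: dict[str, float]
    residuals: pd.DataFrame
    objective: float
    nfev: int
    trace: list[tuple[int, float]] = field(default_factory=list)
    seed: int | None = None
    problem: CalibrationProblem | None = None
    model = None  # set by CrohnsQSPModel.fit

    def summary(self) -> str:
        lines = ["Calibration result", "=" * 66]
        lines.append(f"objective: {self.objective:.6g}   "
                     f"evaluations: {self.nfev}   seed: {self.seed}")
        lines.append("")
        lines.append(f"{'parameter':<24}{'initial':>12}{'fitted':>12}{'ratio':>9}")
        lines.append("-" * 57)
        for name in self.param_names:
            x0 = self.initial_values[name]
            x1 = self.fitted_values[name]
            lines.append(f"{name:<24}{x0:>12.4g}{x1:>12.4g}{x1 / x0:>9.3f}")
        lines.append("")
        lines.append(f"{'target':<44}{'obs':>7}{'sim':>8}")
        lines.append("-" * 59)
        for _, row in self.residuals.iterrows():
            lines.append(f"{row['description']:<44}"
                         f"{row['observed']:>7.4g}{row['simulated']:>8.4g}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "initial_values": self.initial_values,
            "fitted_values": self.fitted_values,
            "kd_overrides": self.kd_overrides,
            "objective": self.objective,
            "nfev": self.nfev,
            "seed": self.seed,
            "residuals": self.residuals.to_dict(orient="records"),
        }


#: legacy-style alias for the results object
FitResult = CalibrationResult


def calibrate(problem: CalibrationProblem, param_names, seed: int = 0,
              maxfev: int = 60, n_starts: int = 1,
              bound_log10: float = 2.0,
              kd_start: dict[str, float] | None = None) -> CalibrationResult:
    """Fit the named parameters by log-space Nelder-Mead (multistart).

    ``param_names`` may mix ParameterSet fields and ``"Kd:<drug>"`` affinity
    entries. The search space is bounded to ±``bound_log10`` decades around
    the starting values (default ±100-fold) via a quadratic penalty.
    ``maxfev = 0`` returns the starting point unchanged.
    """
    from .binding import DEFAULT_KD_NM

    base = problem.base_params
    plain, kd_drugs = _split_names(param_names, base)
    kd_start = kd_start or {}
    x0 = np.array([np.log10(base[n]) for n in plain]
                  + [np.log10(kd_start.get(d, DEFAULT_KD_NM)) for d in kd_drugs])
    if not np.all(np.isfinite(x0)):
        raise ValueError("objective is undefined at the initial point "
                         "(zero-valued parameter cannot be log-scaled)")

    def unpack(x):
        params = base.updated(**{n: 10.0 ** xi for n, xi in zip(plain, x)})
        kd = {d: 10.0 ** xi for d, xi in zip(kd_drugs, x[len(plain):])}
        return params, kd

    trace: list[tuple[int, float]] = []

    def fun(x):
        penalty = float(np.sum(np.maximum(np.abs(x - x0) - bound_log10, 0.0) ** 2))
        params, kd = unpack(x)
        loss = problem.objective(params, kd) + 100.0 * penalty
        trace.append((len(trace), loss))
        return loss

    loss0 = fun(x0)
    best_x, best_loss = x0, loss0
    if not np.isfinite(loss0) or loss0 >= _PENALTY:
        raise ValueError("objective is non-finite at the initial point")

    if maxfev > 0:
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(0, n_starts - 1)):
            starts.append(x0 + rng.uniform(-0.5, 0.5, size=len(x0)))
        per_start = max(maxfev // len(starts), 1)
        for start in starts:
            res = minimize(fun, start, method="Nelder-Mead",
                           options={"maxfev": per_start, "xatol": 1e-3,
                                    "fatol": 1e-6, "adaptive": True})
            if res.fun < best_loss:
                best_loss, best_x = float(res.fun), res.x

    params, kd = unpack(best_x)
    residuals = problem.residuals(params, kd)
    fitted = {n: 10.0 ** xi for n, xi in zip(plain, best_x)}
    fitted.update({f"Kd:{d}": 10.0 ** xi
                   for d, xi in zip(kd_drugs, best_x[len(plain):])})
    initial = {n: 10.0 ** xi for n, xi in zip(plain, x0)}
    initial.update({f"Kd:{d}": 10.0 ** xi
                    for d, xi in zip(kd_drugs, x0[len(plain):])})
    return CalibrationResult(
        params=params, kd_overrides=kd, param_names=tuple(param_names),
        initial_values=initial, fitted_values=fitted, residuals=residuals,
        objective=float((residuals["weight"] * residuals["residual"] ** 2).sum()),
        nfev=len(trace), trace=trace, seed=seed, problem=problem)
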