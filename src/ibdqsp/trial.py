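"""In-silico trial simulation, biomarker summaries, and responder analysis.

Every patient in an arm shares the arm's drug concentration-time profile;
all between-patient variability comes from the mechanistic parameters.
Placebo arms carry no drug and therefore stay at baseline — the framework
predicts treatment effect only, and observed placebo rates are removed from
reported clinical response rates arithmetically (:func:`placebo_corrected`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import builtin_mechanisms, make_free_fraction_fn
from .dynamics import (DEFAULT_SOLVER, IntegrationError, SolverSettings,
                       simulate)
from .pk import ConcentrationProfile, Regimen, default_pk_parameters, resolve_doses
from .population import Cohort
from .species import IDX, SPECIES

__all__ = [
    "TrialSpec",
    "ArmResult",
    "ResponseCriterion",
    "ResponderPartition",
    "ArmSimulationError",
    "simulate_arm",
    "simulate_combination",
    "classify_responders",
    "placebo_corrected",
]

#: markers reported by default in long-format exports
REPORT_MARKERS = ("CRP", "FCP", "IL6", "IL8", "IL17", "IL22", "TNFa", "Treg")


class ArmSimulationError(RuntimeError):
    """More than the tolerated fraction of patients failed to integrate."""


@dataclass(frozen=True)
class TrialSpec:
    """Simulation horizon and output grid for a trial."""

    horizon_days: float = 84.0
    grid: np.ndarray | None = None
    max_failure_fraction: float = 0.05

    def resolve_grid(self) -> np.ndarray:
        if self.grid is None:
            return np.linspace(0.0, self.horizon_days,
                               int(round(self.horizon_days)) + 1)
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) < 0) or g[0] < 0 or g[-1] > self.horizon_days:
            raise ValueError("grid must be sorted and within the horizon")
        return g


@dataclass
class ArmResult:
    """Per-patient biomarker trajectories for one arm plus summary helpers."""

    name: str
    ids: np.ndarray                 # (n_pat,)
    times: np.ndarray               # (n_t,)
    values: np.ndarray              # (n_pat, n_t, n_species)
    failed_ids: tuple[int, ...] = ()
    regimens: tuple[Regimen, ...] = ()

    def series(self, marker: str) -> pd.DataFrame:
        """Patient x time matrix of one marker (index = patient id)."""
        return pd.DataFrame(self.values[:, :, IDX[marker]],
                            index=pd.Index(self.ids, name="id"),
                            columns=self.times)

    def baseline(self, marker: str) -> pd.Series:
        return self.series(marker).iloc[:, 0]

    def value_at(self, marker: str, day: float,
                 day_tolerance: float = 0.5) -> pd.Series:
        i = int(np.argmin(np.abs(self.times - day)))
        if abs(self.times[i] - day) > day_tolerance:
            raise ValueError(
                f"output grid has no point within {day_tolerance} d of day {day}")
        return self.series(marker).iloc[:, i]

    def change(self, marker: str) -> pd.DataFrame:
        s = self.series(marker)
        return s.sub(s.iloc[:, 0], axis=0)

    def percent_change(self, marker: str) -> pd.DataFrame:
        s = self.series(marker)
        return 100.0 * s.sub(s.iloc[:, 0], axis=0).div(s.iloc[:, 0], axis=0)

    def summary(self, marker: str, statistic: str = "median_iqr",
                transform: str = "absolute") -> pd.DataFrame:
        """Summary curves of one marker: median/IQR, mean/SD, or median/range.

        ``transform`` is ``absolute``, ``change`` or ``percent_change``.
        """
        if transform == "absolute":
            data = self.series(marker)
        elif transform == "change":
            data = self.change(marker)
        elif transform == "percent_change":
            data = self.percent_change(marker)
        else:
            raise ValueError(f"unknown transform {transform!r}")
        if statistic == "median_iqr":
            out = pd.DataFrame({
                "median": data.median(axis=0),
                "q25": data.quantile(0.25, axis=0),
                "q75": data.quantile(0.75, axis=0)})
        elif statistic == "mean_sd":
            out = pd.DataFrame({"mean": data.mean(axis=0),
                                "sd": data.std(axis=0, ddof=1)})
        elif statistic == "median_range":
            out = pd.DataFrame({"median": data.median(axis=0),
                                "min": data.min(axis=0),
                                "max": data.max(axis=0)})
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        out.index.name = "time_days"
        return out

    def to_long_frame(self, markers=REPORT_MARKERS) -> pd.DataFrame:
        """Tidy (patient_id, time_days, marker, value) export."""
        frames = []
        for marker in markers:
            s = self.series(marker)
            long = s.reset_index().melt(id_vars="id", var_name="time_days",
                                        value_name="value")
            long["marker"] = marker
            frames.append(long)
        out = pd.concat(frames, ignore_index=True)
        return out.rename(columns={"id": "patient_id"})[
            ["patient_id", "time_days", "marker", "value"]]


def _profiles_for(regimens, pk_library):
    pk_library = pk_library if pk_library is not None else default_pk_parameters()
    profiles = {}
    resolved = []
    for regimen in regimens:
        reg = resolve_doses(regimen)
        resolved.append(reg)
        if reg.is_empty:
            continue
        if reg.drug not in pk_library:
            raise KeyError(f"no PK parameters for drug {reg.drug!r}")
        profiles[reg.drug] = ConcentrationProfile(pk_library[reg.drug], reg)
    return resolved, profiles


def simulate_arm(population: Cohort, regimens, spec: TrialSpec | None = None,
                 mechanisms=None, pk_library=None,
                 solver: SolverSettings = DEFAULT_SOLVER,
                 name: str = "") -> ArmResult:
    """Simulate one dosing arm over a virtual population.

    ``regimens`` is a list of :class:`~ibdqsp.pk.Regimen` (one per drug; an
    empty list is a placebo arm). Patients whose integration fails are
    flagged and skipped; if more than ``spec.max_failure_fraction`` fail the
    whole arm errors out.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    spec = spec or TrialSpec()
    regimens = [regimens] if isinstance(regimens, Regimen) else list(regimens)
    resolved, profiles = _profiles_for(regimens, pk_library)
    for reg in resolved:
        if not reg.is_empty and max(reg.dose_times()) > spec.horizon_days:
            raise ValueError(f"dose beyond trial horizon in {reg.drug}")
    mechanisms = mechanisms if mechanisms is not None else builtin_mechanisms()
    active = [mechanisms[d] for d in profiles if d in mechanisms]
    ff = make_free_fraction_fn(active, profiles) if active else None
    grid = spec.resolve_grid()
    breakpoints = sorted({t for reg in resolved for t in reg.dose_times()})

    kept_ids, rows, failed = [], [], []
    for patient in population:
        try:
            traj = simulate(patient.parameters, spec.horizon_days, ff,
                            grid=grid, y0=patient.baseline,
                            breakpoints=breakpoints, solver=solver)
        except IntegrationError:
            failed.append(patient.id)
            continue
        kept_ids.append(patient.id)
        rows.append(traj.states)
    if len(failed) > spec.max_failure_fraction * len(population):
        raise ArmSimulationError(
            f"{len(failed)}/{len(population)} integrations failed in arm {name!r}")
    label = name or "+".join(r.drug for r in resolved if not r.is_empty) or "placebo"
    return ArmResult(name=label, ids=np.array(kept_ids), times=grid,
                     values=np.array(rows), failed_ids=tuple(failed),
                     regimens=tuple(resolved))


def simulate_combination(population: Cohort, regimen_A: Regimen,
                         regimen_B: Regimen, spec: TrialSpec | None = None,
                         mechanisms=None, pk_library=None,
                         solver: SolverSettings = DEFAULT_SOLVER,
                         ) -> tuple[ArmResult, ArmResult, ArmResult]:
    """Simulate A alone, B alone, and A+B on the identical population.

    The combination arm applies both drug mechanisms concurrently; if both
    were to hit the same cytokine the free fractions would multiply.
    """
    kw = dict(spec=spec, mechanisms=mechanisms, pk_library=pk_library,
              solver=solver)
    res_a = simulate_arm(population, [regimen_A], name=regimen_A.drug, **kw)
    res_b = simulate_arm(population, [regimen_B], name=regimen_B.drug, **kw)
    res_ab = simulate_arm(population, [regimen_A, regimen_B],
                          name=f"{regimen_A.drug}+{regimen_B.drug}", **kw)
    return res_a, res_b, res_ab


@dataclass(frozen=True)
class ResponseCriterion:
    """Biomarker response definition.

    ``percent_decrease``: responder iff percent reduction from baseline at
    the assessment day is at least (``inclusive``) or strictly above the
    threshold. ``absolute_below``: responder iff the marker normalises below
    the threshold; patients already below it at baseline are excluded.
    """

    marker: str = "CRP"
    kind: str = "percent_decrease"
    threshold: float = 60.0
    assessment_day: float = 42.0
    inclusive: bool = True

    def __post_init__(self):
        if self.marker not in SPECIES:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.kind not in ("percent_decrease", "absolute_below"):
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def label(self) -> str:
        unit = "%" if self.kind == "percent_decrease" else ""
        return f"{self.marker} {self.kind} {self.threshold:g}{unit} @ d{self.assessment_day:g}"


@dataclass(frozen=True)
class ResponderPartition:
    """Both / only-A / only-B / neither counts for two treatments."""

    counts: dict[str, int]
    excluded_at_baseline: int
    criterion: str
    arm_a: str = "A"
    arm_b: str = "B"

    @property
    def n_included(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_included
        return {k: v / n for k, v in self.counts.items()} if n else \
            dict.fromkeys(self.counts, float("nan"))

    def as_dict(self) -> dict:
        return {"counts": dict(self.counts), "fractions": self.fractions,
                "excluded_at_baseline": self.excluded_at_baseline,
                "n_included": self.n_included, "criterion": self.criterion,
                "arm_a": self.arm_a, "arm_b": self.arm_b}


def _responders(result: ArmResult, criterion: ResponseCriterion) -> np.ndarray:
    values = result.value_at(criterion.marker, criterion.assessment_day).values
    base = result.baseline(criterion.marker).values
    if criterion.kind == "percent_decrease":
        decrease = 100.0 * (base - values) / base
        if criterion.inclusive:
            return decrease >= criterion.threshold
        return decrease > criterion.threshold
    return values < criterion.threshold


def classify_responders(results_A: ArmResult, results_B: ArmResult,
                        criterion: ResponseCriterion) -> ResponderPartition:
    """Partition a shared population by response to two treatments."""
    if not np.array_equal(results_A.ids, results_B.ids):
        raise ValueError("responder classification needs identical populations")
    base = results_A.baseline(criterion.marker).values
    if criterion.kind == "absolute_below":
        included = base >= criterion.threshold
    else:
        included = np.ones(len(base), dtype=bool)
    resp_a = _responders(results_A, criterion)[included]
    resp_b = _responders(results_B, criterion)[included]
    counts = {
        "both": int(np.sum(resp_a & resp_b)),
        "only_A": int(np.sum(resp_a & ~resp_b)),
        "only_B": int(np.sum(~resp_a & resp_b)),
        "neither": int(np.sum(~resp_a & ~resp_b)),
    }
    return ResponderPartition(counts=counts,
                              excluded_at_baseline=int(np.sum(~included)),
                              criterion=criterion.label(),
                              arm_a=results_A.name, arm_b=results_B.name)


def placebo_corrected(observed_rate: float, placebo_rate: float) -> float:
    """Placebo-corrected response rate (%): observed minus placebo."""
    for r in (observed_rate, placebo_rate):
        if not 0.0 <= r <= 100.0:
            raise ValueError("rates must be percentages in [0, 100]")
    return observed_rate - placebo_rate
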