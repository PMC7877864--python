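"""Virtual patient populations.

A *plausible patient* is a parameter vector drawn around the nominal model
(log-uniform, ±10-fold on a designated variability subset) whose drug-free
steady state converges and falls inside a physiological plausibility window.
A *trial population* is a subset of a plausible-patient cohort selected so
its baseline CRP and FCP statistics match the summary statistics a clinical
trial reported (median+IQR, mean+SD, or median+range), since trial baselines
differ substantially between studies and patient-level data are unavailable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm

from .dynamics import SolverSettings, DEFAULT_SOLVER, SteadyStateError, steady_state
from .params import ParameterSet, VARIABILITY_SUBSET, nominal_parameters
from .species import CYTOKINES, IDX, SPECIES

__all__ = [
    "VirtualPatient",
    "Cohort",
    "PlausibilityWindow",
    "MarkerTarget",
    "BaselineTargets",
    "generate_cohort",
    "select_trial_population",
    "compare_groups",
    "PriorMisspecificationError",
    "MatchingFailureError",
]

DEFAULT_FOLD_RANGE = 10.0  # log-uniform +/- 10-fold around nominal


class PriorMisspecificationError(RuntimeError):
    """Acceptance rate of the plausibility filters fell below 1%."""


class MatchingFailureError(RuntimeError):
    """No subpopulation matched the baseline targets within tolerance."""

    def __init__(self, message: str, best_stats: dict):
        super().__init__(message)
        self.best_stats = best_stats


@dataclass(frozen=True)
class VirtualPatient:
    """One virtual subject: parameters, variability factors, and baseline."""

    id: int
    parameters: ParameterSet
    baseline: np.ndarray            # steady-state species vector
    factors: dict[str, float] = field(default_factory=dict)

    def baseline_value(self, species: str) -> float:
        return float(self.baseline[IDX[species]])


@dataclass(frozen=True)
class PlausibilityWindow:
    """Physiological bounds a plausible patient's baseline must satisfy."""

    crp: tuple[float, float] = (0.1, 200.0)        # mg/L
    fcp: tuple[float, float] = (10.0, 5000.0)      # mg/kg
    cytokine_max: float = 1e4                      # pg/mL

    def accepts(self, baseline: np.ndarray) -> bool:
        crp = baseline[IDX["CRP"]]
        fcp = baseline[IDX["FCP"]]
        if not (self.crp[0] <= crp <= self.crp[1]):
            return False
        if not (self.fcp[0] <= fcp <= self.fcp[1]):
            return False
        for cyt in CYTOKINES:
            if baseline[IDX[cyt]] >= self.cytokine_max:
                return False
        return bool(np.all(np.isfinite(baseline)) and np.all(baseline >= 0))


@dataclass
class Cohort:
    """An ordered collection of virtual patients with its provenance."""

    patients: list[VirtualPatient]
    seed: int | None = None
    priors: dict[str, tuple[float, float]] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient ids in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def ids(self) -> np.ndarray:
        return np.array([p.id for p in self.patients])

    def baseline_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array([p.baseline for p in self.patients]),
            index=pd.Index(self.ids, name="id"), columns=list(SPECIES))

    def parameter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [p.parameters.as_dict() for p in self.patients],
            index=pd.Index(self.ids, name="id"))

    def baselines(self, species: str) -> np.ndarray:
        return np.array([p.baseline_value(species) for p in self.patients])

    def subset(self, ids) -> "Cohort":
        wanted = set(int(i) for i in ids)
        picked = [p for p in self.patients if p.id in wanted]
        return Cohort(patients=picked, seed=self.seed, priors=self.priors,
                      notes=self.notes + " | subset")

    # ------------------------------------------------------------------ io
    def to_csv(self, csv_path, meta_path=None) -> None:
        base = self.baseline_frame().add_prefix("base_")
        pars = self.parameter_frame().add_prefix("param_")
        facs = pd.DataFrame([p.factors for p in self.patients],
                            index=base.index).add_prefix("factor_").fillna(1.0)
        pd.concat([pars, facs, base], axis=1).to_csv(csv_path)
        if meta_path is not None:
            meta = {"seed": self.seed, "n": len(self),
                    "priors": {k: list(v) for k, v in self.priors.items()},
                    "notes": self.notes}
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, csv_path, meta_path=None) -> "Cohort":
        df = pd.read_csv(csv_path, index_col="id")
        param_cols = [c for c in df.columns if c.startswith("param_")]
        factor_cols = [c for c in df.columns if c.startswith("factor_")]
        patients = []
        for pid, row in df.iterrows():
            params = ParameterSet({c[len("param_"):]: row[c] for c in param_cols})
            baseline = np.array([row[f"base_{s}"] for s in SPECIES])
            factors = {c[len("factor_"):]: row[c] for c in factor_cols}
            patients.append(VirtualPatient(id=int(pid), parameters=params,
                                           baseline=baseline, factors=factors))
        meta = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = json.load(fh)
        return cls(patients=patients, seed=meta.get("seed"),
                   priors={k: tuple(v) for k, v in meta.get("priors", {}).items()},
                   notes=meta.get("notes", ""))


def default_priors(fold: float = DEFAULT_FOLD_RANGE,
                   ) -> dict[str, tuple[float, float]]:
    """Log-uniform multiplicative priors on the variability subset."""
    return {name: (1.0 / fold, fold) for name in VARIABILITY_SUBSET}


def generate_cohort(n: int = 40_000,
                    priors: dict[str, tuple[float, float]] | None = None,
                    seed: int = 0,
                    params: ParameterSet | None = None,
                    window: PlausibilityWindow | None = None,
                    solver: SolverSettings = DEFAULT_SOLVER,
                    probe: int = 200,
                    max_attempt_factor: int = 50) -> Cohort:
    """Sample a plausible-patient database of ``n`` retained subjects.

    Draws multiplicative factors from the log-uniform priors, recomputes each
    candidate's steady state, and keeps those passing the plausibility
    window. Deterministic for a given ``(seed, priors, n)``. If, after a
    probe batch, fewer than 1% of draws are accepted, the priors are deemed
    misspecified and a :class:`PriorMisspecificationError` is raised.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    nominal = params if params is not None else nominal_parameters()
    priors = priors if priors is not None else default_priors()
    window = window if window is not None else PlausibilityWindow()
    names = list(priors)
    los = np.log(np.array([priors[k][0] for k in names]))
    his = np.log(np.array([priors[k][1] for k in names]))
    if np.any(his <= los):
        raise ValueError("prior upper bounds must exceed lower bounds")

    rng = np.random.default_rng(seed)
    patients: list[VirtualPatient] = []
    attempts = 0
    rejected = 0
    max_attempts = max(1000, max_attempt_factor * n)
    while len(patients) < n:
        if attempts >= max_attempts:
            raise PriorMisspecificationError(
                f"exhausted {attempts} draws for {n} patients "
                f"({rejected} rejected)")
        attempts += 1
        factors = dict(zip(names, np.exp(rng.uniform(los, his))))
        candidate = nominal.perturbed(factors)
        try:
            ss = steady_state(candidate, solver=solver)
        except SteadyStateError:
            rejected += 1
        else:
            if window.accepts(ss.values):
                patients.append(VirtualPatient(
                    id=len(patients), parameters=candidate,
                    baseline=ss.values, factors=factors))
            else:
                rejected += 1
        if attempts == max(probe, 1) and len(patients) < 0.01 * attempts:
            raise PriorMisspecificationError(
                f"acceptance rate {len(patients)}/{attempts} below 1% "
                "in probe batch; check priors and plausibility window")
    return Cohort(patients=patients, seed=seed,
                  priors={k: tuple(v) for k, v in priors.items()},
                  notes=f"generated n={n}, attempts={attempts}")


# --------------------------------------------------------------------------
# baseline-statistic targets and trial-population selection
# --------------------------------------------------------------------------

_STAT_KINDS = ("median_iqr", "mean_sd", "median_range")


@dataclass(frozen=True)
class MarkerTarget:
    """Target summary statistic for one baseline marker.

    ``kind`` is one of ``median_iqr`` (dispersion = (q25, q75)), ``mean_sd``
    (dispersion = (sd,)), ``median_range`` (dispersion = (min, max)).
    """

    kind: str
    central: float
    dispersion: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in _STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.central <= 0 or any(d <= 0 for d in self.dispersion):
            raise ValueError("targets must be positive")
        if self.kind == "median_iqr" and not (
                self.dispersion[0] <= self.central <= self.dispersion[1]):
            raise ValueError("IQR must bracket the median")
        if self.kind == "median_range" and not (
                self.dispersion[0] <= self.central <= self.dispersion[1]):
            raise ValueError("range must bracket the median")

    def lognormal_moments(self) -> tuple[float, float]:
        """(mu, sigma) of a lognormal consistent with this summary."""
        if self.kind == "median_iqr":
            q25, q75 = self.dispersion
            return np.log(self.central), np.log(q75 / q25) / (2 * norm.ppf(0.75))
        if self.kind == "mean_sd":
            sd, = self.dispersion
            s2 = np.log1p((sd / self.central) ** 2)
            return np.log(self.central) - s2 / 2, np.sqrt(s2)
        lo, hi = self.dispersion  # median_range: range ~ +/- 2.5 sigma
        return np.log(self.central), np.log(hi / lo) / 5.0

    def achieved(self, values: np.ndarray) -> "MarkerTarget":
        return achieved_statistic(values, self.kind)

    def matches(self, values: np.ndarray, tolerance: float) -> bool:
        got = self.achieved(values)
        if abs(got.central - self.central) > tolerance * self.central:
            return False
        scale_tol = 5.0 if self.kind == "median_range" else 3.0
        width = _dispersion_scale(self)
        got_width = _dispersion_scale(got)
        return abs(got_width - width) <= scale_tol * tolerance * width


def _dispersion_scale(t: MarkerTarget) -> float:
    if t.kind == "median_iqr":
        return t.dispersion[1] - t.dispersion[0]
    if t.kind == "mean_sd":
        return t.dispersion[0]
    return t.dispersion[1] - t.dispersion[0]


def achieved_statistic(values: np.ndarray, kind: str) -> MarkerTarget:
    """Recompute a summary of the stated kind directly from sample values."""
    values = np.asarray(values, dtype=float)
    if kind == "median_iqr":
        q25, med, q75 = np.percentile(values, [25, 50, 75])
        return MarkerTarget(kind, med, (q25, q75))
    if kind == "mean_sd":
        return MarkerTarget(kind, float(np.mean(values)),
                            (float(np.std(values, ddof=1)),))
    if kind == "median_range":
        return MarkerTarget(kind, float(np.median(values)),
                            (float(np.min(values)), float(np.max(values))))
    raise ValueError(f"unknown statistic kind {kind!r}")


@dataclass(frozen=True)
class BaselineTargets:
    """Per-marker baseline statistics a trial population must reproduce."""

    crp: MarkerTarget
    fcp: MarkerTarget
    tolerance: float = 0.15   # relative, on the central statistic

    def __post_init__(self):
        if not 0 < self.tolerance <= 0.5:
            raise ValueError("tolerance must be in (0, 0.5]")

    def as_dict(self) -> dict:
        return {
            "CRP": {"kind": self.crp.kind, "central": self.crp.central,
                    "dispersion": list(self.crp.dispersion)},
            "FCP": {"kind": self.fcp.kind, "central": self.fcp.central,
                    "dispersion": list(self.fcp.dispersion)},
            "tolerance": self.tolerance,
        }


def select_trial_population(cohort: Cohort, targets: BaselineTargets,
                            n_out: int, seed: int = 0,
                            max_iter: int = 60) -> Cohort:
    """Select a subpopulation whose baseline CRP/FCP match the trial targets.

    Importance-weighted sampling without replacement toward the target
    lognormal marginals of log-CRP and log-FCP (weights = target density over
    a KDE estimate of the cohort's own density), followed by an
    accept/reject check on the joint achieved statistics. The CRP-FCP
    correlation is left as induced by the shared mechanism. Deterministic
    given ``seed``.
    """
    if n_out >= len(cohort):
        raise ValueError("cohort must be larger than the requested population")
    rng = np.random.default_rng(seed)
    log_crp = np.log(cohort.baselines("CRP"))
    log_fcp = np.log(cohort.baselines("FCP"))
    ids = cohort.ids

    logw = np.zeros(len(cohort))
    for values, marker in ((log_crp, targets.crp), (log_fcp, targets.fcp)):
        mu, sigma = marker.lognormal_moments()
        sigma = max(sigma, 1e-3)
        kde = gaussian_kde(values)
        dens = np.maximum(kde(values), 1e-12)
        logw += norm.logpdf(values, mu, sigma) - np.log(dens)

    best_err = np.inf
    best_stats: dict = {}
    temperatures = [1.0, 0.7, 1.4, 0.5, 2.0, 0.35, 1.0, 0.85, 1.2, 0.6]
    for it in range(max_iter):
        tau = temperatures[it % len(temperatures)]
        w = np.exp(tau * (logw - logw.max()))
        prob = w / w.sum()
        chosen = rng.choice(len(cohort), size=n_out, replace=False, p=prob)
        crp_vals = np.exp(log_crp[chosen])
        fcp_vals = np.exp(log_fcp[chosen])
        ok = (targets.crp.matches(crp_vals, targets.tolerance)
              and targets.fcp.matches(fcp_vals, targets.tolerance))
        err = (abs(achieved_statistic(crp_vals, targets.crp.kind).central
                   - targets.crp.central) / targets.crp.central
               + abs(achieved_statistic(fcp_vals, targets.fcp.kind).central
                     - targets.fcp.central) / targets.fcp.central)
        if err < best_err:
            best_err = err
            best_stats = {
                "CRP": achieved_statistic(crp_vals, targets.crp.kind),
                "FCP": achieved_statistic(fcp_vals, targets.fcp.kind),
            }
        if ok:
            sub = cohort.subset(ids[chosen])
            sub.notes += f" | matched seed={seed} iter={it}"
            return sub
    raise MatchingFailureError(
        f"no subpopulation within tolerance after {max_iter} iterations; "
        f"best achieved: {best_stats}", best_stats)


def compare_groups(cohort: Cohort, grouping) -> pd.DataFrame:
    """Per-group median and IQR of every baseline species and parameter.

    ``grouping`` maps patient id -> label (dict or Series). Empty groups are
    flagged with ``n = 0`` rows rather than raising.
    """
    labels = (grouping if isinstance(grouping, pd.Series)
              else pd.Series(dict(grouping)))
    missing = set(cohort.ids) - set(labels.index)
    if missing:
        raise ValueError(f"patients without a group label: {sorted(missing)[:5]}")
    base = cohort.baseline_frame()
    pars = cohort.parameter_frame()
    wide = pd.concat([base, pars.add_prefix("param:")], axis=1)
    wide["group"] = labels.reindex(wide.index)

    if isinstance(labels.dtype, pd.CategoricalDtype):
        groups = list(labels.cat.categories)  # unused categories -> flagged empty
    else:
        groups = list(pd.unique(labels))
    rows = []
    for group in groups:
        sub = wide[wide["group"] == group].drop(columns="group")
        if len(sub) == 0:
            rows.append(pd.DataFrame(
                {"group": group, "quantity": list(wide.columns[:-1]),
                 "n": 0, "median": np.nan, "q25": np.nan, "q75": np.nan}))
            continue
        q = sub.quantile([0.25, 0.5, 0.75])
        rows.append(pd.DataFrame({
            "group": group, "quantity": sub.columns, "n": len(sub),
            "median": q.loc[0.5].values, "q25": q.loc[0.25].values,
            "q75": q.loc[0.75].values}))
    return pd.concat(rows, ignore_index=True).set_index(["group", "quantity"])
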