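"""Synthetic trial reports and the library of printed regimens/criteria.

Clinical inputs to this framework are *summary statistics* printed in trial
reports, never patient-level data. This module fabricates such reports with
known ground truth — lognormal baseline CRP/FCP distributions summarised in
each trial's preferred style (median+IQR, mean+SD, or median+range) and
longitudinal marker summaries following a prescribed suppression curve plus
seeded sampling noise — so that selection, simulation, classification and
calibration are all testable end-to-end without any external data. All
fixtures carry ``provenance="synthetic"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import BaselineTargets, MarkerTarget, achieved_statistic
from .pk import DoseEvent, Regimen
from .trial import ResponseCriterion

__all__ = [
    "TrialReportFixture",
    "make_trial_fixture",
    "make_paper_defaults",
    "baseline_targets_from_fixture",
    "DEFAULT_BASELINE_LAW",
]

#: default lognormal baseline laws: (median, geometric SD); chosen to sit in
#: the middle of the baseline ranges reported across CD induction trials
DEFAULT_BASELINE_LAW: dict[str, tuple[float, float]] = {
    "CRP": (10.0, 2.5),    # mg/L
    "FCP": (600.0, 2.5),   # mg/kg
}


@dataclass(frozen=True)
class TrialReportFixture:
    """A fully synthetic stand-in for one trial's published summaries."""

    name: str
    arms: dict[str, int]                       # arm -> n
    baseline: dict[str, MarkerTarget]          # marker -> summary
    longitudinal: pd.DataFrame                 # arm, marker, day, statistic,
                                               # value, dispersion
    seed: int
    provenance: str = "synthetic"

    def __post_init__(self):
        for marker, summary in self.baseline.items():
            if summary.kind == "mean_sd" and summary.dispersion[0] < 0:
                raise ValueError(f"negative SD for {marker}")


def make_trial_fixture(seed: int, n_per_arm: int = 60,
                       baseline_law: dict[str, tuple[float, float]] | None = None,
                       effect_profile: dict[str, dict[float, float]] | None = None,
                       stat_kind: str | dict[str, str] = "median_iqr",
                       noise_frac: float = 0.05,
                       name: str = "synthetic-trial") -> TrialReportFixture:
    """Generate a synthetic trial report with known ground truth.

    ``baseline_law`` maps marker -> (median, geometric SD) of a lognormal;
    ``effect_profile`` maps arm -> {day: fractional suppression in [0, 1]};
    the longitudinal "observed" values are the suppressed baseline medians
    with multiplicative Gaussian noise of relative size ``noise_frac``.
    Identical seeds regenerate identical fixtures.
    """
    rng = np.random.default_rng(seed)
    law = baseline_law or DEFAULT_BASELINE_LAW
    effect_profile = effect_profile or {"treatment": {0.0: 0.0, 42.0: 0.5}}
    kinds = ({m: stat_kind for m in law} if isinstance(stat_kind, str)
             else dict(stat_kind))

    baseline: dict[str, MarkerTarget] = {}
    for marker, (median, gsd) in law.items():
        if median <= 0 or gsd <= 1:
            raise ValueError("lognormal law needs median > 0 and gsd > 1")
        draws = np.exp(rng.normal(np.log(median), np.log(gsd),
                                  size=max(n_per_arm, 2)))
        baseline[marker] = achieved_statistic(draws, kinds[marker])

    rows = []
    for arm, curve in effect_profile.items():
        for day, suppression in sorted(curve.items()):
            if not 0.0 <= suppression <= 1.0:
                raise ValueError("suppression must lie in [0, 1]")
            for marker, (median, _) in law.items():
                true_value = median * (1.0 - suppression)
                noise = rng.normal(0.0, noise_frac * max(true_value, 1e-9))
                value = max(true_value + noise, 0.0)
                rows.append({
                    "arm": arm, "marker": marker, "day": day,
                    "statistic": kinds[marker], "value": value,
                    "dispersion": 0.4 * value,
                })
    longitudinal = pd.DataFrame(rows)
    return TrialReportFixture(name=name,
                              arms={arm: n_per_arm for arm in effect_profile},
                              baseline=baseline, longitudinal=longitudinal,
                              seed=seed)


def baseline_targets_from_fixture(fixture: TrialReportFixture,
                                  tolerance: float = 0.15) -> BaselineTargets:
    """Turn a synthetic report's baseline summaries into matching targets."""
    return BaselineTargets(crp=fixture.baseline["CRP"],
                           fcp=fixture.baseline["FCP"], tolerance=tolerance)


def _iv(day, mg=None, mg_per_kg=None):
    return DoseEvent(time=day, amount=mg, amount_per_kg=mg_per_kg, route="iv")


def _sc(day, mg):
    return DoseEvent(time=day, amount=mg, route="sc")


def make_paper_defaults() -> dict:
    """The printed induction regimens and responder criteria.

    Regimens (all at the 70 kg standard body weight):

    * ustekinumab: single IV dose, 130 mg or 6 mg/kg (420 mg), week 0;
    * brazikumab: 700 mg IV weeks 0 and 4, then 210 mg SC every 4 weeks
      after week 12;
    * risankizumab: 200 or 600 mg IV at weeks 0, 4 and 8;
    * infliximab: 5 mg/kg IV at weeks 0, 2 and 6 (CRP/cytokine study) or
      weeks 0 and 8 (FCP study);
    * PF-04236921 (anti-IL-6): 10, 50 or 200 mg SC on days 1 and 28.

    Criteria: >=60% CRP decrease at week 6; normalised CRP below 3 mg/L or
    5 mg/L at week 6 (patients under the cutoff at baseline excluded);
    normalised FCP below 250 mg/kg at week 6.
    """
    regimens = {
        "ustekinumab_130mg": Regimen("ustekinumab", (_iv(0.0, mg=130.0),)),
        "ustekinumab_6mgkg": Regimen("ustekinumab", (_iv(0.0, mg_per_kg=6.0),)),
        "brazikumab": Regimen("brazikumab", (
            _iv(0.0, mg=700.0), _iv(28.0, mg=700.0),
            _sc(84.0, 210.0), _sc(112.0, 210.0))),
        "risankizumab_200mg": Regimen("risankizumab", tuple(
            _iv(d, mg=200.0) for d in (0.0, 28.0, 56.0))),
        "risankizumab_600mg": Regimen("risankizumab", tuple(
            _iv(d, mg=600.0) for d in (0.0, 28.0, 56.0))),
        "infliximab_induction": Regimen("infliximab", tuple(
            _iv(d, mg_per_kg=5.0) for d in (0.0, 14.0, 42.0))),
        "infliximab_fcp": Regimen("infliximab", (
            _iv(0.0, mg_per_kg=5.0), _iv(56.0, mg_per_kg=5.0))),
        "pf04236921_10mg": Regimen("PF-04236921", (_sc(1.0, 10.0), _sc(28.0, 10.0))),
        "pf04236921_50mg": Regimen("PF-04236921", (_sc(1.0, 50.0), _sc(28.0, 50.0))),
        "pf04236921_200mg": Regimen("PF-04236921", (_sc(1.0, 200.0), _sc(28.0, 200.0))),
    }
    criteria = {
        "crp_60pct_decrease": ResponseCriterion(
            marker="CRP", kind="percent_decrease", threshold=60.0),
        "crp_below_3": ResponseCriterion(
            marker="CRP", kind="absolute_below", threshold=3.0),
        "crp_below_5": ResponseCriterion(
            marker="CRP", kind="absolute_below", threshold=5.0),
        "fcp_below_250": ResponseCriterion(
            marker="FCP", kind="absolute_below", threshold=250.0),
    }
    return {"regimens": regimens, "criteria": criteria,
            "baseline_laws": dict(DEFAULT_BASELINE_LAW),
            "provenance": "synthetic defaults encoding printed schedules"}
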