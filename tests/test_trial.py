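"""Arm simulation, biomarker summaries, and responder classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ibdqsp.pk import DoseEvent, Regimen
from ibdqsp.trial import (ArmResult, ResponderPartition, ResponseCriterion,
                          TrialSpec, classify_responders, placebo_corrected,
                          simulate_arm, simulate_combination)

WEEKLY = TrialSpec(horizon_days=84.0,
                   grid=np.arange(0.0, 85.0, 7.0))


@pytest.fixture(scope="module")
def tiny_pop(small_cohort):
    return small_cohort.subset(small_cohort.ids[:12])


@pytest.fixture(scope="module")
def inf_vs_ust(tiny_pop, paper_defaults):
    regs = paper_defaults["regimens"]
    res_a = simulate_arm(tiny_pop, [regs["infliximab_induction"]], spec=WEEKLY)
    res_b = simulate_arm(tiny_pop, [regs["ustekinumab_6mgkg"]], spec=WEEKLY)
    return res_a, res_b


class TestArmSimulation:
    def test_placebo_arm_stays_at_baseline(self, tiny_pop):
        res = simulate_arm(tiny_pop, [], spec=WEEKLY, name="placebo")
        for patient in tiny_pop:
            series = res.series("CRP").loc[patient.id]
            assert np.allclose(series, patient.baseline_value("CRP"),
                               rtol=1e-4)

    def test_deterministic_given_population_and_regimen(self, tiny_pop,
                                                        paper_defaults):
        reg = paper_defaults["regimens"]["infliximab_induction"]
        r1 = simulate_arm(tiny_pop, [reg], spec=WEEKLY)
        r2 = simulate_arm(tiny_pop, [reg], spec=WEEKLY)
        assert np.array_equal(r1.values, r2.values)

    def test_identical_parameters_identical_response(self, small_cohort,
                                                     paper_defaults):
        """All subjects share one PK profile, so two patients with the same
        mechanistic parameters respond identically."""
        from ibdqsp.population import Cohort, VirtualPatient

        p = small_cohort.patients[0]
        clone = VirtualPatient(id=999_999, parameters=p.parameters,
                               baseline=p.baseline, factors=p.factors)
        pop = Cohort(patients=[p, clone])
        reg = paper_defaults["regimens"]["infliximab_induction"]
        res = simulate_arm(pop, [reg], spec=WEEKLY)
        assert np.allclose(res.values[0], res.values[1], rtol=1e-9)

    def test_summary_median_matches_independent_recomputation(self,
                                                              inf_vs_ust):
        res, _ = inf_vs_ust
        summary = res.summary("CRP", "median_iqr")
        raw = res.series("CRP").values
        assert np.allclose(summary["median"].values,
                           np.median(raw, axis=0), rtol=1e-12)
        assert np.allclose(summary["q25"].values,
                           np.quantile(raw, 0.25, axis=0), rtol=1e-12)

    def test_all_summary_kinds_recomputable(self, inf_vs_ust):
        res, _ = inf_vs_ust
        raw = res.percent_change("FCP").values
        mean_sd = res.summary("FCP", "mean_sd", "percent_change")
        assert np.allclose(mean_sd["mean"].values, raw.mean(axis=0))
        rng_summary = res.summary("FCP", "median_range", "percent_change")
        assert np.allclose(rng_summary["min"].values, raw.min(axis=0))

    def test_long_format_round_trip(self, inf_vs_ust):
        res, _ = inf_vs_ust
        long = res.to_long_frame(markers=("CRP",))
        wide = long.pivot(index="patient_id", columns="time_days",
                          values="value")
        assert np.allclose(wide.loc[res.ids].values,
                           res.series("CRP").values)

    def test_dose_beyond_horizon_rejected(self, tiny_pop):
        reg = Regimen("infliximab", (DoseEvent(90.0, amount=100.0),))
        with pytest.raises(ValueError):
            simulate_arm(tiny_pop, [reg], spec=WEEKLY)

    def test_anti_il6_dose_response_is_ordered(self, tiny_pop,
                                               paper_defaults):
        """CRP suppression deepens with dose: 200 <= 50 <= 10 mg curves."""
        regs = paper_defaults["regimens"]
        finals = {}
        for dose in (10, 50, 200):
            res = simulate_arm(tiny_pop, [regs[f"pf04236921_{dose}mg"]],
                               spec=WEEKLY)
            finals[dose] = res.percent_change("CRP").iloc[:, -1].median()
        assert finals[200] <= finals[50] <= finals[10] < 0


class TestCombination:
    def test_empty_regimen_is_neutral_element(self, tiny_pop, paper_defaults):
        reg = paper_defaults["regimens"]["infliximab_induction"]
        placebo = Regimen("ustekinumab", ())
        res_a, _, res_ab = simulate_combination(tiny_pop, reg, placebo,
                                                spec=WEEKLY)
        assert np.allclose(res_a.values, res_ab.values, rtol=1e-10)

    def test_combination_dominates_monotherapies(self, tiny_pop,
                                                 paper_defaults):
        regs = paper_defaults["regimens"]
        res_a, res_b, res_ab = simulate_combination(
            tiny_pop, regs["infliximab_induction"],
            regs["ustekinumab_6mgkg"], spec=WEEKLY)
        final = {r.name: r.series("CRP").iloc[:, -1] for r in
                 (res_a, res_b, res_ab)}
        combo = final[res_ab.name]
        assert combo.median() <= min(final[res_a.name].median(),
                                     final[res_b.name].median())
        dominance = ((combo <= final[res_a.name] + 1e-9)
                     & (combo <= final[res_b.name] + 1e-9)).mean()
        assert dominance >= 0.95


class TestResponderClassification:
    @staticmethod
    def _fake_arm(name, ids, baselines, finals, day=42.0):
        times = np.array([0.0, day])
        n = len(ids)
        values = np.zeros((n, 2, 22))
        from ibdqsp.species import IDX

        values[:, 0, IDX["CRP"]] = baselines
        values[:, 1, IDX["CRP"]] = finals
        return ArmResult(name=name, ids=np.asarray(ids), times=times,
                         values=values)

    def test_sixty_five_percent_decrease_is_responder_at_60(self):
        arm_a = self._fake_arm("A", [0], [10.0], [3.5])
        arm_b = self._fake_arm("B", [0], [10.0], [9.0])
        part = classify_responders(arm_a, arm_b, ResponseCriterion())
        assert part.counts == {"both": 0, "only_A": 1, "only_B": 0,
                               "neither": 0}

    def test_low_baseline_excluded_under_absolute_criterion(self):
        crit = ResponseCriterion(kind="absolute_below", threshold=3.0)
        arm_a = self._fake_arm("A", [0, 1], [2.0, 10.0], [1.0, 2.5])
        arm_b = self._fake_arm("B", [0, 1], [2.0, 10.0], [1.5, 8.0])
        part = classify_responders(arm_a, arm_b, crit)
        assert part.excluded_at_baseline == 1
        assert part.n_included == 1
        assert part.counts["only_A"] == 1

    def test_partition_conserves_population(self):
        """1,000 random synthetic outcomes: counts conserve the population
        and fractions sum to one."""
        rng = np.random.default_rng(0)
        n = 1000
        ids = np.arange(n)
        baselines = np.exp(rng.normal(np.log(8.0), 1.0, n))
        arm_a = self._fake_arm("A", ids, baselines,
                               baselines * rng.uniform(0.05, 1.2, n))
        arm_b = self._fake_arm("B", ids, baselines,
                               baselines * rng.uniform(0.05, 1.2, n))
        for crit in (ResponseCriterion(),
                     ResponseCriterion(kind="absolute_below", threshold=3.0)):
            part = classify_responders(arm_a, arm_b, crit)
            assert part.n_included + part.excluded_at_baseline == n
            assert sum(part.fractions.values()) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_percent_criterion_scale_invariant_absolute_not(self):
        rng = np.random.default_rng(1)
        n = 200
        ids = np.arange(n)
        baselines = np.exp(rng.normal(np.log(8.0), 1.0, n))
        ratios = rng.uniform(0.1, 1.1, n)
        scale = 7.3

        def parts(factor):
            arm_a = self._fake_arm("A", ids, baselines * factor,
                                   baselines * ratios * factor)
            arm_b = self._fake_arm("B", ids, baselines * factor,
                                   baselines * 0.9 * factor)
            pct = classify_responders(arm_a, arm_b, ResponseCriterion())
            absolute = classify_responders(
                arm_a, arm_b,
                ResponseCriterion(kind="absolute_below", threshold=3.0))
            return pct.counts, absolute.counts

        pct_1, abs_1 = parts(1.0)
        pct_s, abs_s = parts(scale)
        assert pct_1 == pct_s
        assert abs_1 != abs_s

    def test_mismatched_populations_rejected(self):
        arm_a = self._fake_arm("A", [0, 1], [10.0, 10.0], [5.0, 5.0])
        arm_b = self._fake_arm("B", [0, 2], [10.0, 10.0], [5.0, 5.0])
        with pytest.raises(ValueError):
            classify_responders(arm_a, arm_b, ResponseCriterion())


class TestPlaceboCorrection:
    @pytest.mark.parametrize("observed,placebo,expected", [
        (30.4, 15.7, 14.7),   # FCP normalisation example
        (30.9, 5.6, 25.3),    # CRP normalisation example
        (42.0, 0.0, 42.0),
    ])
    def test_difference(self, observed, placebo, expected):
        assert placebo_corrected(observed, placebo) == pytest.approx(expected)

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            placebo_corrected(105.0, 10.0)


class TestPlotting:
    def test_summary_plot_renders_all_arms(self, inf_vs_ust):
        from ibdqsp.plotting import plot_arm_summaries

        res_a, res_b = inf_vs_ust
        ax = plot_arm_summaries([res_a, res_b], "CRP", "percent_change")
        assert len(ax.lines) == 2
        assert "CRP" in ax.get_ylabel()
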