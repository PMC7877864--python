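"""Virtual population generation, plausibility filtering, and trial matching."""

from __future__ import annotations

import numpy as np
import pytest

from ibdqsp.population import (BaselineTargets, Cohort, MarkerTarget,
                               MatchingFailureError, PlausibilityWindow,
                               achieved_statistic, compare_groups,
                               generate_cohort, select_trial_population)
from ibdqsp.species import CYTOKINES, IDX


class TestGeneration:
    def test_same_seed_reproduces_cohort_bitwise(self):
        a = generate_cohort(n=12, seed=3)
        b = generate_cohort(n=12, seed=3)
        assert len(a) == len(b) == 12
        for pa, pb in zip(a, b):
            assert pa.id == pb.id
            assert pa.parameters == pb.parameters
            assert np.array_equal(pa.baseline, pb.baseline)

    def test_different_seed_differs(self):
        a = generate_cohort(n=6, seed=3)
        b = generate_cohort(n=6, seed=4)
        assert not np.array_equal(a.patients[0].baseline,
                                  b.patients[0].baseline)

    def test_all_retained_baselines_inside_window(self, small_cohort):
        """Direct scan of every retained patient against the filters."""
        window = PlausibilityWindow()
        for patient in small_cohort:
            crp = patient.baseline_value("CRP")
            fcp = patient.baseline_value("FCP")
            assert window.crp[0] <= crp <= window.crp[1]
            assert window.fcp[0] <= fcp <= window.fcp[1]
            for cyt in CYTOKINES:
                assert patient.baseline[IDX[cyt]] < window.cytokine_max

    def test_ids_unique_and_contiguous(self, small_cohort):
        ids = small_cohort.ids
        assert len(set(ids)) == len(ids)

    def test_csv_round_trip(self, small_cohort, tmp_path):
        csv = tmp_path / "cohort.csv"
        meta = tmp_path / "cohort.meta.json"
        small_cohort.to_csv(csv, meta)
        loaded = Cohort.from_csv(csv, meta)
        assert loaded.seed == small_cohort.seed
        assert np.allclose(loaded.baseline_frame().values,
                           small_cohort.baseline_frame().values, rtol=1e-12)
        p0, q0 = small_cohort.patients[0], loaded.patients[0]
        assert q0.parameters.as_dict() == pytest.approx(p0.parameters.as_dict())


class TestSelection:
    def test_self_match_succeeds(self, fabricated_cohort):
        """Targets set to the cohort's own statistics must be matchable."""
        crp = fabricated_cohort.baselines("CRP")
        fcp = fabricated_cohort.baselines("FCP")
        targets = BaselineTargets(
            crp=achieved_statistic(crp, "median_iqr"),
            fcp=achieved_statistic(fcp, "median_iqr"), tolerance=0.10)
        sub = select_trial_population(fabricated_cohort, targets, 300, seed=0)
        assert len(sub) == 300
        got = achieved_statistic(sub.baselines("CRP"), "median_iqr")
        assert got.central == pytest.approx(targets.crp.central, rel=0.10)

    def test_known_lognormal_median_recovered_within_5pct(self,
                                                          fabricated_cohort):
        """5000 fabricated patients with lognormal CRP (median 10): selecting
        against that known law recovers the median within 5%."""
        targets = BaselineTargets(
            crp=MarkerTarget("median_iqr", 10.0,
                             (10.0 / 2.5 ** 0.6745, 10.0 * 2.5 ** 0.6745)),
            fcp=MarkerTarget("median_iqr", 600.0,
                             (600.0 / 2.0, 600.0 * 2.0)),
            tolerance=0.05)
        sub = select_trial_population(fabricated_cohort, targets, 250, seed=1)
        assert np.median(sub.baselines("CRP")) == pytest.approx(10.0, rel=0.05)

    def test_output_is_subset_by_id(self, fabricated_cohort):
        crp = fabricated_cohort.baselines("CRP")
        targets = BaselineTargets(
            crp=achieved_statistic(crp, "mean_sd"),
            fcp=achieved_statistic(fabricated_cohort.baselines("FCP"),
                                   "mean_sd"),
            tolerance=0.2)
        sub = select_trial_population(fabricated_cohort, targets, 100, seed=2)
        assert set(sub.ids) <= set(fabricated_cohort.ids)
        originals = {p.id: p for p in fabricated_cohort}
        for p in sub:
            assert np.array_equal(p.baseline, originals[p.id].baseline)

    def test_per_trial_targets_give_different_populations(self,
                                                          fabricated_cohort):
        """Different trials report different baselines; matching each gives
        distinct populations from the same database."""
        low = BaselineTargets(
            crp=MarkerTarget("median_iqr", 6.0, (3.0, 12.0)),
            fcp=MarkerTarget("median_iqr", 450.0, (250.0, 900.0)),
            tolerance=0.15)
        high = BaselineTargets(
            crp=MarkerTarget("median_iqr", 18.0, (9.0, 36.0)),
            fcp=MarkerTarget("median_iqr", 900.0, (500.0, 1800.0)),
            tolerance=0.15)
        sub_low = select_trial_population(fabricated_cohort, low, 200, seed=3)
        sub_high = select_trial_population(fabricated_cohort, high, 200, seed=3)
        assert np.median(sub_high.baselines("CRP")) \
            > 2.0 * np.median(sub_low.baselines("CRP"))

    def test_impossible_target_reports_best_achieved(self, fabricated_cohort):
        targets = BaselineTargets(
            crp=MarkerTarget("median_iqr", 190.0, (150.0, 199.0)),
            fcp=MarkerTarget("median_iqr", 600.0, (300.0, 1200.0)),
            tolerance=0.05)
        with pytest.raises(MatchingFailureError) as err:
            select_trial_population(fabricated_cohort, targets, 200, seed=0,
                                    max_iter=8)
        assert "CRP" in err.value.best_stats

    def test_population_must_be_smaller_than_cohort(self, fabricated_cohort):
        targets = BaselineTargets(
            crp=MarkerTarget("median_iqr", 10.0, (5.0, 20.0)),
            fcp=MarkerTarget("median_iqr", 600.0, (300.0, 1200.0)))
        with pytest.raises(ValueError):
            select_trial_population(fabricated_cohort, targets,
                                    len(fabricated_cohort), seed=0)


class TestGroupComparison:
    def test_identical_groups_have_identical_summaries(self, small_cohort):
        labels = {pid: "A" if i % 2 == 0 else "B"
                  for i, pid in enumerate(small_cohort.ids)}
        # force identical membership stats by comparing a group with itself
        df = compare_groups(small_cohort, {pid: "all" for pid in small_cohort.ids})
        again = compare_groups(small_cohort, {pid: "all" for pid in small_cohort.ids})
        assert df.equals(again)
        assert compare_groups(small_cohort, labels).loc["A"].shape == \
            compare_groups(small_cohort, labels).loc["B"].shape

    def test_doubled_tnf_group_shows_ratio_two(self, small_cohort):
        """Construct group A with exactly doubled TNFα baselines; the group
        summary must report (close to) a 2x median ratio."""
        doubled = []
        for p in small_cohort:
            baseline = p.baseline.copy()
            baseline[IDX["TNFa"]] *= 2.0
            doubled.append(type(p)(id=p.id + 10_000, parameters=p.parameters,
                                   baseline=baseline, factors=p.factors))
        merged = Cohort(patients=list(small_cohort.patients) + doubled)
        labels = {p.id: ("A" if p.id >= 10_000 else "B") for p in merged}
        df = compare_groups(merged, labels)
        ratio = df.loc[("A", "TNFa"), "median"] / df.loc[("B", "TNFa"), "median"]
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_empty_group_flagged_not_error(self, small_cohort):
        import pandas as pd

        labels = pd.Series({pid: "present" for pid in small_cohort.ids},
                           dtype=pd.CategoricalDtype(["present", "absent"]))
        df = compare_groups(small_cohort, labels)
        assert (df.loc["present", "n"] > 0).all()
        assert (df.loc["absent", "n"] == 0).all()
        assert df.loc["absent", "median"].isna().all()

    def test_unlabeled_patient_rejected(self, small_cohort):
        labels = {pid: "x" for pid in small_cohort.ids[:-1]}
        with pytest.raises(ValueError):
            compare_groups(small_cohort, labels)
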