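"""Risk strata, reclassification tables and the ORI/NRI statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pneumorisk import (
    Cohort,
    ReclassificationAnalysis,
    ReclassificationTable,
    RiskGroup,
    RiskThresholds,
    assign_risk_group,
    build_reclassification_table,
    decisive_fraction,
    overall_reclassification_improvement,
    predict_probability,
    published_clinical_model,
    published_crp_model,
    stratify_cohort,
    upclassified_intermediate_summary,
)
from pneumorisk._round import pct

LOW, INT, HIGH = RiskGroup.LOW, RiskGroup.INTERMEDIATE, RiskGroup.HIGH


class TestAssignRiskGroup:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.01107, LOW),       # clinical model, no symptoms
            (0.3100, HIGH),       # clinical model, both symptoms
            (0.025, INT),         # boundaries belong to intermediate
            (0.20, INT),
            (0.0, LOW),
            (1.0, HIGH),
        ],
    )
    def test_default_thresholds(self, p, expected):
        assert assign_risk_group(p) is expected

    def test_probability_outside_unit_interval_rejected(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                assign_risk_group(bad)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            RiskThresholds(low_upper=0.5, high_lower=0.2)

    @given(st.floats(0, 1))
    def test_total_order(self, p):
        g = assign_risk_group(p)
        assert g in (LOW, INT, HIGH)
        if g is LOW:
            assert p < 0.025
        elif g is HIGH:
            assert p > 0.20


class TestStratifyCohort:
    def test_fixture_crp_model_prevalences(self, fixture):
        strat = stratify_cohort(fixture, published_crp_model())
        assert strat.group_sizes == {LOW: 49, INT: 125, HIGH: 68}
        assert strat.events_per_group == {LOW: 0, INT: 8, HIGH: 22}
        prev = strat.prevalence
        assert pct(prev[LOW], 1) == 0.0
        assert pct(prev[INT], 1) == 6.4
        assert pct(prev[HIGH], 1) == 32.4

    def test_fixture_clinical_model_low_share(self, fixture):
        strat = stratify_cohort(
            fixture, published_clinical_model(),
            extra_complete_fields=["crp_mg_per_l"],
        )
        assert strat.n_total == 242
        share = strat.group_sizes[LOW] / strat.n_total
        assert pct(share) == 21
        assert strat.events_per_group[LOW] == 0

    def test_single_patient_low(self):
        c = Cohort.from_records(
            [dict(patient_id="a", consolidation=0,
                  runny_nose_absent=0, feels_ill=0, crp_mg_per_l=5.0)]
        )
        strat = stratify_cohort(c, published_crp_model())
        assert strat.group_sizes == {LOW: 1, INT: 0, HIGH: 0}

    def test_no_complete_cases_raises(self):
        c = Cohort.from_records([dict(patient_id="a", consolidation=0)])
        with pytest.raises(ValueError):
            stratify_cohort(c, published_clinical_model())


class TestDecisiveFraction:
    def test_fixture_value(self, reclass_results):
        assert reclass_results.decisive_fraction_new == pytest.approx(117 / 242)
        assert pct(reclass_results.decisive_fraction_new) == 48

    def test_degenerate_distributions(self, fixture):
        strat = stratify_cohort(fixture, published_crp_model())
        strat.group_sizes = {LOW: 0, INT: 10, HIGH: 0}
        assert decisive_fraction(strat) == 0.0
        strat.group_sizes = {LOW: 4, INT: 0, HIGH: 6}
        assert decisive_fraction(strat) == 1.0


class TestReclassificationTable:
    def test_fixture_matches_published_counts(self, reclass_results):
        t = reclass_results.table
        assert t.events.tolist() == [[0, 0, 0], [0, 8, 8], [0, 0, 14]]
        assert t.non_events.tolist() == [[49, 2, 0], [0, 115, 15], [0, 0, 31]]
        assert t.n_events == 30 and t.n_non_events == 212

    def test_identical_assignments_give_diagonal(self):
        groups = [LOW, INT, HIGH, INT]
        t = build_reclassification_table(groups, groups, [1, 0, 1, 0])
        assert np.all(np.triu(t.events, 1) == 0)
        assert np.all(np.tril(t.non_events, -1) == 0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        old = rng.integers(0, 3, 50)
        new = rng.integers(0, 3, 50)
        y = rng.integers(0, 2, 50)
        t1 = build_reclassification_table(old, new, y)
        perm = rng.permutation(50)
        t2 = build_reclassification_table(old[perm], new[perm], y[perm])
        assert np.array_equal(t1.events, t2.events)
        assert np.array_equal(t1.non_events, t2.non_events)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            build_reclassification_table([LOW], [LOW, HIGH], [0, 1])

    def test_marginals_match_stratifications(self, reclass_results):
        t = reclass_results.table
        old_sizes = reclass_results.old_stratification.group_sizes
        new_sizes = reclass_results.new_stratification.group_sizes
        assert t.old_group_sizes().tolist() == [old_sizes[g] for g in RiskGroup]
        assert t.new_group_sizes().tolist() == [new_sizes[g] for g in RiskGroup]


class TestOverallReclassificationImprovement:
    def test_published_components(self, reclass_results):
        s = reclass_results.reclass
        assert s.event_improvement == pytest.approx(8 / 30)
        assert s.non_event_improvement == pytest.approx(-17 / 212)
        assert s.overall_improvement == pytest.approx(-9 / 242)
        d = s.display()
        assert d["event_improvement"] == "26.7%"
        assert d["non_event_improvement"] == "-8.0%"
        assert d["overall_improvement"] == "-3.7%"

    def test_nri_exceeds_ori_here(self, reclass_results):
        # the conventional NRI up-weights the small event group
        s = reclass_results.reclass
        assert s.nri == pytest.approx(8 / 30 - 17 / 212)
        assert pct(s.nri, 1) == 18.6
        assert s.nri > s.overall_improvement

    def test_diagonal_table_all_zero(self):
        t = ReclassificationTable(
            np.diag([3, 4, 5]), np.diag([10, 20, 30])
        )
        s = overall_reclassification_improvement(t)
        assert s.event_improvement == s.non_event_improvement == 0.0
        assert s.overall_improvement == s.nri == 0.0

    def test_zero_denominator_raises(self):
        t = ReclassificationTable(np.zeros((3, 3)), np.diag([5, 5, 5]))
        with pytest.raises(ZeroDivisionError, match="events"):
            overall_reclassification_improvement(t)

    @given(
        st.lists(st.integers(0, 20), min_size=9, max_size=9),
        st.lists(st.integers(0, 20), min_size=9, max_size=9),
    )
    def test_antisymmetric_under_model_swap(self, ev, ne):
        ev = np.array(ev).reshape(3, 3)
        ne = np.array(ne).reshape(3, 3)
        if ev.sum() == 0 or ne.sum() == 0:
            return
        fwd = overall_reclassification_improvement(
            ReclassificationTable(ev, ne)
        )
        rev = overall_reclassification_improvement(
            ReclassificationTable(ev.T, ne.T)
        )
        assert rev.overall_improvement == pytest.approx(
            -fwd.overall_improvement
        )
        assert rev.nri == pytest.approx(-fwd.nri)


class TestIntermediateUpclassification:
    def test_published_counts(self, reclass_results):
        up = reclass_results.upclassified
        assert up.n_moved == 23
        assert up.n_events_moved == 8
        assert up.n_intermediate_old == 146
        assert pct(up.moved_share) == 16
        assert pct(up.event_fraction, 1) == 34.8
        assert pct(up.event_fraction) == 35
        assert up.n_moved_to_low == 0

    def test_diagonal_table_undefined_fraction(self):
        t = ReclassificationTable(np.diag([1, 1, 1]), np.diag([2, 2, 2]))
        up = upclassified_intermediate_summary(t)
        assert up.n_moved == 0 and up.n_events_moved == 0
        assert up.event_fraction is None


class TestStructuralMonotonicity:
    def test_crp_model_never_downgrades_any_covariate_pattern(self):
        """Adding a positive-coefficient CRP term cannot move a patient to a
        lower stratum: checked exhaustively over all 8 covariate patterns."""
        clin, crp = published_clinical_model(), published_crp_model()
        for r in (0, 1):
            for i in (0, 1):
                old = assign_risk_group(
                    predict_probability(
                        clin, {"runny_nose_absent": r, "feels_ill": i}
                    )
                )
                for c in (0, 1):
                    new = assign_risk_group(
                        predict_probability(
                            crp,
                            {"runny_nose_absent": r, "feels_ill": i,
                             "crp_gt_30": c},
                        )
                    )
                    assert new >= old

    def test_swapping_models_flips_signs_on_fixture(self, fixture):
        rev = ReclassificationAnalysis(
            fixture, published_crp_model(), published_clinical_model()
        ).fit()
        assert rev.reclass.overall_improvement == pytest.approx(9 / 242)
        assert rev.reclass.nri == pytest.approx(-(8 / 30 - 17 / 212))
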