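"""Utilisation family, downtime methods, aggregation regimes, potential gains."""

from fractions import Fraction

import pytest

from otmetrics import (
    EmptyCohortError,
    InvalidSessionError,
    capped_touch_time_utilisation,
    distribution_utilisation,
    intercase_downtime,
    pooled_relative_reduction,
    pooled_utilisation,
    potential_gains,
    raw_utilisation,
    touch_time_utilisation,
    utilisation_bundle,
)

from conftest import make_cohort, make_list


def list_with_used(used, alloc=480, list_id="L0001"):
    """Single fully-touched case occupying `used` minutes from session start."""
    return make_list([(540, 540 + used)], sched=(540, 540 + alloc), list_id=list_id)


class TestPerListUtilisation:
    def test_worked_example_raw_80_percent(self, worked_example):
        assert raw_utilisation(worked_example.lists[0]) == 0.80

    def test_worked_example_touch_60_percent(self, worked_example):
        assert touch_time_utilisation(worked_example.lists[0]) == 0.60

    def test_cancelled_list_is_zero_everywhere(self):
        lst = make_list([])
        assert raw_utilisation(lst) == 0
        assert touch_time_utilisation(lst) == 0
        assert capped_touch_time_utilisation(lst) == 0

    def test_overrun_pushes_raw_above_one(self):
        lst = make_list([(540, 1050)], sched=(540, 1020))  # 510 of 480 min
        assert raw_utilisation(lst) == 510 / 480

    def test_zero_allocation_is_an_error(self):
        with pytest.raises(InvalidSessionError):
            raw_utilisation(make_list([(540, 600)], sched=(540, 540)))


class TestIntercaseDowntime:
    def test_methods_coincide_for_single_segment_cases(self):
        lst = make_list([(540, 600), (630, 700)])
        assert intercase_downtime(lst, "gap_sum") == 30
        assert intercase_downtime(lst, "span_minus_touch") == 30

    def test_single_case_has_zero_downtime_both_ways(self):
        lst = make_list([(540, 700)])
        assert intercase_downtime(lst, "gap_sum") == 0
        assert intercase_downtime(lst, "span_minus_touch") == 0

    def test_within_case_pause_counts_only_in_span_minus_touch(self):
        lst = make_list([[(540, 580), (590, 650)], (680, 740)])
        assert intercase_downtime(lst, "gap_sum") == 30
        assert intercase_downtime(lst, "span_minus_touch") == 40

    def test_worked_example_gap_sum_120(self, worked_example):
        assert intercase_downtime(worked_example.lists[0], "gap_sum") == 120

    def test_gap_sum_never_exceeds_span_minus_touch(self):
        for cases in [
            [(540, 600)],
            [(540, 600), (630, 700)],
            [[(540, 570), (580, 640)], (700, 760), (790, 900)],
        ]:
            lst = make_list(cases)
            assert intercase_downtime(lst, "gap_sum") <= intercase_downtime(
                lst, "span_minus_touch"
            )


class TestCappedUtilisation:
    def test_overrunning_segment_contributes_only_its_in_window_part(self):
        # 300 touch minutes inside the window plus a segment overrunning
        # the 17:00 end by 60 min, of which 20 survive the clip
        lst = make_list(
            [(600, 750), (780, 930), (1000, 1080)], sched=(540, 1020)
        )
        assert capped_touch_time_utilisation(lst) == (300 + 20) / 480

    def test_all_touch_inside_window_equals_touch_utilisation(self):
        lst = make_list([(560, 700), (730, 900)])
        assert capped_touch_time_utilisation(lst) == touch_time_utilisation(lst)

    def test_all_touch_after_window_is_zero(self):
        lst = make_list([(1030, 1100)], sched=(540, 1020))
        assert capped_touch_time_utilisation(lst) == 0

    def test_cap_side_end_keeps_pre_window_touch(self):
        lst = make_list([(500, 700)], sched=(540, 1020))
        assert capped_touch_time_utilisation(lst, cap_side="both") == 160 / 480
        assert capped_touch_time_utilisation(lst, cap_side="end") == 200 / 480

    def test_ordering_capped_touch_raw(self):
        lst = make_list([(500, 640), (700, 1060)], sched=(540, 1020))
        b = utilisation_bundle(lst)
        assert b.capped_touch <= b.touch <= b.raw
        assert b.capped_touch <= 1


class TestAggregation:
    def cohort(self):
        return make_cohort(
            list_with_used(400, list_id="A"),
            list_with_used(360, list_id="B"),
            list_with_used(480, list_id="C"),
        )

    def test_pooled_is_sum_over_sum(self):
        pooled = pooled_utilisation(self.cohort(), "touch")
        assert pooled.numerator_minutes == 1240
        assert pooled.denominator_minutes == 1440
        assert pooled.value == 1240 / 1440

    def test_pooled_single_list_equals_its_utilisation(self):
        pooled = pooled_utilisation(make_cohort(list_with_used(400)), "touch")
        assert pooled.value == 400 / 480

    def test_pooled_shape_has_no_variance_fields(self):
        # one scalar and its audit trail; deliberately nothing else
        fields = set(pooled_utilisation(self.cohort(), "touch").to_dict())
        assert fields == {"value", "numerator_minutes", "denominator_minutes", "n_lists"}
        assert not fields & {"sd", "variance", "iqr", "q25", "q75", "se"}

    def test_distribution_reports_the_median_list(self):
        dist = distribution_utilisation(self.cohort(), "touch")
        assert dist.median == pytest.approx(400 / 480)
        assert dist.n == 3

    def test_pooled_and_median_generically_disagree(self):
        pooled = pooled_utilisation(self.cohort(), "touch").value
        median = distribution_utilisation(self.cohort(), "touch").median
        assert pooled != median  # 0.8611 vs 0.8333

    def test_identical_lists_make_the_regimes_agree(self):
        cohort = make_cohort(
            *(list_with_used(400, list_id=f"L{i}") for i in range(4))
        )
        assert pooled_utilisation(cohort, "touch").value == pytest.approx(
            distribution_utilisation(cohort, "touch").median
        )

    def test_pooled_equals_allocation_weighted_mean_exactly(self):
        cohort = make_cohort(
            list_with_used(300, alloc=480, list_id="A"),
            list_with_used(200, alloc=240, list_id="B"),
            list_with_used(500, alloc=600, list_id="C"),
        )
        pooled = pooled_utilisation(cohort, "touch")
        weighted = sum(
            Fraction(lst.allocated) * Fraction(lst.cases[0].touch_time, lst.allocated)
            for lst in cohort
        ) / sum(lst.allocated for lst in cohort)
        assert Fraction(pooled.numerator_minutes, pooled.denominator_minutes) == weighted

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyCohortError):
            pooled_utilisation(make_cohort(), "touch")


class TestPooledRelativeReduction:
    def test_blood_pressure_analogy_25_percent(self):
        assert pooled_relative_reduction(40_000, 30_000) == 25.0

    def test_no_change_is_zero(self):
        assert pooled_relative_reduction(123.0, 123.0) == 0.0

    def test_total_elimination_is_100(self):
        assert pooled_relative_reduction(100, 0) == 100.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            pooled_relative_reduction(0, 10)


class TestPotentialGains:
    def test_1200_unused_minutes_claims_20_extra_cases(self):
        # ten 480-min lists each leaving 120 min unused: 1200 pooled minutes
        cohort = make_cohort(
            *(list_with_used(360, list_id=f"L{i}") for i in range(10))
        )
        g = potential_gains(cohort, 60, mode="touch")
        assert g.unused_minutes == 1200
        assert g.pooled_extra_cases == 20
        assert g.feasible_extra_cases == 20  # here each list really fits 2 cases

    def test_scattered_five_minute_aliquots_pool_but_cannot_be_used(self):
        cohort = make_cohort(
            *(list_with_used(475, list_id=f"L{i:03d}") for i in range(100))
        )
        g = potential_gains(cohort, 60, mode="touch")
        assert g.unused_minutes == 500
        assert g.pooled_extra_cases == 8
        assert g.feasible_extra_cases == 0

    def test_fully_used_cohort_has_no_gains(self):
        cohort = make_cohort(list_with_used(480))
        g = potential_gains(cohort, 60, mode="touch")
        assert (g.unused_minutes, g.pooled_extra_cases, g.feasible_extra_cases) == (0, 0, 0)

    def test_overrun_contributes_zero_not_negative_unused(self):
        cohort = make_cohort(
            make_list([(540, 1080)], sched=(540, 1020), list_id="over"),  # 60 min over
            list_with_used(420, list_id="idle"),  # 60 min idle
        )
        g = potential_gains(cohort, 60, mode="touch")
        assert g.unused_minutes == 60  # the overrun does not cancel the idle hour
        strict = potential_gains(cohort, 60, mode="touch", strict_box1=True)
        assert strict.unused_minutes == 0

    def test_capped_mode_never_claims_fewer_than_touch_mode(self):
        cohort = make_cohort(
            make_list([(540, 700), (720, 1100)], sched=(540, 1020), list_id="A"),
            list_with_used(400, list_id="B"),
        )
        capped = potential_gains(cohort, 45, mode="capped")
        touch = potential_gains(cohort, 45, mode="touch")
        assert capped.pooled_extra_cases >= touch.pooled_extra_cases

    def test_pooled_always_at_least_feasible(self):
        cohort = make_cohort(
            list_with_used(395, list_id="A"),
            list_with_used(430, list_id="B"),
            list_with_used(401, list_id="C"),
        )
        g = potential_gains(cohort, 60, mode="touch")
        assert g.pooled_extra_cases >= g.feasible_extra_cases

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            potential_gains(make_cohort(list_with_used(400)), 0)
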