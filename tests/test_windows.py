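"""Delivery-anchored re-indexing, window collapse and the worked example."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from artpdc import (
    WindowSpec,
    build_daily_stock,
    coverage_over_window,
    days_on_art_at_delivery,
    fixtures,
    load_dispensing_table,
    reindex_to_anchor,
    results_to_frame,
    run_pipeline,
)

from conftest import single_dispensing_timeline

D = dt.date
DELIVERY = D(2017, 5, 2)


class TestWindowSpec:
    def test_default_is_final_24_weeks(self):
        w = WindowSpec()
        assert (w.start_offset, w.end_offset, w.divisor, w.length) == (-167, 0, 168, 168)
        assert w == WindowSpec.final_weeks(24)

    def test_divisor_defaults_to_window_length(self):
        w = WindowSpec(start_offset=1, end_offset=42)
        assert w.divisor == 42

    def test_postpartum_windows(self):
        assert WindowSpec.postpartum_weeks(6) == WindowSpec(1, 42)
        assert WindowSpec.postpartum_weeks(24) == WindowSpec(1, 168)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(start_offset=1, end_offset=0)
        with pytest.raises(ValueError):
            WindowSpec(divisor=0)
        with pytest.raises(ValueError):
            WindowSpec(anchor="conception")


class TestReindexToAnchor:
    def test_first_dispense_of_naive_patient_at_minus_81(self, example_timelines):
        series = build_daily_stock(example_timelines["2"])
        covered = reindex_to_anchor(series, DELIVERY, -280, 365)
        offsets = np.arange(-280, 366)
        assert covered[offsets == -82] == 0
        assert covered[offsets == -81] == 1  # ANC day = first dispense day
        assert covered[offsets == 0] == 1    # delivery day

    def test_days_before_initiation_read_uncovered(self):
        tl = single_dispensing_timeline(30, -10)  # initiates 10 days after delivery
        series = build_daily_stock(tl)
        covered = reindex_to_anchor(series, DELIVERY, -280, 365)
        assert not covered[: 280 + 10].any()
        assert covered[280 + 10] == 1

    def test_invalid_range_rejected(self, example_timelines):
        series = build_daily_stock(example_timelines["2"])
        with pytest.raises(ValueError):
            reindex_to_anchor(series, DELIVERY, 5, 4)


class TestWorkedExample:
    """The two-patient example must be reproduced cell for cell."""

    def test_final_outcome_rows(self, example_records):
        frame = results_to_frame(run_pipeline(example_records))
        expected = fixtures.expected_coverage_table()
        assert frame.to_dict("records") == expected.to_dict("records")

    def test_coverage_ratios_exact(self, example_records):
        by_id = {r.patient_id: r for r in run_pipeline(example_records)}
        assert by_id["1"].covered_days == 151
        assert by_id["1"].coverage == pytest.approx(151 / 168, abs=1e-12)
        assert abs(by_id["1"].coverage - 0.898810) < 5e-7
        assert by_id["2"].covered_days == 82
        assert abs(by_id["2"].coverage - 0.488095) < 5e-7
        assert (by_id["1"].flag_threshold, by_id["2"].flag_threshold) == (1, 0)

    def test_days_on_art_at_delivery(self, example_timelines):
        assert days_on_art_at_delivery(example_timelines["1"]) == 684
        assert days_on_art_at_delivery(example_timelines["2"]) == 81

    def test_endpoint_conventions_agree_on_example(self, example_records):
        w168 = run_pipeline(example_records, window=WindowSpec.final_weeks(24, "168"))
        w169 = run_pipeline(example_records, window=WindowSpec.final_weeks(24, "169"))
        assert [r.covered_days for r in w168] == [r.covered_days for r in w169]

    def test_endpoint_conventions_differ_at_day_minus_168(self):
        tl = single_dispensing_timeline(1, 168)  # covered only on day -168
        series = build_daily_stock(tl, DELIVERY)
        narrow = coverage_over_window(series, tl, WindowSpec.final_weeks(24, "168"))
        wide = coverage_over_window(series, tl, WindowSpec.final_weeks(24, "169"))
        assert (narrow.covered_days, wide.covered_days) == (0, 1)


class TestCoverageOverWindow:
    def test_post_delivery_initiator_has_zero_antenatal_coverage(self):
        recs = load_dispensing_table(fixtures.id3_table())
        (res,) = run_pipeline(recs)
        assert res.covered_days == 0
        assert res.coverage == 0.0
        assert res.days_on_art_at_delivery == -18  # reported, not clamped

    def test_post_delivery_initiator_covered_postpartum(self):
        recs = load_dispensing_table(fixtures.id3_table())
        (res,) = run_pipeline(recs, window=WindowSpec.postpartum_weeks(24))
        assert res.covered_days > 0

    def test_initiation_on_delivery_day(self):
        tl = single_dispensing_timeline(30, 0)
        series = build_daily_stock(tl)
        res = coverage_over_window(series, tl)
        assert res.days_on_art_at_delivery == 0
        assert res.covered_days == 1
        assert res.coverage == pytest.approx(1 / 168)

    def test_threshold_is_inclusive(self):
        tl = single_dispensing_timeline(17, 19)
        series = build_daily_stock(tl)
        window = WindowSpec(start_offset=-19, end_offset=0, divisor=20)
        res = coverage_over_window(series, tl, window, threshold=0.85)
        assert res.coverage == pytest.approx(0.85)
        assert res.flag_threshold == 1

    def test_threshold_out_of_range_rejected(self, example_timelines):
        tl = example_timelines["2"]
        series = build_daily_stock(tl)
        with pytest.raises(ValueError):
            coverage_over_window(series, tl, threshold=1.2)

    @settings(derandomize=True, max_examples=40)
    @given(days=st.integers(1, 200), offset=st.integers(0, 167))
    def test_single_dispensing_closed_form(self, days, offset):
        """One pack of D days at day -k covers min(D, k+1) window days."""
        tl = single_dispensing_timeline(days, offset)
        series = build_daily_stock(tl, DELIVERY)
        res = coverage_over_window(series, tl)
        assert res.covered_days == min(days, offset + 1)

    @settings(derandomize=True, max_examples=40)
    @given(split=st.integers(-166, -1), seed=st.integers(0, 50))
    def test_window_additivity(self, split, seed):
        from conftest import random_timeline

        tl = random_timeline(np.random.default_rng(seed))
        series = build_daily_stock(tl)
        def covered(a, b):
            return coverage_over_window(
                series, tl, WindowSpec(start_offset=a, end_offset=b)
            ).covered_days
        assert covered(-167, 0) == covered(-167, split) + covered(split + 1, 0)

    def test_enlarging_window_never_loses_covered_days(self, example_timelines):
        tl = example_timelines["1"]
        series = build_daily_stock(tl)
        counts = [
            coverage_over_window(series, tl, WindowSpec(-k, 0)).covered_days
            for k in range(0, 280, 7)
        ]
        assert counts == sorted(counts)


class TestPipeline:
    def test_one_row_per_patient_ordered(self, example_records):
        results = run_pipeline(example_records)
        assert [r.patient_id for r in results] == ["1", "2"]

    def test_full_window_dispensing_gives_unit_coverage(self):
        tl = single_dispensing_timeline(168, 167)
        series = build_daily_stock(tl)
        assert coverage_over_window(series, tl).coverage == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_pipeline([])

    def test_output_frame_layout(self, example_records):
        frame = results_to_frame(run_pipeline(example_records))
        assert list(frame.columns) == [
            "ID", "daysonarvs", "date_delivery", "date_ANC", "date_beginart",
            "hasarvs", "coverage", "flag",
        ]
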