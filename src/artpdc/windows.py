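"""Delivery-anchored observation windows and coverage metrics.

The daily stock series lives on a days-on-ART axis; here it is re-indexed to
days relative to an anchor date (delivery by default, offset 0 = the anchor
day, negative = before) and collapsed over a window into the proportion of
days covered (PDC):

    coverage = (covered days in window) / divisor

The default window is the final 24 weeks of pregnancy, offsets [-167, 0]
inclusive (168 days) with divisor 168, so coverage is bounded by 1 and the
delivery day itself is inside the window.  A 169-day variant with offsets
[-168, 0] and the same divisor 168 is available via
``WindowSpec.final_weeks(..., endpoint_convention="169")``; the two differ
only for a patient covered on day -168.  Postpartum windows (e.g. offsets
[1, 42] for the 6-week infant test) use the same machinery.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DispensingRecord, PatientTimeline, build_timelines
from .stock import DailyStockSeries, build_daily_stock, default_horizon

__all__ = [
    "WindowSpec",
    "CoverageResult",
    "reindex_to_anchor",
    "coverage_over_window",
    "days_on_art_at_delivery",
    "run_pipeline",
    "results_to_frame",
    "DEFAULT_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.85

# Default re-indexing span: conception (40-week term) to one year postpartum.
DEFAULT_RANGE = (-280, 365)


@dataclass(frozen=True)
class WindowSpec:
    """An observation window as day offsets relative to an anchor date.

    ``start_offset``/``end_offset`` are inclusive day offsets from the
    anchor (delivery), negative = antenatal.  ``divisor`` is the denominator
    of the coverage ratio; by default the window length.
    """

    start_offset: int = -167
    end_offset: int = 0
    divisor: int | None = None
    anchor: str = "delivery"

    def __post_init__(self) -> None:
        if self.start_offset > self.end_offset:
            raise ValueError(
                f"start_offset {self.start_offset} > end_offset {self.end_offset}"
            )
        if self.divisor is None:
            object.__setattr__(self, "divisor", self.length)
        if self.divisor < 1:
            raise ValueError(f"divisor must be >= 1, got {self.divisor}")
        if self.anchor != "delivery":
            raise ValueError(f"unsupported anchor {self.anchor!r}")

    @property
    def length(self) -> int:
        return self.end_offset - self.start_offset + 1

    @classmethod
    def final_weeks(cls, weeks: int = 24, endpoint_convention: str = "168") -> "WindowSpec":
        """Final ``weeks`` of pregnancy, ending on the delivery day.

        ``endpoint_convention="168"`` (default) uses offsets
        [-(7*weeks - 1), 0], so window length equals the divisor 7*weeks;
        ``"169"`` additionally includes day -7*weeks while keeping the same
        divisor, so coverage can marginally exceed 1.
        """
        divisor = 7 * weeks
        if endpoint_convention == "168":
            return cls(start_offset=-(divisor - 1), end_offset=0, divisor=divisor)
        if endpoint_convention == "169":
            return cls(start_offset=-divisor, end_offset=0, divisor=divisor)
        raise ValueError(f"unknown endpoint convention {endpoint_convention!r}")

    @classmethod
    def postpartum_weeks(cls, weeks: int) -> "WindowSpec":
        """First ``weeks`` after delivery, offsets [1, 7*weeks]."""
        return cls(start_offset=1, end_offset=7 * weeks)


@dataclass(frozen=True)
class CoverageResult:
    """One patient's collapsed coverage row (the final-outcome schema)."""

    patient_id: str
    days_on_art_at_delivery: int
    delivery_date: dt.date
    anc_date: dt.date
    initiation_date: dt.date
    covered_days: int
    coverage: float
    flag_threshold: int


def reindex_to_anchor(
    series: DailyStockSeries,
    anchor_date: dt.date,
    range_start: int = DEFAULT_RANGE[0],
    range_end: int = DEFAULT_RANGE[1],
) -> np.ndarray:
    """Covered indicator per day-offset relative to ``anchor_date``.

    Offsets before initiation or beyond the series horizon read as 0
    (uncovered): a day outside the built series is a day without supply.
    """
    if range_start > range_end:
        raise ValueError(f"range_start {range_start} > range_end {range_end}")
    offsets = np.arange(range_start, range_end + 1)
    # series index of each offset's calendar day
    base = (anchor_date - series.start_date).days
    idx = base + offsets
    out = np.zeros(len(offsets), dtype=np.int8)
    valid = (idx >= 0) & (idx < len(series.covered))
    out[valid] = series.covered[idx[valid]]
    return out


def days_on_art_at_delivery(timeline: PatientTimeline) -> int:
    """Whole days from ART initiation to delivery.

    Negative for women who initiate only after delivery; reported as
    computed, never clamped.
    """
    return (timeline.delivery_date - timeline.initiation_date).days


def coverage_over_window(
    series: DailyStockSeries,
    timeline: PatientTimeline,
    window: WindowSpec | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CoverageResult:
    """Collapse the daily series over ``window`` into a coverage row."""
    if window is None:
        window = WindowSpec()
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    covered = reindex_to_anchor(
        series, timeline.delivery_date, window.start_offset, window.end_offset
    )
    covered_days = int(covered.sum())
    coverage = covered_days / window.divisor
    days_at_delivery = days_on_art_at_delivery(timeline)
    if days_at_delivery < 0:
        logger.warning(
            "patient %s initiated ART %d days after delivery; antenatal "
            "coverage is zero", timeline.patient_id, -days_at_delivery,
        )
    return CoverageResult(
        patient_id=timeline.patient_id,
        days_on_art_at_delivery=days_at_delivery,
        delivery_date=timeline.delivery_date,
        anc_date=timeline.anc_date,
        initiation_date=timeline.initiation_date,
        covered_days=covered_days,
        coverage=coverage,
        flag_threshold=int(coverage >= threshold),
    )


def run_pipeline(
    records: Iterable[DispensingRecord],
    window: WindowSpec | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    stock_cap: int | None = None,
) -> list[CoverageResult]:
    """End-to-end: records -> timelines -> daily stock -> coverage rows.

    One :class:`CoverageResult` per patient, ordered by patient id.  The
    stock horizon is delivery + 365 days per patient, extended to cover any
    later dispensing, so any window inside the default re-indexing span is
    fully supported.
    """
    timelines = build_timelines(records)
    if not timelines:
        raise ValueError("no patients in input")
    results = []
    for tl in timelines:
        series = build_daily_stock(tl, default_horizon(tl), stock_cap=stock_cap)
        results.append(coverage_over_window(series, tl, window, threshold))
    return results


def results_to_frame(
    results: Sequence[CoverageResult],
    date_format: str = "%Y-%m-%d",
) -> pd.DataFrame:
    """Render results in the final-outcome column layout.

    Columns: ``ID, daysonarvs, date_delivery, date_ANC, date_beginart,
    hasarvs, coverage, flag`` — days on ART at delivery, the three anchor
    dates, covered days in the window, the coverage ratio (6 decimals) and
    the threshold indicator.
    """
    return pd.DataFrame(
        {
            "ID": [r.patient_id for r in results],
            "daysonarvs": [r.days_on_art_at_delivery for r in results],
            "date_delivery": [r.delivery_date.strftime(date_format) for r in results],
            "date_ANC": [r.anc_date.strftime(date_format) for r in results],
            "date_beginart": [r.initiation_date.strftime(date_format) for r in results],
            "hasarvs": [r.covered_days for r in results],
            "coverage": [round(r.coverage, 6) for r in results],
            "flag": [r.flag_threshold for r in results],
        }
    )
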