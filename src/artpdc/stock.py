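"""Daily pill-count engine: days of ART supply on hand, day by day.

For each calendar day from treatment initiation to a horizon, the engine
tracks the days of once-daily supply available after crediting that day's
dispensing, under the standard proportion-of-days-covered accounting:

    stock[d] = max(stock[d-1] - 1, 0) + dispensed[d],   stock[init] = dispensed[init]

One day of supply is consumed per calendar day while any remains.  A refill
that arrives early is added to the leftover supply (stockpiling carryover);
an exact refill produces no gap; a late refill leaves zero-stock days in
between.  A day is *covered* iff stock >= 1 after the day's credit, so the
initiation day itself counts as covered.

:func:`build_daily_stock` computes the series event-by-event with vectorized
segment fills; :func:`oracle_daily_stock` is a deliberately naive one-day-at-
a-time simulation of the same contract, kept as an independent cross-check
for the test suite.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import PatientTimeline

__all__ = ["DailyStockSeries", "build_daily_stock", "oracle_daily_stock",
           "default_horizon"]

POSTPARTUM_HORIZON_DAYS = 365


@dataclass(frozen=True)
class DailyStockSeries:
    """Per-day supply on hand and covered indicator for one patient.

    Day index 0 is the initiation date; ``stock[i]`` is the days of supply
    available on day ``start_date + i`` after crediting that day's
    dispensing, and ``covered[i] = 1`` iff ``stock[i] >= 1``.
    """

    patient_id: str
    start_date: dt.date
    horizon_date: dt.date
    stock: np.ndarray = field(repr=False)
    covered: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.stock)

    @property
    def days_on_art(self) -> np.ndarray:
        """Integer day index from initiation (the series' time axis)."""
        return np.arange(len(self.stock))

    def index_of(self, day: dt.date) -> int:
        return (day - self.start_date).days

    def stock_on(self, day: dt.date) -> int:
        i = self.index_of(day)
        if not 0 <= i < len(self.stock):
            raise IndexError(f"{day} is outside the series range")
        return int(self.stock[i])

    def covered_on(self, day: dt.date) -> int:
        """Covered indicator for any calendar day; 0 outside the series."""
        i = self.index_of(day)
        if 0 <= i < len(self.covered):
            return int(self.covered[i])
        return 0

    def to_frame(self) -> pd.DataFrame:
        """Per-day diagnostic table (patient, date, day index, stock, covered)."""
        dates = pd.date_range(self.start_date, self.horizon_date, freq="D").date
        return pd.DataFrame(
            {
                "ID": self.patient_id,
                "date": [d.isoformat() for d in dates],
                "days_on_art": self.days_on_art,
                "stock": self.stock,
                "covered": self.covered,
            }
        )


def default_horizon(timeline: PatientTimeline) -> dt.date:
    """Delivery + 365 days, extended to cover any later dispensing."""
    return max(
        timeline.delivery_date + dt.timedelta(days=POSTPARTUM_HORIZON_DAYS),
        timeline.last_dispense_date,
    )


def build_daily_stock(
    timeline: PatientTimeline,
    horizon_date: dt.date | None = None,
    stock_cap: int | None = None,
) -> DailyStockSeries:
    """Compute the daily stock series from initiation to ``horizon_date``.

    Parameters
    ----------
    timeline
        Consolidated dispensing history for one patient.
    horizon_date
        Last day of the series (default :func:`default_horizon`).  Must not
        precede the initiation date.
    stock_cap
        Optional ceiling on the post-credit stock (no cap by default;
        carryover is unlimited).

    Notes
    -----
    Instead of stepping day by day, the recursion is advanced only at
    dispensing events: between consecutive events the stock declines by one
    per day with a floor at zero, so each inter-event segment is filled with
    a single vectorized ramp.  The per-day semantics are identical to
    :func:`oracle_daily_stock`.
    """
    if horizon_date is None:
        horizon_date = default_horizon(timeline)
    n_days = (horizon_date - timeline.initiation_date).days + 1
    if n_days < 1:
        raise ValueError(
            f"horizon {horizon_date} precedes initiation "
            f"{timeline.initiation_date} for patient {timeline.patient_id!r}"
        )
    stock = np.zeros(n_days, dtype=np.int64)
    events = [
        ((day - timeline.initiation_date).days, qty)
        for day, qty in sorted(timeline.dispensed_by_date.items())
        if (day - timeline.initiation_date).days < n_days
    ]
    level = 0          # post-credit stock at the segment's first day
    seg_start = 0
    for offset, qty in events:
        if offset > seg_start:
            # decline from the previous event's level, floored at zero
            ramp = level - np.arange(offset - seg_start)
            stock[seg_start:offset] = np.maximum(ramp, 0)
            level = max(level - (offset - seg_start), 0)
        level += qty
        if stock_cap is not None:
            level = min(level, stock_cap)
        seg_start = offset
    ramp = level - np.arange(n_days - seg_start)
    stock[seg_start:] = np.maximum(ramp, 0)
    covered = (stock >= 1).astype(np.int8)
    return DailyStockSeries(
        patient_id=timeline.patient_id,
        start_date=timeline.initiation_date,
        horizon_date=horizon_date,
        stock=stock,
        covered=covered,
    )


def oracle_daily_stock(
    timeline: PatientTimeline,
    horizon_date: dt.date | None = None,
    stock_cap: int | None = None,
) -> DailyStockSeries:
    """Naive one-day-at-a-time reference simulation (tests only).

    Same contract as :func:`build_daily_stock`, with no vectorization and no
    event bookkeeping: the recursion is executed literally, one calendar day
    per loop iteration.
    """
    if horizon_date is None:
        horizon_date = default_horizon(timeline)
    if horizon_date < timeline.initiation_date:
        raise ValueError(
            f"horizon {horizon_date} precedes initiation "
            f"{timeline.initiation_date} for patient {timeline.patient_id!r}"
        )
    stock_list: list[int] = []
    level = 0
    day = timeline.initiation_date
    first = True
    while day <= horizon_date:
        if first:
            level = timeline.dispensed_by_date.get(day, 0)
            first = False
        else:
            level = max(level - 1, 0) + timeline.dispensed_by_date.get(day, 0)
        if stock_cap is not None:
            level = min(level, stock_cap)
        stock_list.append(level)
        day += dt.timedelta(days=1)
    stock = np.asarray(stock_list, dtype=np.int64)
    return DailyStockSeries(
        patient_id=timeline.patient_id,
        start_date=timeline.initiation_date,
        horizon_date=horizon_date,
        stock=stock,
        covered=(stock >= 1).astype(np.int8),
    )
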