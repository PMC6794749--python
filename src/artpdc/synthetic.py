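"""Seeded generator of synthetic dispensing cohorts.

Emits tables in the canonical five-column schema spanning the three patient
categories relevant to the PMTCT cascade:

* *treatment-experienced* — initiated ART before conception;
* *treatment-naive* — initiated at the first ANC visit;
* *post-delivery initiator* — first dispensing only after delivery
  (zero antenatal coverage by construction).

Refill behaviour is controlled by a finite set of pack sizes and a
distribution of refill timing relative to stock exhaustion (negative =
early, stockpiling; positive = late, coverage gaps).  The generator exists
to exercise code paths and closed forms, not to model adherence psychology.
All draws come from one ``numpy`` Generator seeded from ``seed`` and are
consumed in a fixed documented order, so a given seed is fully reproducible.
"""

from __future__ import annotations

import datetime as dt
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    DispensingDataError,
    load_dispensing_table,
    build_timeline,
)
from .stock import default_horizon, oracle_daily_stock
from .windows import WindowSpec, coverage_over_window

__all__ = ["CohortGenParams", "generate_cohort", "generate_ground_truth",
           "make_table1_like", "CATEGORIES"]

CATEGORIES = ("experienced", "naive", "post_delivery")

TERM_DAYS = 280


@dataclass(frozen=True)
class CohortGenParams:
    """Knobs for :func:`generate_cohort`.

    Defaults: pack sizes are the common clinic quantities 15/30/60/90/100
    days; gestational age at the first ANC visit is uniform over 56-252 days
    (8-36 weeks), spanning early and late presenters; refill timing is
    uniform over -14..+14 days around stock exhaustion; deliveries are
    spread over one calendar year.
    """

    n_patients: int = 100
    p_experienced: float = 0.4
    p_post_delivery: float = 0.1
    ga_at_anc_range: tuple[int, int] = (56, 252)
    refill_quantities: Sequence[int] = (15, 30, 60, 90, 100)
    refill_delay_choices: Sequence[int] = tuple(range(-14, 15))
    base_delivery_date: dt.date = dt.date(2020, 1, 1)
    delivery_spread_days: int = 365
    preconception_max_days: int = 730
    postpartum_horizon_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0 <= self.p_experienced <= 1 and 0 <= self.p_post_delivery <= 1):
            raise ValueError("category probabilities must be in [0, 1]")
        if self.p_experienced + self.p_post_delivery > 1:
            raise ValueError("p_experienced + p_post_delivery must be <= 1")
        if not self.refill_quantities or min(self.refill_quantities) < 1:
            raise ValueError("refill_quantities must be a non-empty set of packs >= 1")
        lo, hi = self.ga_at_anc_range
        if not 0 <= lo <= hi <= TERM_DAYS:
            raise ValueError(f"ga_at_anc_range must satisfy 0 <= lo <= hi <= {TERM_DAYS}")
        if not self.refill_delay_choices:
            raise ValueError("refill_delay_choices must be non-empty")


def _patient_events(rng: np.random.Generator, params: CohortGenParams,
                    initiation: dt.date, horizon: dt.date) -> list[tuple[dt.date, int]]:
    """Refill walk: pack draw, then next visit at exhaustion + delay draw."""
    packs = np.asarray(params.refill_quantities)
    delays = np.asarray(params.refill_delay_choices)
    events: list[tuple[dt.date, int]] = []
    day = initiation
    while day <= horizon or not events:
        qty = int(rng.choice(packs))
        events.append((day, qty))
        exhaustion = day + dt.timedelta(days=qty)
        nxt = exhaustion + dt.timedelta(days=int(rng.choice(delays)))
        # a very early return cannot precede the visit it follows
        day = max(nxt, day + dt.timedelta(days=1))
    return events


def generate_cohort(params: CohortGenParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort; returns ``(table, categories)``.

    ``table`` is a canonical five-column dispensing table; ``categories``
    maps each patient id to its drawn category.  Per patient, in order:
    category draw; delivery-date offset; gestational age at ANC (sets the
    ANC date); initiation offset for the experienced / post-delivery
    categories; then the refill walk (pack size and delay alternating).
    Deterministic per ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    p_naive = 1.0 - params.p_experienced - params.p_post_delivery
    rows: list[dict] = []
    for i in range(params.n_patients):
        pid = f"P{i + 1:04d}"
        category = rng.choice(
            CATEGORIES, p=[params.p_experienced, p_naive, params.p_post_delivery]
        )
        delivery = params.base_delivery_date + dt.timedelta(
            days=int(rng.integers(0, params.delivery_spread_days))
        )
        lo, hi = params.ga_at_anc_range
        ga = int(rng.integers(lo, hi + 1))
        anc = delivery - dt.timedelta(days=TERM_DAYS - ga)
        if category == "experienced":
            initiation = delivery - dt.timedelta(
                days=TERM_DAYS + int(rng.integers(1, params.preconception_max_days + 1))
            )
        elif category == "naive":
            initiation = anc
        else:  # post-delivery initiator
            initiation = delivery + dt.timedelta(days=int(rng.integers(1, 61)))
        horizon = delivery + dt.timedelta(days=params.postpartum_horizon_days)
        for day, qty in _patient_events(rng, params, initiation, horizon):
            rows.append(
                {
                    "ID": pid,
                    "date": day.isoformat(),
                    "daysarvs": qty,
                    "ANCdate": anc.isoformat(),
                    "deliverydate": delivery.isoformat(),
                    "_category": category,
                }
            )
    frame = pd.DataFrame(rows)
    return frame.drop(columns="_category"), frame[["ID", "_category"]].drop_duplicates(
        "ID"
    ).rename(columns={"_category": "category"}).reset_index(drop=True)


def generate_ground_truth(table: pd.DataFrame, categories: pd.DataFrame,
                          window: WindowSpec | None = None) -> pd.DataFrame:
    """Companion truth table: category plus covered days from the naive oracle.

    The covered-day counts are computed with the day-by-day reference
    simulation, independently of the production engine, so the pair
    (table, truth) can be used to validate any implementation.
    """
    records = load_dispensing_table(table)
    by_patient: dict[str, list] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    rows = []
    for pid, recs in sorted(by_patient.items()):
        tl = build_timeline(recs)
        series = oracle_daily_stock(tl, default_horizon(tl))
        res = coverage_over_window(series, tl, window)
        rows.append({"ID": pid, "covered_days": res.covered_days,
                     "coverage": round(res.coverage, 6)})
    truth = pd.DataFrame(rows)
    return truth.merge(categories, on="ID")


def make_table1_like(patients: Sequence[Mapping]) -> pd.DataFrame:
    """Build a dispensing table from explicit per-patient event lists.

    Each entry needs ``patient_id``, ``anc_date``, ``delivery_date`` (ISO
    strings or dates) and ``events``: a sequence of ``(date, days)`` pairs.
    Used to encode hand-crafted fixtures (the worked example, same-day
    duplicates, post-delivery initiators).  An empty event list is an error:
    a patient must have at least one dispensing.
    """
    rows = []
    for spec in patients:
        events = spec["events"]
        if not events:
            raise DispensingDataError(
                f"patient {spec['patient_id']!r} has no dispensing events"
            )
        for day, qty in events:
            if int(qty) < 1:
                raise DispensingDataError(
                    f"patient {spec['patient_id']!r}: days supplied must be >= 1, "
                    f"got {qty} on {day}"
                )
            rows.append(
                {
                    "ID": str(spec["patient_id"]),
                    "date": str(day),
                    "daysarvs": int(qty),
                    "ANCdate": str(spec["anc_date"]),
                    "deliverydate": str(spec["delivery_date"]),
                }
            )
    return pd.DataFrame(rows)
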