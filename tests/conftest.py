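import datetime as dt

import numpy as np
import pytest

from artpdc import build_timelines, fixtures
from artpdc.records import PatientTimeline

PACK_SIZES = (15, 30, 60, 90, 100)


def random_timeline(rng: np.random.Generator) -> PatientTimeline:
    """A random single-patient dispensing history around a pregnancy.

    Initiation anywhere from ~400 days before to 100 days after delivery;
    refills drawn from common pack sizes with -14..+14 day timing jitter,
    continuing through one year postpartum.
    """
    delivery = dt.date(2019, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))
    anc = delivery - dt.timedelta(days=int(rng.integers(28, 225)))
    initiation = delivery + dt.timedelta(days=int(rng.integers(-400, 101)))
    horizon = delivery + dt.timedelta(days=365)
    dispensed: dict[dt.date, int] = {}
    day = initiation
    while day <= horizon or not dispensed:
        qty = int(rng.choice(PACK_SIZES))
        dispensed[day] = dispensed.get(day, 0) + qty
        step = qty + int(rng.integers(-14, 15))
        day = day + dt.timedelta(days=max(step, 1))
    return PatientTimeline(
        patient_id="R",
        initiation_date=min(dispensed),
        dispensed_by_date=dict(sorted(dispensed.items())),
        anc_date=anc,
        delivery_date=delivery,
    )


def single_dispensing_timeline(days_supplied: int, offset_before_delivery: int,
                               delivery: dt.date = dt.date(2017, 5, 2)) -> PatientTimeline:
    """One dispensing of ``days_supplied`` days, ``offset_before_delivery``
    days before delivery (0 = on the delivery day)."""
    start = delivery - dt.timedelta(days=offset_before_delivery)
    return PatientTimeline(
        patient_id="S",
        initiation_date=start,
        dispensed_by_date={start: days_supplied},
        anc_date=delivery - dt.timedelta(days=81),
        delivery_date=delivery,
    )


@pytest.fixture(scope="session")
def example_records():
    return fixtures.example_records()


@pytest.fixture(scope="session")
def example_timelines(example_records):
    return {tl.patient_id: tl for tl in build_timelines(example_records)}
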