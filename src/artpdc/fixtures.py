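"""Built-in worked-example fixtures.

Two women delivering on 2017-05-02 who both presented for their first ANC
visit on 2017-02-10 (81 days before delivery, ~28 weeks gestation):

* patient ``1`` — treatment-experienced, on ART since 2015-06-18 (12
  dispensing events);
* patient ``2`` — treatment-naive, initiated at the ANC visit (4 events).

A third patient category — a woman whose first dispensing falls only after
delivery, hence zero antenatal coverage — is available as
:func:`id3_table`.  :func:`expected_coverage_table` holds the final-outcome
rows for patients 1 and 2 under the default final-24-weeks window and 0.85
threshold, for regression checks.
"""

from __future__ import annotations

import pandas as pd

from .records import DispensingRecord, load_dispensing_table
from .synthetic import make_table1_like

__all__ = ["example_table", "example_records", "id3_table",
           "expected_coverage_table"]

_EXAMPLE_PATIENTS = [
    {
        "patient_id": "1",
        "anc_date": "2017-02-10",
        "delivery_date": "2017-05-02",
        "events": [
            ("2015-06-18", 15),
            ("2015-08-12", 60),
            ("2015-10-09", 90),
            ("2016-02-17", 60),
            ("2016-04-19", 90),
            ("2016-07-29", 90),
            ("2016-11-21", 100),
            ("2017-02-10", 30),
            ("2017-04-12", 60),
            ("2017-06-19", 30),
            ("2017-07-25", 60),
            ("2017-09-29", 60),
        ],
    },
    {
        "patient_id": "2",
        "anc_date": "2017-02-10",
        "delivery_date": "2017-05-02",
        "events": [
            ("2017-02-10", 15),
            ("2017-02-25", 30),
            ("2017-03-27", 30),
            ("2017-04-26", 60),
        ],
    },
]

# Post-delivery initiator: first dispensing 18 days after delivery.
_ID3_PATIENT = {
    "patient_id": "3",
    "anc_date": "2017-02-10",
    "delivery_date": "2017-05-02",
    "events": [("2017-05-20", 30), ("2017-06-19", 30), ("2017-07-19", 60)],
}

# Final-outcome rows for the example cohort (default window, 0.85 threshold).
_EXPECTED_COVERAGE = [
    {"ID": "1", "daysonarvs": 684, "date_delivery": "2017-05-02",
     "date_ANC": "2017-02-10", "date_beginart": "2015-06-18",
     "hasarvs": 151, "coverage": 0.898810, "flag": 1},
    {"ID": "2", "daysonarvs": 81, "date_delivery": "2017-05-02",
     "date_ANC": "2017-02-10", "date_beginart": "2017-02-10",
     "hasarvs": 82, "coverage": 0.488095, "flag": 0},
]


def example_table() -> pd.DataFrame:
    """The 16-row, 2-patient worked-example dispensing table."""
    return make_table1_like(_EXAMPLE_PATIENTS)


def example_records() -> list[DispensingRecord]:
    """The worked example as validated records."""
    return load_dispensing_table(example_table())


def id3_table() -> pd.DataFrame:
    """A post-delivery initiator (zero antenatal coverage)."""
    return make_table1_like([_ID3_PATIENT])


def expected_coverage_table() -> pd.DataFrame:
    """Expected final-outcome rows for :func:`example_table`."""
    return pd.DataFrame(_EXPECTED_COVERAGE)
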