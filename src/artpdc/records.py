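"""Reading, validation and normalization of ART dispensing tables.

The canonical input is a delimited-text table with one row per dispensing
event and five columns::

    ID, date, daysarvs, ANCdate, deliverydate

``ID`` is an opaque patient identifier, ``date`` the calendar date the
antiretrovirals were dispensed, ``daysarvs`` the days of once-daily supply
handed over, and ``ANCdate`` / ``deliverydate`` the pregnancy anchor dates
(first antenatal-care visit and delivery), constant within a patient.  A
missing ``deliverydate`` is permitted only when a gestational-age column
(``ga_days``, days at the first ANC visit) is present; the delivery date is
then imputed under a 280-day term before any coverage computation.
"""

from __future__ import annotations

import datetime as dt
import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DispensingRecord",
    "PatientTimeline",
    "DispensingDataError",
    "DATE_DIALECTS",
    "load_dispensing_table",
    "records_to_frame",
    "write_dispensing_table",
    "build_timeline",
    "build_timelines",
    "estimate_delivery_date",
]

# Term length used for the delivery-date imputation and the antenatal axis:
# 40 weeks of gestation.
TERM_DAYS = 280

#: Accepted date dialects.  The dialect is declared by the caller, never
#: sniffed per cell: silently mixing day-first and month-first parses can
#: corrupt day counts by months.
DATE_DIALECTS: Mapping[str, str] = {
    "iso": "%Y-%m-%d",       # 2017-05-02 (canonical)
    "dmy": "%d-%b-%y",       # 2-May-17 (common print format)
}

#: Default header names for the five canonical columns plus the optional
#: gestational-age column.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "patient_id": "ID",
    "dispense_date": "date",
    "days_supplied": "daysarvs",
    "anc_date": "ANCdate",
    "delivery_date": "deliverydate",
    "ga_days": "ga_days",
}


class DispensingDataError(ValueError):
    """A dispensing table failed validation; the message names row/column."""


@dataclass(frozen=True)
class DispensingRecord:
    """One dispensing event plus the patient's pregnancy anchor dates."""

    patient_id: str
    dispense_date: dt.date
    days_supplied: int
    anc_date: dt.date
    delivery_date: dt.date

    def __post_init__(self) -> None:
        if self.days_supplied < 1:
            raise DispensingDataError(
                f"days_supplied must be >= 1, got {self.days_supplied} "
                f"for patient {self.patient_id!r} on {self.dispense_date}"
            )


@dataclass(frozen=True)
class PatientTimeline:
    """Per-patient consolidated dispensing history.

    ``initiation_date`` is the earliest dispense date (the date of ART
    initiation); ``dispensed_by_date`` maps each dispense date to the total
    days of supply handed over that day, with same-day events summed.
    ``delivery_date`` may precede ``initiation_date`` for women who initiate
    ART only after delivery; that is a valid state, not an error.
    """

    patient_id: str
    initiation_date: dt.date
    dispensed_by_date: Mapping[dt.date, int]
    anc_date: dt.date
    delivery_date: dt.date

    @property
    def last_dispense_date(self) -> dt.date:
        return max(self.dispensed_by_date)

    @property
    def total_days_supplied(self) -> int:
        return sum(self.dispensed_by_date.values())


def estimate_delivery_date(anc_date: dt.date, gestational_age_at_anc: int) -> dt.date:
    """Impute a delivery date from gestational age at the first ANC visit.

    Under the 280-day (40-week) term convention the expected delivery date is
    ``anc_date + (280 - gestational_age_at_anc)`` days.
    """
    ga = int(gestational_age_at_anc)
    if not 0 <= ga <= TERM_DAYS:
        raise DispensingDataError(
            f"gestational age at ANC must be in [0, {TERM_DAYS}] days, got {ga}"
        )
    return anc_date + dt.timedelta(days=TERM_DAYS - ga)


def _parse_date(raw: object, fmt: str, row: int, column: str) -> dt.date:
    # .dta / DataFrame inputs may carry already-parsed timestamps
    if isinstance(raw, (pd.Timestamp, dt.datetime)):
        return raw.date()
    if isinstance(raw, dt.date):
        return raw
    text = str(raw).strip()
    try:
        return dt.datetime.strptime(text, fmt).date()
    except ValueError:
        raise DispensingDataError(
            f"row {row}: cannot parse {column}={text!r} with format {fmt!r}"
        ) from None


def _read_frame(source, **kwargs) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, (str, os.PathLike)) and str(source).endswith(".dta"):
        # Optional Stata convenience path; delimited text stays canonical.
        return pd.read_stata(source)
    return pd.read_csv(source, dtype=str, skipinitialspace=True, **kwargs)


def load_dispensing_table(
    source,
    date_dialect: str = "iso",
    columns: Mapping[str, str] | None = None,
) -> list[DispensingRecord]:
    """Read a dispensing table into validated records.

    Parameters
    ----------
    source
        Path, file-like object or :class:`pandas.DataFrame`.  A ``.dta``
        path is read as a Stata dataset; anything else as delimited text.
    date_dialect
        Key of :data:`DATE_DIALECTS` or an explicit ``strptime`` format.
        Applied uniformly; a cell that does not parse is an error naming the
        row and column.
    columns
        Overrides for the default header names (keys of
        :data:`DEFAULT_COLUMNS`).

    Returns
    -------
    list of :class:`DispensingRecord`, sorted by (patient_id, dispense_date).
    Same-day duplicates are preserved here; consolidation happens in
    :func:`build_timeline`.
    """
    fmt = DATE_DIALECTS.get(date_dialect, date_dialect)
    names = dict(DEFAULT_COLUMNS)
    if columns:
        names.update(columns)

    frame = _read_frame(source)
    for field in ("patient_id", "dispense_date", "days_supplied", "anc_date"):
        if names[field] not in frame.columns:
            raise DispensingDataError(f"missing required column {names[field]!r}")
    has_delivery = names["delivery_date"] in frame.columns
    has_ga = names["ga_days"] in frame.columns
    if not has_delivery and not has_ga:
        raise DispensingDataError(
            f"missing required column {names['delivery_date']!r} "
            f"(or a {names['ga_days']!r} column to impute it)"
        )

    records: list[DispensingRecord] = []
    for row_label, row in frame.iterrows():
        row_no = int(row_label) + 1  # 1-based data row, header excluded
        pid = str(row[names["patient_id"]]).strip()
        raw_days = str(row[names["days_supplied"]]).strip()
        try:
            as_float = float(raw_days)
            if not as_float.is_integer():
                raise ValueError
            days = int(as_float)
            if days < 1:
                raise ValueError
        except (TypeError, ValueError):
            raise DispensingDataError(
                f"row {row_no}: {names['days_supplied']}={raw_days!r} "
                "is not a positive integer"
            ) from None
        dispense = _parse_date(row[names["dispense_date"]], fmt, row_no,
                               names["dispense_date"])
        anc = _parse_date(row[names["anc_date"]], fmt, row_no, names["anc_date"])
        delivery_raw = row[names["delivery_date"]] if has_delivery else None
        if delivery_raw is None or pd.isna(delivery_raw) or str(delivery_raw).strip() == "":
            if not has_ga or pd.isna(row[names["ga_days"]]):
                raise DispensingDataError(
                    f"row {row_no}: {names['delivery_date']} is missing and no "
                    f"{names['ga_days']} value is available to impute it"
                )
            delivery = estimate_delivery_date(anc, int(float(row[names["ga_days"]])))
        else:
            delivery = _parse_date(delivery_raw, fmt, row_no, names["delivery_date"])
        records.append(
            DispensingRecord(
                patient_id=pid,
                dispense_date=dispense,
                days_supplied=days,
                anc_date=anc,
                delivery_date=delivery,
            )
        )
    records.sort(key=lambda r: (r.patient_id, r.dispense_date))
    return records


def records_to_frame(
    records: Iterable[DispensingRecord],
    date_dialect: str = "iso",
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Render records back to the canonical five-column table."""
    fmt = DATE_DIALECTS.get(date_dialect, date_dialect)
    names = dict(DEFAULT_COLUMNS)
    if columns:
        names.update(columns)
    rows = [
        {
            names["patient_id"]: r.patient_id,
            names["dispense_date"]: r.dispense_date.strftime(fmt),
            names["days_supplied"]: r.days_supplied,
            names["anc_date"]: r.anc_date.strftime(fmt),
            names["delivery_date"]: r.delivery_date.strftime(fmt),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(names.values())[:5])


def write_dispensing_table(
    records: Iterable[DispensingRecord],
    destination,
    date_dialect: str = "iso",
) -> None:
    """Write records as CSV; reloading yields identical records."""
    frame = records_to_frame(records, date_dialect=date_dialect)
    frame.to_csv(destination, index=False)


def build_timeline(records: Sequence[DispensingRecord]) -> PatientTimeline:
    """Consolidate one patient's records into a :class:`PatientTimeline`.

    The initiation date is the earliest dispense date; same-day events are
    summed (total supply is conserved).  Conflicting anchor dates within a
    patient are an error listing the conflicting values.
    """
    if not records:
        raise DispensingDataError("cannot build a timeline from zero records")
    pids = {r.patient_id for r in records}
    if len(pids) != 1:
        raise DispensingDataError(
            f"records span multiple patients: {sorted(pids)}"
        )
    for field in ("delivery_date", "anc_date"):
        values = {getattr(r, field) for r in records}
        if len(values) != 1:
            raise DispensingDataError(
                f"conflicting {field} values for patient "
                f"{records[0].patient_id!r}: {sorted(map(str, values))}"
            )
    dispensed: dict[dt.date, int] = {}
    for r in records:
        dispensed[r.dispense_date] = dispensed.get(r.dispense_date, 0) + r.days_supplied
    return PatientTimeline(
        patient_id=records[0].patient_id,
        initiation_date=min(dispensed),
        dispensed_by_date=dict(sorted(dispensed.items())),
        anc_date=records[0].anc_date,
        delivery_date=records[0].delivery_date,
    )


def build_timelines(records: Iterable[DispensingRecord]) -> list[PatientTimeline]:
    """Group records by patient and build one timeline per patient."""
    by_patient: dict[str, list[DispensingRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    return [build_timeline(rs) for _, rs in sorted(by_patient.items())]
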