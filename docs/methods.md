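# Methods

## Model

`artpdc` measures adherence to a once-daily fixed-dose antiretroviral
regimen as the proportion of days covered (PDC): the fraction of days in an
observation window on which the patient possesses at least one day of
supply. One dispensing row contributes `daysarvs` days of supply; one day
of supply is consumed per calendar day while any remains. The daily stock
recursion, starting on the initiation date (the earliest dispense date),

    stock[d] = max(stock[d−1] − 1, 0) + dispensed[d]

credits a day's dispensing **before** that day's coverage test, so the
initiation day itself is covered. This convention is forced by the worked
example: the treatment-naive patient's 82 covered days over an 81-day
antenatal treatment span require both her first dispense day (day −81) and
the delivery day (day 0) to count. Early refills therefore stockpile
(leftover supply adds to the new pack), exact refills produce seamless
coverage, and late refills leave zero-stock days. What the printed stock
value means on a refill day (post-credit rather than a
beginning-of-day snapshot, e.g. 92 rather than 2 when a 90-day pack lands
with 2 days left) is a package convention; the covered/uncovered indicator
is unaffected.

Assumptions: one pill = one day of supply (no dose adjustment, splitting or
regimen switching); supply is never discarded; stockpiling is unlimited
unless a `stock_cap` is set (default: no cap — the data give no ceiling);
one delivery anchor per patient per run.

## Windows and metrics

The daily series is re-indexed to day offsets relative to the delivery date
(offset 0 = delivery day, negative = antenatal; default span −280…+365,
conception under a 280-day term through one year postpartum). A window is
an inclusive offset pair plus a divisor; coverage = covered days / divisor,
and the flag is an **inclusive** threshold comparison (default ≥ 0.85).
Days before initiation or beyond the built series read as uncovered.

The default window is the final 24 weeks of pregnancy. "24 weeks = 168
days" and "from day −168 to day 0" cannot both hold for an inclusive span,
and the worked example cannot disambiguate (both conventions reproduce it
exactly — a patient is only affected if covered on day −168 itself). The
default is offsets [−167, 0] with divisor 168, which keeps coverage ≤ 1;
the 169-day variant [−168, 0] with the same divisor is available as
endpoint convention `"169"` (`--endpoint-convention 169` on the CLI).
Postpartum windows (offsets [1, 7w]) reuse the same machinery with the
divisor defaulting to the window length.

`days_on_art_at_delivery` = delivery − initiation in whole days; negative
values (post-delivery initiators) are reported as computed, with a log
warning, never clamped — such women legitimately have zero antenatal
coverage but positive postpartum coverage.

## Input handling

The canonical input is CSV with columns `ID,date,daysarvs,ANCdate,
deliverydate` (aliases configurable); `.dta` files are read via pandas as a
convenience. The date dialect (`iso` default, `dmy` for `18-Jun-15`-style
tables, or any strptime format) is declared by the caller and applied
uniformly — per-cell sniffing of day-first vs month-first dates can shift
events by months and silently corrupt day counts. Validation errors name
the offending row and column. Same-day duplicate dispensings are summed,
conserving total supply. A missing delivery date is permitted only when a
gestational-age column is present; it is imputed as
`ANCdate + (280 − ga_days)` under the 40-week term convention before any
coverage computation. Patient IDs are opaque strings.

## Numerical and implementation choices

The production engine advances the recursion event-by-event: between
dispensings the stock is a unit-slope ramp floored at zero, filled with
vectorized numpy segments. `oracle_daily_stock` executes the identical
contract as a literal one-day-per-iteration pure-Python loop and exists
only as an independent cross-check in the tests; the suite asserts
element-wise equality of the two routes on 1,000+ seeded random histories,
plus conservation (covered days ≤ dispensed days), monotonicity (an extra
dispensing never uncovers a day), translation invariance, the exact-refill
identity, and the closed form `covered_days = min(D, k+1)` for a single
D-day pack dispensed k days before delivery under the default window. All
quantities are integer day counts; the only floating-point value is the
final ratio.

The stock horizon defaults to delivery + 365 days, extended to cover any
later dispensing, so every window inside the default re-indexing span is
supported without recomputation.

## Synthetic cohorts

`generate_cohort` draws patients from the three cascade categories —
treatment-experienced (initiation 1–730 days before conception),
treatment-naive (initiation at the ANC visit), post-delivery initiator
(first dispensing 1–60 days after delivery) — with defaults chosen as
plausible clinic behaviour: category probabilities 0.4 / 0.5 / 0.1;
gestational age at first ANC uniform on 56–252 days (8–36 weeks, spanning
early and late presenters); pack sizes 15/30/60/90/100 days; refill timing
uniform on −14…+14 days around stock exhaustion; deliveries spread over one
calendar year. All draws come from a single seeded numpy Generator consumed
in a fixed order, so tables are byte-reproducible per seed (bit-identity of
draws across numpy versions or other implementations is not promised). The
ground-truth companion is computed with the naive oracle, not the
production engine.

The generator emulates dispensing *geometry* only — visit timing, pack
sizes, category mix. It does not model adherence psychology, regimen
switches, transfers between clinics, data-entry errors or record-linkage
gaps; passing tests on synthetic cohorts demonstrate the accounting is
correct, not that real-world dispensing data are this clean.

## Problem sizes

The test and acceptance workloads are desk-scale by design: the worked
example is 16 rows, property sweeps use 1,000 random patient histories of
one-to-three years each and a 200 × 168 closed-form grid, and the CLI
property run uses a 200-patient cohort. The full suite completes in a few
seconds.

## Known limitations

* One pregnancy per patient per run; repeat pregnancies need separate runs
  with re-assigned anchors.
* No support for regimens other than once-daily fixed-dose combinations.
* The endpoint-convention ambiguity above is inherent to the window
  definition; both conventions are provided, and analyses should state
  which they used.
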