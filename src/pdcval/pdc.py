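"""Gap-adjusted coverage and Proportion of Days Covered (PDC).

PDC is the fraction of days in an observation window on which the patient
had medication supply available, computed from prescription-fill dates and
days supplied.  The rules implemented here:

* **Carry-over** — an early refill does not vanish: its coverage is
  deferred to start the day after the previous supply runs out, so
  overlapping supplies accumulate (stockpiling is uncapped).
* **Switching** — fills are pooled across drug codes within a therapeutic
  class, so a switch (e.g. rosuvastatin to atorvastatin) carries over.
* **Pre-supply look-back** — fills dated in the 90 days before the index
  event contribute the part of their (carry-over adjusted) coverage that
  spills into the observation window.
* **Hospital credit** — days spent in hospital count as covered, because
  in-hospital supply is assumed.
* The numerator is the size of the **union** of supply-covered and
  hospital days, counted at most once per calendar day and capped at the
  denominator, so PDC never exceeds 1 even when a hospital stay overlaps
  supply.
* The denominator is the follow-up time from the index date, capped at
  365 days.

All day windows are inclusive day sets: a fill on date ``d`` with ``s``
days supplied covers ``d .. d+s-1``; the 1-year window is
``index .. index+364`` and the 90-day predictor window ``index .. index+89``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

__all__ = [
    "FillRecord",
    "HospitalStay",
    "CoverageInterval",
    "AdherenceRecord",
    "build_coverage",
    "presupply_credit",
    "compute_adherence",
    "supply_covered_days",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_DAYS = 365
DEFAULT_PREDICTOR_DAYS = 90
DEFAULT_LOOKBACK_DAYS = 90


class InvalidWindowError(ValueError):
    """Observation window ends before it starts."""


@dataclass(frozen=True)
class FillRecord:
    """One prescription fill from a pharmacy-claims table."""

    patient_id: str
    drug_class: str
    drug_code: str
    fill_date: date
    days_supplied: int

    def __post_init__(self) -> None:
        if self.days_supplied < 1:
            raise ValueError(f"days_supplied must be >= 1, got {self.days_supplied}")


@dataclass(frozen=True)
class HospitalStay:
    """One inpatient episode; admit and discharge dates are inclusive."""

    patient_id: str
    admit_date: date
    discharge_date: date

    def __post_init__(self) -> None:
        if self.admit_date > self.discharge_date:
            raise ValueError("admit_date must be <= discharge_date")


@dataclass(frozen=True)
class CoverageInterval:
    """A contiguous run of supply-covered calendar days (inclusive)."""

    start: date
    end: date
    source: str = "post_index_fill"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class AdherenceRecord:
    """Per-patient adherence summary: the 90-day predictor and 1-year PDC.

    ``numerator_days`` and ``denominator_days`` are audit fields;
    ``pdc_1yr == numerator_days / denominator_days`` always holds.
    """

    patient_id: str
    drug_class: str
    days_covered_90: int
    pdc_1yr: float
    numerator_days: int
    denominator_days: int
    presupply_days: int
    hospital_days_credited: int
    user_status: str = "new"


def _carryover_spans(
    fills: Sequence[FillRecord],
) -> list[tuple[int, int]]:
    """Raw carry-over spans as (start_ordinal, end_ordinal), not yet merged.

    Each fill starts at the later of its fill date and the day after the
    previous span's end; sorting by fill date is stable so same-day fills
    queue up deterministically.
    """
    spans: list[tuple[int, int]] = []
    prev_end = None
    for f in sorted(fills, key=lambda f: f.fill_date):
        start = f.fill_date.toordinal()
        if prev_end is not None:
            start = max(start, prev_end + 1)
        end = start + f.days_supplied - 1
        spans.append((start, end))
        prev_end = end
    return spans


def _merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_coverage(
    fills: Sequence[FillRecord],
    horizon_end: date,
    source: str = "post_index_fill",
) -> list[CoverageInterval]:
    """Expand fills of one patient and class into disjoint coverage intervals.

    Fills are pooled across drug codes within the class (switch carry-over)
    and sorted by fill date; each fill's coverage starts at the later of its
    fill date and the day after the previous coverage end and lasts
    ``days_supplied`` days.  The result is a minimal sorted list of disjoint
    intervals truncated at ``horizon_end``.  An empty fill list yields an
    empty list.
    """
    if not fills:
        return []
    horizon = horizon_end.toordinal()
    merged = _merge_spans(_carryover_spans(fills))
    out: list[CoverageInterval] = []
    for s, e in merged:
        if s > horizon:
            break
        out.append(
            CoverageInterval(
                start=date.fromordinal(s),
                end=date.fromordinal(min(e, horizon)),
                source=source,
            )
        )
    return out


def _lookback_fills(
    pre_index_fills: Sequence[FillRecord],
    index_date: date,
    lookback_days: int,
) -> list[FillRecord]:
    lo = index_date - timedelta(days=lookback_days)
    return [f for f in pre_index_fills if lo <= f.fill_date < index_date]


def presupply_credit(
    pre_index_fills: Sequence[FillRecord],
    index_date: date,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> int:
    """Days of pre-index supply carried over into the observation window.

    Only fills dated within ``lookback_days`` before the index date are
    considered; carry-over coverage is built among them and the count of
    covered days falling on or after the index date is returned.
    """
    fills = _lookback_fills(pre_index_fills, index_date, lookback_days)
    if not fills:
        return 0
    idx = index_date.toordinal()
    spans = _merge_spans(_carryover_spans(fills))
    return sum(max(0, e - max(s, idx) + 1) for s, e in spans)


def supply_covered_days(
    fills: Sequence[FillRecord],
    index_date: date,
    window_end: date,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> set[int]:
    """Supply-covered day ordinals inside ``[index_date, window_end]``.

    Pre-index fills contribute only through the look-back rule (fills in
    the ``lookback_days`` window before index, carry-over built among
    themselves); post-index fills contribute through fresh carry-over
    coverage starting at their fill dates.
    """
    idx = index_date.toordinal()
    end = window_end.toordinal()
    pre = [f for f in fills if f.fill_date < index_date]
    post = [f for f in fills if f.fill_date >= index_date]
    days: set[int] = set()
    for f_set in (
        _merge_spans(_carryover_spans(_lookback_fills(pre, index_date, lookback_days))),
        _merge_spans(_carryover_spans(post)),
    ):
        for s, e in f_set:
            lo, hi = max(s, idx), min(e, end)
            if lo <= hi:
                days.update(range(lo, hi + 1))
    return days


def compute_adherence(
    fills: Sequence[FillRecord],
    stays: Sequence[HospitalStay],
    index_date: date,
    end_of_observation: date,
    user_status: str = "new",
    window_days: int = DEFAULT_WINDOW_DAYS,
    predictor_days: int = DEFAULT_PREDICTOR_DAYS,
    lookback_days: int = DEFAULT_LOOKBACK_DAYS,
) -> AdherenceRecord:
    """Compute the 90-day predictor and 1-year PDC for one patient/class.

    ``end_of_observation`` must already be the earliest of index+364,
    death, and administrative end of study (caller's responsibility).

    The denominator is ``min(days from index to end_of_observation
    inclusive, window_days)``.  The numerator is the size of the union of
    pre-supply coverage, post-index carry-over coverage, and hospital days,
    each clipped to the window and each calendar day counted at most once,
    capped at the denominator.
    """
    if end_of_observation < index_date:
        raise InvalidWindowError(
            f"end_of_observation {end_of_observation} precedes index {index_date}"
        )
    idx = index_date.toordinal()
    followup = end_of_observation.toordinal() - idx + 1
    denominator = min(followup, window_days)
    window_end = idx + denominator - 1

    supply = supply_covered_days(
        fills, index_date, date.fromordinal(window_end), lookback_days
    )
    presupply = presupply_credit(
        [f for f in fills if f.fill_date < index_date], index_date, lookback_days
    )
    # presupply coverage beyond the window does not count
    presupply = min(presupply, denominator)

    hospital: set[int] = set()
    for st in stays:
        lo = max(st.admit_date.toordinal(), idx)
        hi = min(st.discharge_date.toordinal(), window_end)
        if lo <= hi:
            hospital.update(range(lo, hi + 1))

    union = supply | hospital
    if len(union) != len(supply) + len(hospital):
        logger.debug(
            "patient %s: hospital stays overlap supply by %d days; union semantics applied",
            fills[0].patient_id if fills else "?",
            len(supply) + len(hospital) - len(union),
        )
    numerator = min(len(union), denominator)

    pred_end = min(idx + predictor_days - 1, window_end)
    days_covered_90 = min(
        sum(1 for d in union if d <= pred_end), predictor_days
    )

    drug_class = fills[0].drug_class if fills else ""
    patient_id = (
        fills[0].patient_id
        if fills
        else (stays[0].patient_id if stays else "")
    )
    return AdherenceRecord(
        patient_id=patient_id,
        drug_class=drug_class,
        days_covered_90=days_covered_90,
        pdc_1yr=numerator / denominator,
        numerator_days=numerator,
        denominator_days=denominator,
        presupply_days=presupply,
        hospital_days_credited=len(hospital),
        user_status=user_status,
    )
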