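"""Eligibility and exclusion rules for the stroke/TIA adherence cohorts.

Starting from index events (first recorded stroke or TIA per patient),
the analysis cohort is built by removing, in a fixed, auditable order:

1. patients under 18 at index,
2. pregnant patients (a per-patient flag covering follow-up),
3. patients who died within 100 days of index (strictly before day 100;
   a death on day 100 survives and instead truncates follow-up),
4. patients who switched health insurer within the first year,

and, for the antiplatelet cohort only,

5. concurrent oral-anticoagulant users,
6. patients with a bleeding event during follow-up.

Every removal is recorded in an :class:`ExclusionLedger` so that
``initial - sum(removed) == final`` holds for every run.

New vs prevalent user status is classified from pre-index fills with a
365-day look-back (the conventional one-year washout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Optional, Sequence

from .pdc import FillRecord

__all__ = [
    "IndexEvent",
    "ExclusionLedger",
    "deduplicate_events",
    "apply_exclusions",
    "classify_user_status",
    "end_of_observation",
]

DRUG_CLASSES = ("statin", "antiplatelet")
EARLY_DEATH_DAYS = 100
INSURER_SWITCH_DAYS = 365
NEW_USER_LOOKBACK_DAYS = 365


@dataclass(frozen=True)
class IndexEvent:
    """The qualifying stroke/TIA event that starts a patient's follow-up."""

    patient_id: str
    index_date: date
    event_type: str = "stroke"
    age: float = 65.0
    pregnant: bool = False
    death_date: Optional[date] = None
    insurer_switch_date: Optional[date] = None
    oac_user: bool = False
    bleeding_event: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.death_date is not None and self.death_date < self.index_date:
            raise ValueError("death_date must be on or after index_date")


@dataclass
class ExclusionLedger:
    """Ordered record of how many patients each rule removed."""

    initial: int
    rows: list[tuple[str, int]] = field(default_factory=list)

    @property
    def final(self) -> int:
        return self.initial - sum(n for _, n in self.rows)

    def to_dict(self) -> dict:
        return {
            "initial": self.initial,
            "removed": [{"rule": r, "count": n} for r, n in self.rows],
            "final": self.final,
        }


def deduplicate_events(events: Sequence[IndexEvent]) -> list[IndexEvent]:
    """Keep one event per patient: the earliest by index date.

    Ties are broken by stable input order (the first record wins).
    """
    best: dict[str, IndexEvent] = {}
    for ev in events:
        prev = best.get(ev.patient_id)
        if prev is None or ev.index_date < prev.index_date:
            best[ev.patient_id] = ev
    # preserve first-seen patient order
    seen: set[str] = set()
    out = []
    for ev in events:
        if ev.patient_id not in seen:
            seen.add(ev.patient_id)
            out.append(best[ev.patient_id])
    return out


def _early_death(ev: IndexEvent) -> bool:
    return (
        ev.death_date is not None
        and (ev.death_date - ev.index_date).days < EARLY_DEATH_DAYS
    )


def _insurer_switch(ev: IndexEvent) -> bool:
    return (
        ev.insurer_switch_date is not None
        and 0 <= (ev.insurer_switch_date - ev.index_date).days < INSURER_SWITCH_DAYS
    )


def apply_exclusions(
    events: Sequence[IndexEvent],
    drug_class: str,
    end_of_study: Optional[date] = None,
    early_death_days: int = EARLY_DEATH_DAYS,
) -> tuple[list[IndexEvent], ExclusionLedger]:
    """Apply the exclusion rules in fixed order and return cohort + ledger.

    ``events`` should already be deduplicated.  ``end_of_study`` is carried
    through for downstream follow-up truncation and does not remove
    patients.  The antiplatelet-specific oral-anticoagulant and bleeding
    rules run only for ``drug_class == "antiplatelet"``.
    """
    if drug_class not in DRUG_CLASSES:
        raise ValueError(
            f"unknown drug_class {drug_class!r}; expected one of {DRUG_CLASSES}"
        )

    rules: list[tuple[str, Callable[[IndexEvent], bool]]] = [
        ("age_under_18", lambda ev: ev.age < 18),
        ("pregnancy", lambda ev: ev.pregnant),
        (
            "death_within_100_days",
            lambda ev: ev.death_date is not None
            and (ev.death_date - ev.index_date).days < early_death_days,
        ),
        ("insurer_switch_within_1_year", _insurer_switch),
    ]
    if drug_class == "antiplatelet":
        rules.append(("oral_anticoagulant_use", lambda ev: ev.oac_user))
        rules.append(("bleeding_event", lambda ev: ev.bleeding_event))

    ledger = ExclusionLedger(initial=len(events))
    cohort = list(events)
    for name, hits in rules:
        removed = [ev for ev in cohort if hits(ev)]
        cohort = [ev for ev in cohort if not hits(ev)]
        ledger.rows.append((name, len(removed)))
    return cohort, ledger


def classify_user_status(
    fills: Sequence[FillRecord],
    index_date: date,
    drug_class: str,
    lookback_days: int = NEW_USER_LOOKBACK_DAYS,
) -> str:
    """'prevalent' iff any fill of the class falls in the year before index.

    The window is ``[index - lookback_days, index - 1]`` (strictly before
    the index date); otherwise the patient is a new user.
    """
    lo = index_date - timedelta(days=lookback_days)
    for f in fills:
        if f.drug_class == drug_class and lo <= f.fill_date < index_date:
            return "prevalent"
    return "new"


def end_of_observation(
    ev: IndexEvent,
    end_of_study: Optional[date] = None,
    window_days: int = 365,
) -> date:
    """Earliest of index+window-1, death, and administrative end of study."""
    end = ev.index_date + timedelta(days=window_days - 1)
    if ev.death_date is not None:
        end = min(end, ev.death_date)
    if end_of_study is not None:
        end = min(end, end_of_study)
    return max(end, ev.index_date)
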