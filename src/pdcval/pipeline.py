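"""End-to-end convenience chain: cohort -> PDC -> prediction -> validation."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from datetime import date
from typing import Optional, Sequence

import numpy as np

from .cohort import (
    IndexEvent,
    apply_exclusions,
    classify_user_status,
    deduplicate_events,
    end_of_observation,
)
from .models import ModelSpec, predict_pdc
from .pdc import AdherenceRecord, FillRecord, HospitalStay, compute_adherence
from .validation import ValidationReport, validate

__all__ = ["cohort_adherence", "run_validation"]


def cohort_adherence(
    events: Sequence[IndexEvent],
    fills: Sequence[FillRecord],
    stays: Sequence[HospitalStay],
    drug_class: str,
    end_of_study: Optional[date] = None,
) -> tuple[list[AdherenceRecord], dict]:
    """Deduplicate, exclude, and compute one AdherenceRecord per survivor."""
    events = deduplicate_events(events)
    cohort, ledger = apply_exclusions(events, drug_class, end_of_study)
    fills_by_pid: dict[str, list[FillRecord]] = defaultdict(list)
    for f in fills:
        if f.drug_class == drug_class:
            fills_by_pid[f.patient_id].append(f)
    stays_by_pid: dict[str, list[HospitalStay]] = defaultdict(list)
    for s in stays:
        stays_by_pid[s.patient_id].append(s)

    records = []
    for ev in cohort:
        pfills = fills_by_pid.get(ev.patient_id, [])
        rec = compute_adherence(
            pfills,
            stays_by_pid.get(ev.patient_id, []),
            ev.index_date,
            end_of_observation(ev, end_of_study),
            user_status=classify_user_status(pfills, ev.index_date, drug_class),
        )
        # patients with no fills/stays still get a (zero-coverage) record
        records.append(
            replace(rec, patient_id=ev.patient_id, drug_class=drug_class)
        )
    return records, ledger.to_dict()


def run_validation(
    records: Sequence[AdherenceRecord],
    model: ModelSpec,
    n_bins: int = 10,
) -> ValidationReport:
    """Predict from the 90-day predictor and validate against observed PDC."""
    observed = np.array([r.pdc_1yr for r in records])
    predicted = predict_pdc(model, np.array([r.days_covered_90 for r in records]))
    return validate(observed, predicted, n_bins=n_bins)
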