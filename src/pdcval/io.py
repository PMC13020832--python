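"""Reading and writing the pipeline's delimited-text tables.

All tables are headed CSV with ISO-8601 (YYYY-MM-DD) dates:

* ``fills.csv``  — patient_id, drug_class, drug_code, fill_date, days_supplied
* ``stays.csv``  — patient_id, admit_date, discharge_date
* ``index.csv``  — patient_id, index_date, event_type, age, pregnant,
  death_date, insurer_switch_date, oac_user, bleeding_event (optional
  dates empty when absent)
* ``cohort.csv`` — surviving index events plus end_of_observation and
  user_status
* ``adherence.csv`` — one AdherenceRecord per patient and class
"""

from __future__ import annotations

from dataclasses import asdict
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cohort import IndexEvent
from .pdc import AdherenceRecord, FillRecord, HospitalStay

__all__ = [
    "read_fills",
    "read_stays",
    "read_index",
    "write_cohort",
    "read_cohort",
    "write_adherence",
    "read_adherence",
]


def _parse_date(value) -> Optional[date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return date.fromisoformat(str(value))


def read_fills(path: str | Path) -> list[FillRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return [
        FillRecord(
            patient_id=row.patient_id,
            drug_class=row.drug_class,
            drug_code=str(row.drug_code),
            fill_date=date.fromisoformat(row.fill_date),
            days_supplied=int(row.days_supplied),
        )
        for row in df.itertuples()
    ]


def read_stays(path: str | Path) -> list[HospitalStay]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    return [
        HospitalStay(
            patient_id=row.patient_id,
            admit_date=date.fromisoformat(row.admit_date),
            discharge_date=date.fromisoformat(row.discharge_date),
        )
        for row in df.itertuples()
    ]


def read_index(path: str | Path) -> list[IndexEvent]:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    return [
        IndexEvent(
            patient_id=row.patient_id,
            index_date=date.fromisoformat(row.index_date),
            event_type=row.event_type,
            age=float(row.age),
            pregnant=str(row.pregnant) == "True",
            death_date=_parse_date(row.death_date),
            insurer_switch_date=_parse_date(row.insurer_switch_date),
            oac_user=str(row.oac_user) == "True",
            bleeding_event=str(row.bleeding_event) == "True",
        )
        for row in df.itertuples()
    ]


def write_cohort(
    events: Sequence[IndexEvent],
    end_dates: Sequence[date],
    statuses: Sequence[str],
    path: str | Path,
) -> None:
    pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "index_date": [e.index_date.isoformat() for e in events],
            "end_of_observation": [d.isoformat() for d in end_dates],
            "user_status": list(statuses),
        }
    ).to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["index_date"] = df["index_date"].map(date.fromisoformat)
    df["end_of_observation"] = df["end_of_observation"].map(date.fromisoformat)
    return df


def write_adherence(records: Sequence[AdherenceRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def read_adherence(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})
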