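from __future__ import annotations

from datetime import date, timedelta

import pytest

from pdcval import FillRecord, builtin_models

INDEX = date(2016, 1, 1)


def day(offset: int) -> date:
    """Calendar date at a day offset from the fixture index date."""
    return INDEX + timedelta(days=offset)


def fill(offset: int, supply: int, code: str = "atorvastatin", pid: str = "p1") -> FillRecord:
    return FillRecord(
        patient_id=pid,
        drug_class="statin",
        drug_code=code,
        fill_date=day(offset),
        days_supplied=supply,
    )


def pill_stock_days(fills) -> set[int]:
    """Brute-force coverage oracle: a day-by-day pill-stock simulation.

    Every fill adds its supply to a stock; each day with positive stock
    consumes one pill and counts as covered.  No interval arithmetic.
    """
    if not fills:
        return set()
    additions: dict[int, int] = {}
    for f in fills:
        d = f.fill_date.toordinal()
        additions[d] = additions.get(d, 0) + f.days_supplied
    d = min(additions)
    last = max(additions)
    stock = 0
    covered: set[int] = set()
    while stock > 0 or d <= last:
        stock += additions.get(d, 0)
        if stock > 0:
            covered.add(d)
            stock -= 1
        d += 1
    return covered


@pytest.fixture(scope="session")
def statin_model():
    return builtin_models()[0]


@pytest.fixture(scope="session")
def antiplatelet_model():
    return builtin_models()[1]
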