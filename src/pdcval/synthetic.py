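"""Synthetic pharmacy-claims cohorts for adherence-pipeline testing.

Real claims registries behind adherence studies are not public, so this
module generates inputs with the statistical structure the analysis
assumes, at two levels:

* :func:`generate_outcome_pairs` draws (predictor, outcome) pairs directly
  from the beta-regression data-generating process that the prediction
  models describe — the generative inverse of the model being validated —
  for metric-recovery tests.
* :func:`generate_fill_histories` simulates full prescription-fill
  histories (index events, refill renewal processes with gaps, switching,
  pre-index supply, hospital stays, deaths and exclusion-triggering
  attributes) for end-to-end pipeline tests, together with a per-patient
  ground-truth set of supply-covered days computed by day-by-day stock
  simulation, independent of the interval arithmetic it is used to check.

Default parameters emulate a post-stroke secondary-prevention cohort:
~94% one-month refill cycles with the remainder on 2–3-month cycles, a
U-shaped adherence-propensity distribution producing heavy mass at zero
days covered and near-complete coverage, ~35% prevalent statin users, and
occasional hospitalizations and deaths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

from .cohort import IndexEvent
from .models import ModelSpec
from .pdc import FillRecord, HospitalStay

__all__ = [
    "SimulationConfig",
    "FillHistories",
    "generate_outcome_pairs",
    "generate_fill_histories",
    "write_outputs",
]

EPOCH = date(2016, 1, 1)

DRUG_CODES = {
    "statin": ("atorvastatin", "rosuvastatin", "simvastatin", "pravastatin"),
    "antiplatelet": ("aspirin", "clopidogrel"),
}


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


def _default_exclusion_rates() -> dict[str, float]:
    # roughly the per-rule removal fractions seen in stroke/TIA claims cohorts
    return {
        "under_18": 0.004,
        "pregnancy": 0.004,
        "death_100": 0.010,
        "insurer_switch": 0.010,
        "oac_user": 0.091,
        "bleeding": 0.0005,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``refill_cycle_probs`` maps days-supplied per fill to its probability;
    the default 94.2% / 3.1% / 2.7% split over 30/60/90-day supplies
    mirrors a system where monthly dispensing dominates.  Adherence
    propensity is Beta(``propensity_alpha``, ``propensity_beta``) per
    patient (a zero value for either shape parameter degenerates to a
    point mass at 0 or 1, handy for edge-case tests).
    """

    n_patients: int = 2000
    drug_class: str = "statin"
    refill_cycle_probs: Mapping[int, float] = field(
        default_factory=lambda: {30: 0.942, 60: 0.031, 90: 0.027}
    )
    propensity_alpha: float = 0.55
    propensity_beta: float = 0.45
    initial_fill_prob: float = 0.85
    discontinuation_rate: float = 0.001
    switch_prob: float = 0.05
    prevalent_fraction: float = 0.353
    hospitalization_rate: float = 0.30
    mean_stay_days: float = 6.0
    mean_fill_delay_days: float = 1.5
    late_death_rate: float = 0.021
    exclusion_rates: Mapping[str, float] = field(
        default_factory=_default_exclusion_rates
    )
    beta_precision: float = 3.0
    predictor_mixture: tuple[float, float, float] = (0.30, 0.45, 0.25)
    zero_outcome_prob: float = 0.5
    index_spread_days: int = 1950
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be >= 1")
        if self.beta_precision <= 0:
            raise InvalidConfigError("beta_precision must be positive")
        probs = list(self.refill_cycle_probs.values())
        if abs(sum(probs) - 1.0) > 1e-9:
            raise InvalidConfigError("refill_cycle_probs must sum to 1")
        if any(not 0 <= p <= 1 for p in probs):
            raise InvalidConfigError("refill_cycle_probs must lie in [0, 1]")
        if abs(sum(self.predictor_mixture) - 1.0) > 1e-9:
            raise InvalidConfigError("predictor_mixture must sum to 1")
        for name in (
            "initial_fill_prob",
            "switch_prob",
            "prevalent_fraction",
            "zero_outcome_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        for name in (
            "discontinuation_rate",
            "hospitalization_rate",
            "late_death_rate",
            "propensity_alpha",
            "propensity_beta",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if any(not 0 <= r <= 1 for r in self.exclusion_rates.values()):
            raise InvalidConfigError("exclusion_rates must lie in [0, 1]")
        if self.drug_class not in DRUG_CODES:
            raise InvalidConfigError(f"unknown drug_class {self.drug_class!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def generate_outcome_pairs(
    model: ModelSpec, config: SimulationConfig
) -> list[tuple[int, float]]:
    """Draw (days_covered_90, observed 1-year PDC) pairs from the model's DGP.

    The predictor is an integer in [0, 90] from a three-part mixture: a
    point mass at 0, a near-ceiling block on 85–90, and a uniform spread
    over 1–84, weighted by ``config.predictor_mixture`` (chosen so the
    default median and IQR resemble a real claims cohort).  The outcome is
    beta-distributed with mean ``inverse-logit(intercept + slope * x)`` and
    precision φ (shapes mean*φ and (1-mean)*φ).

    Never-takers: patients with x = 0 receive outcome exactly 0 with
    probability ``zero_outcome_prob``; the continuous component's mean is
    rescaled to ``mu / (1 - p0)`` so the conditional mean at x = 0 still
    follows the model and calibration metrics recover their ideal values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    phi = config.beta_precision
    w0, w_mid, _ = config.predictor_mixture

    u = rng.random(n)
    x = np.zeros(n, dtype=int)
    mid = (u >= w0) & (u < w0 + w_mid)
    hi = u >= w0 + w_mid
    x[mid] = rng.integers(1, 85, size=int(mid.sum()))
    x[hi] = rng.integers(85, 91, size=int(hi.sum()))

    mu = expit(model.intercept + model.slope * x)
    y = rng.beta(mu * phi, (1 - mu) * phi)

    p0 = config.zero_outcome_prob
    zero = x == 0
    if p0 > 0 and zero.any():
        mu0 = float(expit(model.intercept))
        mu0c = mu0 / (1 - p0) if p0 < 1 else 1.0
        if mu0c >= 1:
            raise InvalidConfigError(
                "zero_outcome_prob too large: rescaled mean at x=0 reaches 1"
            )
        n0 = int(zero.sum())
        is_zero = rng.random(n0) < p0
        y0 = rng.beta(mu0c * phi, (1 - mu0c) * phi, size=n0)
        y0[is_zero] = 0.0
        y[zero] = y0

    return list(zip(x.tolist(), y.tolist()))


@dataclass
class FillHistories:
    """Raw synthetic inputs plus the generator's ground-truth coverage."""

    fills: list[FillRecord]
    stays: list[HospitalStay]
    index_events: list[IndexEvent]
    truth: dict[str, list[str]]  # patient_id -> ISO dates of supply-covered days


def _stock_covered_days(day_supplies: Sequence[tuple[int, int]]) -> set[int]:
    """Day-by-day pill-stock simulation: the brute-force coverage oracle.

    Each fill adds its supply to a stock; every day with positive stock
    consumes one pill and is covered.  Equivalent to uncapped carry-over,
    but computed without interval arithmetic.
    """
    if not day_supplies:
        return set()
    additions: dict[int, int] = {}
    for d, s in day_supplies:
        additions[d] = additions.get(d, 0) + s
    day = min(additions)
    last_fill = max(additions)
    stock = 0
    covered: set[int] = set()
    while stock > 0 or day <= last_fill:
        stock += additions.get(day, 0)
        if stock > 0:
            covered.add(day)
            stock -= 1
        day += 1
    return covered


def _truth_days(
    fills: Sequence[FillRecord],
    index_ord: int,
    lookback_days: int = 90,
    window_days: int = 365,
) -> list[int]:
    """Intended supply-covered day ordinals in the 1-year window.

    Post-index fills contribute via stock simulation from the index on;
    pre-index fills only if dated within the look-back window, their stock
    coverage clipped to on-or-after index.
    """
    window_end = index_ord + window_days - 1
    pre = [
        (f.fill_date.toordinal(), f.days_supplied)
        for f in fills
        if index_ord - lookback_days <= f.fill_date.toordinal() < index_ord
    ]
    post = [
        (f.fill_date.toordinal(), f.days_supplied)
        for f in fills
        if f.fill_date.toordinal() >= index_ord
    ]
    days = {
        d
        for d in _stock_covered_days(pre) | _stock_covered_days(post)
        if index_ord <= d <= window_end
    }
    return sorted(days)


def _geometric_delay(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean))) - 1


def _propensity(rng: np.random.Generator, alpha: float, beta: float) -> float:
    if alpha == 0 and beta == 0:
        raise InvalidConfigError("propensity_alpha and propensity_beta cannot both be 0")
    if alpha == 0:
        return 0.0
    if beta == 0:
        return 1.0
    return float(rng.beta(alpha, beta))


def generate_fill_histories(config: SimulationConfig) -> FillHistories:
    """Simulate per-patient index events, fills, hospital stays and truth.

    Fills follow a renewal process: an initiating fill on the index date
    (realized with ``initial_fill_prob``), then refills scheduled every
    cycle length, each realized with the patient's adherence propensity and
    delayed by a geometric lag, until discontinuation, death, or the end of
    the 1-year window.  Prevalent users also receive pre-index fills on the
    same renewal process, some of which land inside the 90-day look-back.
    Identical seeds produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    cycles = np.array(sorted(config.refill_cycle_probs), dtype=int)
    cycle_p = np.array([config.refill_cycle_probs[c] for c in cycles], dtype=float)
    codes = DRUG_CODES[config.drug_class]
    excl = {**_default_exclusion_rates(), **dict(config.exclusion_rates)}

    fills: list[FillRecord] = []
    stays: list[HospitalStay] = []
    events: list[IndexEvent] = []
    truth: dict[str, list[str]] = {}

    for i in range(config.n_patients):
        pid = f"p{i:05d}"
        index_off = int(rng.integers(0, config.index_spread_days))
        index_date = EPOCH + timedelta(days=index_off)
        index_ord = index_date.toordinal()
        cycle = int(rng.choice(cycles, p=cycle_p))
        prop = _propensity(rng, config.propensity_alpha, config.propensity_beta)

        if rng.random() < excl["under_18"]:
            age = int(rng.integers(1, 18))
        else:
            age = int(np.clip(round(rng.normal(70, 12)), 18, 100))
        pregnant = bool(rng.random() < excl["pregnancy"])
        u = rng.random()
        death_off: Optional[int] = None
        if u < excl["death_100"]:
            death_off = int(rng.integers(0, 100))
        elif u < excl["death_100"] + config.late_death_rate:
            death_off = int(rng.integers(100, 365))
        switch_off: Optional[int] = (
            int(rng.integers(0, 365)) if rng.random() < excl["insurer_switch"] else None
        )
        event = IndexEvent(
            patient_id=pid,
            index_date=index_date,
            event_type="stroke" if rng.random() < 0.7 else "TIA",
            age=age,
            pregnant=pregnant,
            death_date=index_date + timedelta(days=death_off)
            if death_off is not None
            else None,
            insurer_switch_date=index_date + timedelta(days=switch_off)
            if switch_off is not None
            else None,
            oac_user=bool(rng.random() < excl["oac_user"]),
            bleeding_event=bool(rng.random() < excl["bleeding"]),
        )
        events.append(event)

        code = str(rng.choice(codes))
        patient_fills: list[FillRecord] = []

        def add_fill(offset: int, c: str) -> str:
            if rng.random() < config.switch_prob:
                others = [x for x in codes if x != c]
                c = str(rng.choice(others)) if others else c
            patient_fills.append(
                FillRecord(
                    patient_id=pid,
                    drug_class=config.drug_class,
                    drug_code=c,
                    fill_date=index_date + timedelta(days=offset),
                    days_supplied=cycle,
                )
            )
            return c

        # pre-index renewal process for prevalent users
        if rng.random() < config.prevalent_fraction:
            start = -int(rng.integers(cycle, 366))
            s, first = start, True
            while s <= -1:
                if first or rng.random() < prop:
                    d = s + _geometric_delay(rng, config.mean_fill_delay_days)
                    if d <= -1:
                        code = add_fill(d, code)
                first = False
                s += cycle

        # post-index renewal process
        stop = 364
        if death_off is not None:
            stop = min(stop, death_off)
        if config.discontinuation_rate > 0:
            stop = min(stop, int(rng.exponential(1.0 / config.discontinuation_rate)))
        if rng.random() < config.initial_fill_prob:
            sched, first = 0, True
            while sched <= stop:
                take = first or rng.random() < prop
                if take:
                    d = sched + (0 if first else _geometric_delay(rng, config.mean_fill_delay_days))
                    if d > stop:
                        break
                    code = add_fill(d, code)
                    sched = d + cycle
                else:
                    sched += cycle
                first = False

        fills.extend(patient_fills)

        n_stays = int(rng.poisson(config.hospitalization_rate))
        for _ in range(n_stays):
            admit_off = int(rng.integers(0, 365))
            if death_off is not None and admit_off > death_off:
                continue
            los = int(rng.geometric(1.0 / max(config.mean_stay_days, 1.0)))
            discharge_off = admit_off + los - 1
            if death_off is not None:
                discharge_off = min(discharge_off, death_off)
            stays.append(
                HospitalStay(
                    patient_id=pid,
                    admit_date=index_date + timedelta(days=admit_off),
                    discharge_date=index_date + timedelta(days=discharge_off),
                )
            )

        truth[pid] = [
            date.fromordinal(d).isoformat()
            for d in _truth_days(patient_fills, index_ord)
        ]

    return FillHistories(fills=fills, stays=stays, index_events=events, truth=truth)


def write_outputs(hist: FillHistories, outdir: str | Path) -> None:
    """Write fills.csv, stays.csv, index.csv and truth.json to a directory."""
    import pandas as pd

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": f.patient_id,
                "drug_class": f.drug_class,
                "drug_code": f.drug_code,
                "fill_date": f.fill_date.isoformat(),
                "days_supplied": f.days_supplied,
            }
            for f in hist.fills
        ],
        columns=["patient_id", "drug_class", "drug_code", "fill_date", "days_supplied"],
    ).to_csv(out / "fills.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "admit_date": s.admit_date.isoformat(),
                "discharge_date": s.discharge_date.isoformat(),
            }
            for s in hist.stays
        ],
        columns=["patient_id", "admit_date", "discharge_date"],
    ).to_csv(out / "stays.csv", index=False)
    pd.DataFrame(
        [
            {
                "patient_id": ev.patient_id,
                "index_date": ev.index_date.isoformat(),
                "event_type": ev.event_type,
                "age": ev.age,
                "pregnant": ev.pregnant,
                "death_date": ev.death_date.isoformat() if ev.death_date else "",
                "insurer_switch_date": ev.insurer_switch_date.isoformat()
                if ev.insurer_switch_date
                else "",
                "oac_user": ev.oac_user,
                "bleeding_event": ev.bleeding_event,
            }
            for ev in hist.index_events
        ],
        columns=[
            "patient_id",
            "index_date",
            "event_type",
            "age",
            "pregnant",
            "death_date",
            "insurer_switch_date",
            "oac_user",
            "bleeding_event",
        ],
    ).to_csv(out / "index.csv", index=False)
    (out / "truth.json").write_text(json.dumps(hist.truth))
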