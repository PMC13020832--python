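"""Coverage interval arithmetic and PDC computation."""

from __future__ import annotations

from datetime import timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdcval import (
    HospitalStay,
    build_coverage,
    compute_adherence,
    presupply_credit,
    supply_covered_days,
)
from pdcval.pdc import InvalidWindowError

from conftest import INDEX, day, fill, pill_stock_days


def interval_days(intervals) -> set[int]:
    out: set[int] = set()
    for iv in intervals:
        out.update(range(iv.start.toordinal(), iv.end.toordinal() + 1))
    return out


class TestBuildCoverage:
    @pytest.mark.parametrize(
        "fills, expected_spans",
        [
            # early refill: carry-over defers the second fill, one merged run
            ([(0, 30), (20, 30)], [(0, 59)]),
            # late refill: a 10-day gap splits coverage
            ([(0, 30), (40, 30)], [(0, 29), (40, 69)]),
            # single fill
            ([(0, 30)], [(0, 29)]),
            # same-day double fill stockpiles
            ([(0, 30), (0, 30)], [(0, 59)]),
            # switch between drug codes within class carries over
            ([(0, 30), (25, 30)], [(0, 59)]),
        ],
    )
    def test_matches_day_by_day_oracle(self, fills, expected_spans):
        recs = [fill(off, s) for off, s in fills]
        got = build_coverage(recs, day(2000))
        assert [
            (iv.start.toordinal() - INDEX.toordinal(), iv.end.toordinal() - INDEX.toordinal())
            for iv in got
        ] == expected_spans
        assert interval_days(got) == pill_stock_days(recs)

    def test_switching_pools_codes(self):
        recs = [fill(0, 30, code="atorvastatin"), fill(25, 30, code="rosuvastatin")]
        got = build_coverage(recs, day(2000))
        assert len(got) == 1 and got[0].n_days == 60

    def test_empty_fills_empty_intervals(self):
        assert build_coverage([], day(100)) == []

    def test_truncation_at_horizon(self):
        got = build_coverage([fill(0, 30)], day(9))
        assert len(got) == 1 and got[0].n_days == 10

    def test_total_days_before_truncation_is_sum_of_supply(self):
        recs = [fill(0, 30), fill(5, 60), fill(7, 90)]
        got = build_coverage(recs, day(5000))
        assert sum(iv.n_days for iv in got) == 180

    @given(
        fills=st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 90)),
            min_size=1,
            max_size=15,
        )
    )
    @settings(deadline=None, max_examples=200)
    def test_property_equals_pill_stock_oracle(self, fills):
        recs = [fill(off, s) for off, s in fills]
        got = build_coverage(recs, day(5000))
        assert interval_days(got) == pill_stock_days(recs)
        # intervals are disjoint, sorted, minimal
        for a, b in zip(got, got[1:]):
            assert a.end.toordinal() + 1 < b.start.toordinal()

    @given(
        fills=st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 90)), min_size=1, max_size=10
        ),
        seed=st.integers(0, 100),
    )
    @settings(deadline=None, max_examples=100)
    def test_permutation_invariance(self, fills, seed):
        import random

        recs = [fill(off, s) for off, s in fills]
        shuffled = recs[:]
        random.Random(seed).shuffle(shuffled)
        assert build_coverage(recs, day(5000)) == build_coverage(shuffled, day(5000))


class TestPresupplyCredit:
    @pytest.mark.parametrize(
        "fills, expected",
        [
            ([(-15, 30)], 15),  # half the supply spills past index
            ([(-91, 30)], 0),  # outside the 90-day look-back
            ([(-60, 30), (-30, 30)], 0),  # tiling ends the day before index
            ([(-90, 30)], 0),  # boundary fill, fully pre-index
            ([(-1, 90)], 89),  # near-index fill carries most supply over
            ([(-30, 30), (-15, 30)], 30),  # carry-over chain crosses index
            ([], 0),
        ],
    )
    def test_examples(self, fills, expected):
        recs = [fill(off, s) for off, s in fills]
        assert presupply_credit(recs, INDEX) == expected


class TestComputeAdherence:
    def test_single_fill_new_user(self):
        rec = compute_adherence([fill(0, 30)], [], INDEX, day(364))
        assert rec.days_covered_90 == 30
        assert rec.numerator_days == 30
        assert rec.denominator_days == 365
        assert rec.pdc_1yr == pytest.approx(30 / 365)

    def test_hospital_days_add_to_numerator(self):
        stay = HospitalStay("p1", day(100), day(109))
        rec = compute_adherence([fill(0, 30)], [stay], INDEX, day(364))
        assert rec.numerator_days == 40
        assert rec.hospital_days_credited == 10
        assert rec.pdc_1yr == pytest.approx(40 / 365)

    def test_perfect_adherer_with_overlapping_stay_caps_at_one(self):
        fills = [fill(30 * k, 30) for k in range(13)]
        stay = HospitalStay("p1", day(50), day(70))
        rec = compute_adherence(fills, [stay], INDEX, day(364))
        assert rec.pdc_1yr == 1.0
        assert rec.numerator_days == rec.denominator_days == 365

    def test_presupply_counts_once_against_same_day_fill(self):
        # pre-index supply spilling over plus an index-day fill: the union
        # counts each calendar day once, and carry-over defers nothing pre-index
        recs = [fill(-15, 30), fill(0, 30)]
        rec = compute_adherence(recs, [], INDEX, day(364))
        assert rec.presupply_days == 15
        # presupply covers days 0-14, index fill covers 0-29: union is 30 days
        assert rec.numerator_days == 30

    def test_death_shortens_denominator(self):
        rec = compute_adherence([fill(0, 30)], [], INDEX, day(199))
        assert rec.denominator_days == 200
        assert rec.pdc_1yr == pytest.approx(30 / 200)

    def test_invalid_window_raises(self):
        with pytest.raises(InvalidWindowError):
            compute_adherence([fill(0, 30)], [], INDEX, INDEX - timedelta(days=1))

    def test_predictor_window_is_first_90_days(self):
        rec = compute_adherence([fill(85, 30)], [], INDEX, day(364))
        assert rec.days_covered_90 == 5  # days 85-89 fall inside the window
        assert rec.numerator_days == 30

    @given(
        fills=st.lists(
            st.tuples(st.integers(0, 364), st.integers(1, 90)), min_size=0, max_size=12
        ),
        extra=st.tuples(st.integers(0, 364), st.integers(1, 90)),
        stay=st.tuples(st.integers(0, 364), st.integers(1, 20)),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotonicity_adding_fill_or_stay(self, fills, extra, stay):
        recs = [fill(off, s) for off, s in fills]
        base = compute_adherence(recs, [], INDEX, day(364))
        more = compute_adherence(recs + [fill(*extra)], [], INDEX, day(364))
        assert more.numerator_days >= base.numerator_days
        assert more.days_covered_90 >= base.days_covered_90
        st_rec = HospitalStay("p1", day(stay[0]), day(min(stay[0] + stay[1] - 1, 364)))
        with_stay = compute_adherence(recs, [st_rec], INDEX, day(364))
        assert with_stay.numerator_days >= base.numerator_days

    @given(
        fills=st.lists(
            st.tuples(st.integers(-120, 364), st.integers(1, 90)),
            min_size=0,
            max_size=12,
        ),
        end_off=st.integers(100, 364),
    )
    @settings(deadline=None, max_examples=150)
    def test_bounds_and_window_consistency(self, fills, end_off):
        recs = [fill(off, s) for off, s in fills]
        rec = compute_adherence(recs, [], INDEX, day(end_off))
        assert 0.0 <= rec.pdc_1yr <= 1.0
        assert rec.numerator_days <= rec.denominator_days
        assert rec.days_covered_90 <= min(90, rec.denominator_days)
        if rec.denominator_days >= 90:
            assert rec.days_covered_90 <= rec.numerator_days
        assert rec.pdc_1yr == pytest.approx(rec.numerator_days / rec.denominator_days)


class TestSupplyCoveredDays:
    def test_lookback_boundary_excludes_old_fills(self):
        # a fill outside the look-back cannot chain supply into the window
        recs = [fill(-95, 90), fill(-60, 90)]
        got = supply_covered_days(recs, INDEX, day(364))
        # only the -60 fill counts: carry-over from its own date, 90 days
        assert got == set(range(INDEX.toordinal(), INDEX.toordinal() + 30))
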