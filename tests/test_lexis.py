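"""Person-time splitting and stratum tabulation."""
import datetime as dt

import numpy as np
import pandas as pd
import pytest

import occmort as om
from occmort.cohort import DAYS_PER_YEAR
from tests.conftest import make_record


def day_count_oracle(age, years, bands):
    """Brute-force: walk the follow-up day by day, splitting each day's
    sliver of age across bands exactly."""
    edges = [b.lower for b in sorted(bands)] + [sorted(bands)[-1].upper]
    totals = {b.lower: 0.0 for b in bands}
    totals["overflow"] = 0.0
    days = int(round(years * 365.25))
    for d in range(days):
        t0, t1 = d / 365.25, (d + 1) / 365.25
        a_lo, a_hi = age + t0, age + t1
        for lo, hi in zip(edges[:-1], edges[1:]):
            ov = min(a_hi, hi) - max(a_lo, lo)
            if ov > 0:
                totals[lo] += ov
        if a_hi > edges[-1]:
            totals["overflow"] += a_hi - max(a_lo, edges[-1])
    return totals


class TestSplitPersonTime:
    def test_partition_across_one_boundary_with_death(self):
        rec = make_record(23.0, 6.2, died=True)
        parts = om.split_person_time(rec)
        got = {(b.lower, b.upper): (py, d) for b, py, d in parts}
        py20 = got[(20.0, 25.0)][0]
        py25 = got[(25.0, 30.0)][0]
        assert py20 == pytest.approx(2.0, abs=0.01)  # exact up to day rounding
        assert py25 == pytest.approx(4.2, abs=0.01)
        assert got[(20.0, 25.0)][1] is False
        assert got[(25.0, 30.0)][1] is True

    def test_censoring_splits_without_death(self):
        rec = make_record(40.0, 10.0, died=False)
        parts = om.split_person_time(rec)
        assert [(b.lower, round(py, 2), d) for b, py, d in parts] == [
            (40.0, 5.0, False), (45.0, 5.0, False)
        ]

    def test_total_person_time_conserved(self):
        rec = make_record(33.7, 9.3, died=True)
        parts = om.split_person_time(rec)
        assert sum(py for _, py, _ in parts) == pytest.approx(
            rec.follow_up_years, abs=1e-12)

    def test_overflow_routed_to_catch_all_with_warning(self):
        rec = make_record(63.0, 10.0, died=True, soc="")
        with pytest.warns(UserWarning, match="70"):
            parts = om.split_person_time(rec)
        assert np.isinf(sorted(parts)[-1][0].upper)
        # death is attributed to the catch-all band (last with time)
        assert parts[-1][2] is True

    def test_matches_day_count_oracle_on_random_records(self):
        rng = np.random.default_rng(42)
        bands = om.default_bands()
        for _ in range(25):
            age = rng.uniform(20, 60)
            years = rng.uniform(0.1, 10)
            rec = make_record(age, years, died=False)
            with pytest.warns(UserWarning) if age + years > 70 else _nullcontext():
                parts = om.split_person_time(rec, bands)
            oracle = day_count_oracle(age, rec.follow_up_years, bands)
            for band, py, _ in parts:
                key = band.lower if np.isfinite(band.upper) else "overflow"
                assert py == pytest.approx(oracle[key], abs=1e-9)

    def test_subinterval_additivity(self):
        # splitting the follow-up at an arbitrary date and summing the two
        # halves reproduces the whole
        rec = make_record(28.0, 8.0, died=False)
        first = make_record(28.0, 3.0, died=False)
        cut = 28.0 + first.follow_up_years
        second = make_record(cut, rec.follow_up_years - first.follow_up_years,
                             died=False)
        whole = {b.lower: py for b, py, _ in om.split_person_time(rec)}
        partial = {}
        for r in (first, second):
            for b, py, _ in om.split_person_time(r):
                partial[b.lower] = partial.get(b.lower, 0.0) + py
        assert set(whole) == set(partial)
        for k in whole:
            assert whole[k] == pytest.approx(partial[k], abs=1e-9)

    def test_baseline_basis_attributes_everything_to_entry_band(self):
        rec = make_record(23.0, 6.2, died=True)
        parts = om.split_person_time(rec, age_basis="baseline")
        assert len(parts) == 1
        band, py, died = parts[0]
        assert (band.lower, band.upper) == (20.0, 25.0)
        assert py == pytest.approx(rec.follow_up_years)
        assert died


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


class TestTabulate:
    def test_single_record_matches_split(self, two_group_scheme):
        rec = make_record(23.0, 6.2, died=True)
        frame = pd.DataFrame([{
            "person_id": rec.person_id, "sex": rec.sex,
            "age_at_census": rec.age_at_census, "soc_code": rec.soc_code,
            "geography": rec.geography, "entry_date": rec.entry_date,
            "exit_date": rec.exit_date, "died": int(rec.died),
        }])
        tab = om.tabulate(frame, two_group_scheme)
        split = {b.lower: (py, d) for b, py, d in om.split_person_time(rec)}
        assert len(tab) == len(split)
        for row in tab.itertuples(index=False):
            py, d = split[row.band_lower]
            assert row.person_years == pytest.approx(py, abs=1e-12)
            assert row.deaths == int(d)

    def test_conservation_on_simulated_cohort(self, two_group_scheme):
        cfg = om.SimulationConfig(
            sex="male", geography="EW", n=10_000,
            groups=[om.GroupSpec("821", 0.7, 700, "821"),
                    om.GroupSpec("none", 0.3, 1200, None)],
        )
        coh = om.simulate_cohort(cfg, seed=9)
        tab = om.tabulate(coh, two_group_scheme)
        days = (coh["exit_date"] - coh["entry_date"]).map(lambda d: d.days)
        assert tab["person_years"].sum() == pytest.approx(
            days.sum() / DAYS_PER_YEAR, rel=1e-12)
        assert tab["deaths"].sum() == coh["died"].sum()

    def test_totals_invariant_under_regrouping(self, small_cohort_frame):
        fine = om.GroupingScheme([
            om.OccupationGroup("821", "Drivers", frozenset({"821"})),
            om.OccupationGroup("none", "None", frozenset(),
                               includes_no_occupation=True),
        ])
        # no-occupation kept separate but occupation codes pooled into "8"
        coarse = om.GroupingScheme([
            om.OccupationGroup("8", "Operatives", frozenset({"8"})),
            om.OccupationGroup("none", "None", frozenset(),
                               includes_no_occupation=True),
        ])
        ta = om.tabulate(small_cohort_frame, fine)
        tb = om.tabulate(small_cohort_frame, coarse)
        assert ta["person_years"].sum() == pytest.approx(
            tb["person_years"].sum(), rel=1e-12)
        assert ta["deaths"].sum() == tb["deaths"].sum()

    def test_empty_cohort_gives_empty_table(self, two_group_scheme):
        empty = pd.DataFrame(columns=[
            "person_id", "sex", "age_at_census", "soc_code", "geography",
            "entry_date", "exit_date", "died"])
        assert om.tabulate(empty, two_group_scheme).empty

    def test_uncovered_code_propagates_error(self, small_cohort_frame,
                                             two_group_scheme):
        bad = small_cohort_frame.copy()
        bad.loc[0, "soc_code"] = "999"
        with pytest.raises(ValueError, match="999"):
            om.tabulate(bad, two_group_scheme)

    def test_vectorised_matches_per_record_split(self, two_group_scheme):
        cfg = om.SimulationConfig(
            sex="male", geography="EW", n=400,
            groups=[om.GroupSpec("821", 0.5, 2000, "821"),
                    om.GroupSpec("none", 0.5, 2000, None)],
        )
        coh = om.simulate_cohort(cfg, seed=21)
        tab = om.tabulate(coh, two_group_scheme)
        from occmort.cohort import records_from_frame
        agg = {}
        for rec in records_from_frame(coh):
            gid = two_group_scheme.assign(rec.soc_code)
            for b, py, d in om.split_person_time(rec):
                key = (gid, b.lower)
                p, dd = agg.get(key, (0.0, 0))
                agg[key] = (p + py, dd + int(d))
        assert len(tab) == len(agg)
        for row in tab.itertuples(index=False):
            p, d = agg[(row.group_id, row.band_lower)]
            assert row.person_years == pytest.approx(p, abs=1e-9)
            assert row.deaths == d
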