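import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import peakeffort as pe
from peakeffort.lifehistory import histories_to_frame


def _history(fid, cohort, pups_by_age, recruits_by_age=None):
    recruits_by_age = recruits_by_age or [0] * len(pups_by_age)
    recs = tuple(
        pe.AnnualRecord(fid, cohort, cohort + a + 1, p, r)
        for a, (p, r) in enumerate(zip(pups_by_age, recruits_by_age))
    )
    return pe.FemaleLifeHistory(fid, cohort, len(pups_by_age), recs)


class TestSummarizeFemale:
    def test_first_attainment_and_totals(self, calendar):
        s = pe.summarize_female(_history("A", 1990, [2, 4, 4, 1]), calendar)
        assert s.peak_effort == 4
        assert s.peak_age == 2                 # first attainment, not the tie
        assert s.lifetime_pups == 11
        assert s.post_peak_pups == 5
        assert s.post_peak_lifespan == 2
        assert s.pre_peak_rate == 2.0          # 2 pups over 1 pre-peak year
        assert s.primiparity == 1

    def test_single_event_female_lifetime_equals_peak(self, calendar):
        s = pe.summarize_female(_history("B", 1992, [5]), calendar)
        assert s.peak_effort == s.lifetime_pups == 5
        assert s.pre_peak_rate == 0.0
        assert s.post_peak_lifespan == 0
        assert s.n_breeding_years == 1

    def test_non_breeder_flagged(self, calendar):
        s = pe.summarize_female(_history("C", 1995, [0, 0]), calendar)
        assert not s.is_breeder
        assert math.isnan(s.prop_recruited)

    def test_delayed_primiparity(self, calendar):
        s = pe.summarize_female(_history("D", 1990, [0, 3, 1]), calendar)
        assert s.primiparity == 0
        assert s.peak_age == 2

    def test_mast_exposure_variables(self, calendar):
        # cohort 1992: ages 1..4 are 1993-1996, so the 1993 mast is age 1
        s = pe.summarize_female(_history("E", 1992, [1, 2, 2, 1]), calendar)
        assert s.experienced_mast and s.age_at_mast == 1.0
        assert s.mast_peak is False            # peak age 2 = 1994, non-mast
        t = pe.summarize_female(_history("F", 1992, [3, 1, 1, 1]), calendar)
        assert t.mast_peak is True             # peak age 1 = 1993 mast
        u = pe.summarize_female(_history("G", 1999, [1, 2]), calendar)
        assert not u.experienced_mast and math.isnan(u.age_at_mast)

    def test_order_insensitive_to_record_permutation(self, calendar):
        recs = [pe.AnnualRecord("H", 1990, 1990 + a, p, 0)
                for a, p in [(1, 2), (2, 4), (3, 1)]]
        h1 = pe.FemaleLifeHistory("H", 1990, 3, tuple(recs))
        h2 = pe.FemaleLifeHistory("H", 1990, 3, tuple(reversed(recs)))
        assert pe.summarize_female(h1, calendar) == pe.summarize_female(h2, calendar)


@settings(deadline=None, max_examples=60)
@given(pups=st.lists(st.integers(0, 12), min_size=1, max_size=9))
def test_summary_axioms_hold_for_arbitrary_records(pups):
    calendar = pe.study_calendar()
    s = pe.summarize_female(_history("X", 1990, pups), calendar)
    assert s.lifetime_pups >= s.peak_effort
    assert 1 <= s.peak_age <= s.lifespan
    assert s.post_peak_lifespan == s.lifespan - s.peak_age
    assert s.lifetime_pups == sum(pups)
    # prepending a larger earlier peak strictly decreases peak_age
    if s.is_breeder and s.peak_age > 1:
        boosted = [s.peak_effort + 1] + pups[1:]
        s2 = pe.summarize_female(_history("X", 1990, boosted), calendar)
        assert s2.peak_age == 1 < s.peak_age


def test_conservation_between_annual_and_summary(small_population):
    summ = small_population["summaries"]
    frame = histories_to_frame(small_population["histories"])
    assert summ["lifetime_pups"].sum() == frame["pups"].sum()
    assert summ["lifetime_recruits"].sum() == frame["recruits"].sum()


def test_analysis_sets_partition(small_population, toy_histories, calendar):
    sets = small_population["sets"]
    full, mast, never = (sets["full_set"], sets["mast_experienced_set"],
                         sets["never_mast_set"])
    assert len(mast) + len(never) == len(full)
    assert set(mast["female_id"]).isdisjoint(never["female_id"])
    assert full["is_breeder"].all()
    assert set(sets["multi_year_set"]["female_id"]) <= set(full["female_id"])
    # toy: one of three females never bred
    toy_sets = pe.build_analysis_sets(pe.summarize_females(toy_histories, calendar))
    assert len(toy_sets["full_set"]) == 2


class TestAnnualTable:
    def test_tie_years_both_flagged(self, calendar):
        tab = pe.annual_table([_history("T", 1990, [3, 3])], calendar)
        assert tab["is_peak_year"].tolist() == [1, 1]

    def test_every_breeder_has_a_peak_year(self, small_population):
        tab = small_population["annual"]
        breeders = set(
            small_population["sets"]["full_set"]["female_id"])
        flags = tab[tab["female_id"].isin(breeders)].groupby("female_id")[
            "is_peak_year"].sum()
        assert (flags >= 1).all()

    def test_row_count_and_mast_flags(self, small_population, calendar):
        tab = small_population["annual"]
        hists = small_population["histories"]
        assert len(tab) == sum(len(h.records) for h in hists)
        assert (tab["is_mast"] == tab["year"].isin(calendar.mast_years)).all()


class TestScaling:
    def test_three_point_example(self):
        scaled, info = pe.scale_predictors([1.0, 2.0, 3.0])
        np.testing.assert_allclose(scaled, [-1.0, 0.0, 1.0])
        assert info.mean == 2.0 and info.sd == 1.0    # sample (n-1) sd

    def test_round_trip_and_moments(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(3.0, 2.0, 200)
        scaled, info = pe.scale_predictors(x)
        assert abs(scaled.mean()) < 1e-12
        assert abs(scaled.std(ddof=1) - 1.0) < 1e-12
        np.testing.assert_allclose(info.unscale(scaled), x, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            pe.scale_predictors([4.0, 4.0, 4.0])


def test_records_frame_round_trip(toy_histories):
    frame = histories_to_frame(toy_histories)
    back = pe.frame_to_histories(frame)
    assert sorted(h.female_id for h in back) == ["A", "B", "C"]
    pd.testing.assert_frame_equal(histories_to_frame(back), frame)


def test_invalid_records_rejected():
    with pytest.raises(ValueError):
        pe.AnnualRecord("A", 1990, 1991, 2, 3)       # recruits > pups
    with pytest.raises(ValueError):
        pe.AnnualRecord("A", 1990, 1990, 1, 0)       # breeding at age 0
    rec = pe.AnnualRecord("A", 1990, 1991, 1, 0)
    with pytest.raises(ValueError):
        pe.FemaleLifeHistory("A", 1990, 3, (rec, rec))   # duplicate year


def test_xlsx_reader_with_column_map(tmp_path, toy_histories):
    openpyxl = pytest.importorskip("openpyxl")  # noqa: F841
    frame = histories_to_frame(toy_histories).rename(columns={
        "female_id": "squirrel_id", "cohort": "byear", "year": "yr",
        "pups": "n_pups", "recruits": "n_recruits"})
    path = tmp_path / "deposit.xlsx"
    frame.drop(columns=["age"]).to_excel(path, index=False)
    got = pe.read_records_xlsx(path, {
        "squirrel_id": "female_id", "byear": "cohort", "yr": "year",
        "n_pups": "pups", "n_recruits": "recruits"})
    pd.testing.assert_frame_equal(
        got.sort_values(["female_id", "year"]).reset_index(drop=True),
        histories_to_frame(toy_histories))
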