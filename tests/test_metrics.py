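"""Descriptive resight metrics against hand-enumerated oracles."""

import datetime as dt

import pandas as pd
import pytest

from photoid import (FlankCatalogue, SiteSpec, WorldConfig,
                     build_flank_views, cross_site_matches,
                     max_consecutive_years, mean_years_observed,
                     min_travel_speed, proportion_resighted_per_year,
                     sex_composition, simulate_world, site_year_summaries,
                     years_observed_distribution)

from conftest import rec


class TestSiteYearSummaries:
    def test_toy_catalogue_hand_enumeration(self, toy_view):
        s = site_year_summaries(toy_view).set_index("year")
        assert s.loc[2005, ["n_unique", "n_new", "n_resight"]].tolist() == [1, 1, 0]
        assert s.loc[2006, ["n_unique", "n_new", "n_resight"]].tolist() == [2, 1, 1]

    def test_repeat_encounters_count_once_per_year(self):
        view = FlankCatalogue("LB", [rec("A", "n", f"2006-0{m}-01")
                                     for m in range(1, 4)])
        s = site_year_summaries(view)
        assert s["n_unique"].tolist() == [1]

    def test_unique_equals_new_plus_resight_everywhere(self, two_site_world):
        records, _ = two_site_world
        lb, _ = build_flank_views(records)
        s = site_year_summaries(lb)
        assert (s["n_unique"] == s["n_new"] + s["n_resight"]).all()

    def test_first_year_has_no_resights(self, two_site_world):
        records, _ = two_site_world
        lb, _ = build_flank_views(records)
        s = site_year_summaries(lb)
        firsts = s.loc[s.groupby("site")["year"].idxmin()]
        assert (firsts["n_resight"] == 0).all()

    def test_new_counts_sum_to_unique_individuals(self, two_site_world):
        records, _ = two_site_world
        lb, _ = build_flank_views(records)
        s = site_year_summaries(lb)
        per_site_ids = {}
        for r in lb.records:
            per_site_ids.setdefault(r.site, set()).add(r.individual_id)
        for site, grp in s.groupby("site"):
            assert grp["n_new"].sum() == len(per_site_ids[site])

    def test_empty_year_range_rejected(self, toy_view):
        with pytest.raises(ValueError):
            site_year_summaries(toy_view, year_range=(2010, 2005))

    def test_certain_sighting_unique_equals_population(self):
        config = WorldConfig(
            sites=[SiteSpec("only", 60, 1.0, flank_probs=(1.0, 0.0, 0.0))],
            years=(2005, 2008), seed=1)
        records, _ = simulate_world(config)
        lb, _ = build_flank_views(records)
        s = site_year_summaries(lb)
        assert (s["n_unique"] == 60).all()


class TestProportionResighted:
    def test_toy_catalogue(self, toy_view):
        props = proportion_resighted_per_year(site_year_summaries(toy_view))
        assert len(props) == 1
        assert props.iloc[0]["year"] == 2006
        assert props.iloc[0]["prop_resight"] == 0.5

    def test_single_year_site_excluded(self):
        view = FlankCatalogue("LB", [rec("A", "n", "2006-01-01")])
        props = proportion_resighted_per_year(site_year_summaries(view))
        assert props.empty

    def test_everyone_resighted_gives_one(self):
        view = FlankCatalogue("LB", [rec("A", "n", f"{y}-06-01")
                                     for y in (2005, 2006, 2007)])
        props = proportion_resighted_per_year(site_year_summaries(view))
        assert (props["prop_resight"] == 1.0).all()


class TestYearsObserved:
    def _view(self):
        # 10 individuals over 2005-2010: I1 all 6 years; I2 five years;
        # I3-I4 two years; I5-I10 one year each (hand-countable).
        records = []
        for y in range(2005, 2011):
            records.append(rec("I1", "n", f"{y}-03-01"))
        for y in range(2005, 2010):
            records.append(rec("I2", "n", f"{y}-03-01"))
        for iid in ("I3", "I4"):
            records.append(rec(iid, "n", "2005-03-01"))
            records.append(rec(iid, "n", "2007-03-01"))
        for i, y in zip(range(5, 11), range(2005, 2011)):
            records.append(rec(f"I{i}", "n", f"{y}-03-01"))
        return FlankCatalogue("LB", records)

    def test_hand_count_with_pooling(self):
        table = years_observed_distribution(self._view(), {"n": (2005, 2010)})
        assert table.loc["n"].to_dict() == {
            "1": 6, "2": 2, "3": 0, "4": 0, "5-6": 2}
        assert table.loc["n"].sum() == 10

    def test_hand_count_without_pooling(self):
        table = years_observed_distribution(self._view(), {"n": (2005, 2010)},
                                            pool_top=False)
        assert table.loc["n"].to_dict() == {
            "1": 6, "2": 2, "3": 0, "4": 0, "5": 1, "6": 1}

    def test_full_window_individual_lands_in_top_category(self):
        view = FlankCatalogue("LB", [rec("A", "n", f"{y}-01-01")
                                     for y in range(2005, 2011)])
        table = years_observed_distribution(view, {"n": (2005, 2010)})
        assert table.loc["n", "5-6"] == 1

    def test_window_outside_sampled_years_names_site(self):
        with pytest.raises(ValueError, match="n:"):
            years_observed_distribution(self._view(), {"n": (2006, 2011)})

    def test_window_must_span_six_years(self):
        with pytest.raises(ValueError):
            years_observed_distribution(self._view(), {"n": (2005, 2009)})


class TestMeanYearsObserved:
    def test_two_individuals_mean(self):
        records = [rec("A", "n", "2005-01-01")]
        records += [rec("B", "n", f"{y}-01-01") for y in (2005, 2006, 2007)]
        out = mean_years_observed(FlankCatalogue("LB", records))
        assert out.iloc[0]["mean_years"] == 2.0

    def test_all_single_year_has_zero_se(self):
        records = [rec(f"X{i}", "n", "2005-01-01") for i in range(5)]
        out = mean_years_observed(FlankCatalogue("LB", records))
        assert out.iloc[0]["mean_years"] == 1.0
        assert out.iloc[0]["se_years"] == 0.0

    def test_toy_catalogue(self, toy_view):
        out = mean_years_observed(toy_view)
        assert out.iloc[0]["mean_years"] == pytest.approx(1.5)  # A:2, B:1


class TestMaxConsecutiveYears:
    @pytest.mark.parametrize("years,expected", [
        ((2005, 2006, 2007, 2010), 3),
        ((2005,), 1),
        ((2005, 2007, 2009), 1),
    ])
    def test_run_lengths(self, years, expected):
        view = FlankCatalogue("LB", [rec("A", "n", f"{y}-01-01") for y in years])
        assert max_consecutive_years(view)["A"] == expected

    def test_runs_do_not_bridge_sites(self):
        view = FlankCatalogue("LB", [rec("A", "n", "2005-01-01"),
                                     rec("A", "s", "2006-01-01"),
                                     rec("A", "n", "2007-01-01")])
        assert max_consecutive_years(view)["A"] == 1

    def test_matches_truth_on_certain_sighting_world(self):
        config = WorldConfig(sites=[SiteSpec("only", 30, 1.0)],
                             years=(2005, 2009), seed=2)
        records, _ = simulate_world(config)
        lb, _ = build_flank_views(records)
        runs = max_consecutive_years(lb)
        # everyone present and photographed every year (both-flank records
        # are in LB by construction when flank prob both > 0) — but LB only
        # holds left-inclusive records, so runs are <= 5 and individuals with
        # all-left/both years reach 5
        assert max(runs.values()) <= 5


class TestCrossSiteMatches:
    def test_zero_migration_world_has_no_matches(self, two_site_world):
        records, _ = two_site_world
        lb, rb = build_flank_views(records)
        assert cross_site_matches(lb) == []
        assert cross_site_matches(rb) == []

    def test_planted_migrant_found_with_speed(self):
        view = FlankCatalogue("LB", [
            rec("M", "mozambique", "2005-11-20"),
            rec("M", "mozambique", "2010-01-25"),
            rec("M", "seychelles", "2010-09-03"),
            rec("X", "mozambique", "2010-02-01"),
        ])
        matches = cross_site_matches(
            view, distances_km={("mozambique", "seychelles"): 3000.0})
        assert len(matches) == 1
        m = matches[0]
        assert m.individual_id == "M"
        assert m.first_leg == ("mozambique", "seychelles")
        assert m.elapsed_days == 221
        assert round(m.speed_km_per_day, 1) == 13.6

    def test_single_site_individual_excluded(self, toy_view):
        assert cross_site_matches(toy_view) == []


class TestMinTravelSpeed:
    @pytest.mark.parametrize("d,days,expected", [
        (3000, 221, 13.6), (100, 8, 12.5), (42, 42, 1.0)])
    def test_values(self, d, days, expected):
        assert round(min_travel_speed(d, days), 1) == expected

    @pytest.mark.parametrize("d,days", [(0, 10), (10, 0), (-5, 3)])
    def test_nonpositive_rejected(self, d, days):
        with pytest.raises(ValueError):
            min_travel_speed(d, days)


class TestSexComposition:
    def test_all_male(self):
        view = FlankCatalogue("LB", [rec(f"A{i}", "n", "2006-01-01", sex="male")
                                     for i in range(4)])
        out = sex_composition(view).set_index("site")
        assert out.loc["n", ["male", "female", "indeterminate"]].tolist() == [1, 0, 0]

    def test_fixture_truth_recovered(self):
        records = []
        for i in range(39):
            records.append(rec(f"M{i}", "n", "2006-01-01", sex="male"))
        for i in range(14):
            records.append(rec(f"F{i}", "n", "2006-01-01", sex="female"))
        for i in range(47):
            records.append(rec(f"I{i}", "n", "2006-01-01", sex="indeterminate"))
        out = sex_composition(FlankCatalogue("LB", records)).set_index("site")
        assert out.loc["n", "male"] == pytest.approx(0.39)

    def test_indeterminate_upgraded_by_later_record(self):
        view = FlankCatalogue("LB", [
            rec("A", "n", "2005-01-01", sex="indeterminate"),
            rec("A", "n", "2006-01-01", sex="male"),
        ])
        out = sex_composition(view).set_index("site")
        assert out.loc["n", "male"] == 1.0

    def test_proportions_sum_to_one(self, two_site_world):
        records, _ = two_site_world
        lb, _ = build_flank_views(records)
        out = sex_composition(lb)
        import numpy as np

        assert np.allclose(out["male"] + out["female"] + out["indeterminate"], 1.0)
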