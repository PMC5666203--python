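"""Counterfactual expected-deaths engine."""
import numpy as np
import pandas as pd
import pytest

import occmort as om


def rate_table(rows):
    return pd.DataFrame(
        rows, columns=["group_id", "label", "rate", "se"])


class TestBuildPopulation:
    def test_proportional_split(self):
        pop = om.build_population({"a": 75.0, "b": 25.0}, 1000.0)
        assert pop.persons.to_dict() == {"a": 750.0, "b": 250.0}
        assert pop.total == pytest.approx(1000.0)

    def test_single_group_gets_everything(self):
        pop = om.build_population({"a": 42.0}, 5_000.0)
        assert pop.persons["a"] == pytest.approx(5_000.0)

    def test_zero_total_py_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            om.build_population({"a": 0.0}, 1000.0)

    def test_shares_match_generator_prevalences(self):
        # population shares recovered from a simulated cohort's person-years
        prevs = {"821": 0.55, "none": 0.45}
        cfg = om.SimulationConfig(
            sex="male", geography="SCO", n=30_000,
            groups=[om.GroupSpec("821", prevs["821"], 600, "821"),
                    om.GroupSpec("none", prevs["none"], 1100, None)],
        )
        coh = om.simulate_cohort(cfg, seed=13)
        scheme = om.GroupingScheme([
            om.OccupationGroup("821", "Drivers", frozenset({"821"}), "male"),
            om.OccupationGroup("none", "None", frozenset(), "male",
                               includes_no_occupation=True),
        ])
        strata = om.tabulate(coh, scheme)
        py = strata.groupby("group_id")["person_years"].sum()
        pop = om.build_population(py, 1_000_000.0)
        for gid, share in prevs.items():
            # person-years shares are close to prevalences (slightly
            # distorted by differential mortality); 1.5 points is ample
            assert pop.persons[gid] / pop.total == pytest.approx(
                share, abs=0.015)


class TestExpectedDeaths:
    def test_rate_times_population(self):
        pop = om.SyntheticPopulation(pd.Series({"a": 50_000.0, "b": 50_000.0}))
        d = om.expected_deaths(pop, rate_table([("a", "A", 300.0, 10.0),
                                                ("b", "B", 500.0, 10.0)]))
        assert d.to_dict() == {"a": 150.0, "b": 250.0}
        assert d.sum() == pytest.approx(400.0)

    def test_zero_population_group(self):
        pop = om.SyntheticPopulation(pd.Series({"a": 0.0, "b": 100_000.0}))
        d = om.expected_deaths(pop, rate_table([("a", "A", 300.0, 10.0),
                                                ("b", "B", 500.0, 10.0)]))
        assert d["a"] == 0.0

    def test_missing_rate_group_excluded_with_warning(self):
        pop = om.SyntheticPopulation(pd.Series({"a": 1000.0, "b": 1000.0}))
        with pytest.warns(UserWarning, match="'b'"):
            d = om.expected_deaths(pop, rate_table([("a", "A", 300.0, 10.0)]))
        assert list(d.index) == ["a"]


class TestRunScenario:
    def two_group_setup(self):
        pop = om.SyntheticPopulation(pd.Series({"a": 50_000.0, "b": 50_000.0}))
        base = rate_table([("a", "A", 300.0, 20.0), ("b", "B", 500.0, 30.0)])
        cf = rate_table([("a", "A", 250.0, 15.0), ("b", "B", 400.0, 25.0)])
        return pop, base, cf

    def test_self_scenario_is_exactly_zero(self):
        pop, base, _ = self.two_group_setup()
        res = om.run_scenario(pop, base, base.copy(), n_sim=500, seed=3)
        assert (res.table["change"] == 0).all()
        assert res.total_change == 0.0
        assert res.total_change_ci == (0.0, 0.0)

    def test_degenerate_uncertainty_pins_the_interval(self):
        pop, base, cf = self.two_group_setup()
        base["se"] = 1e-12
        cf["se"] = 1e-12
        res = om.run_scenario(pop, base, cf, n_sim=500, seed=3)
        assert res.total_change == pytest.approx(-75.0, abs=1e-6)
        assert res.total_change_ci[0] == pytest.approx(-75.0, abs=1e-6)
        assert res.total_change_ci[1] == pytest.approx(-75.0, abs=1e-6)

    def test_mean_change_matches_closed_form(self):
        pop, base, cf = self.two_group_setup()
        res = om.run_scenario(pop, base, cf, n_sim=100_000, seed=5)
        # E[delta_g] = (rate'_g - rate_g) * P_g / 1e5 = -25, -50
        closed = {"a": -25.0, "b": -50.0}
        for row in res.table.itertuples(index=False):
            se_delta = np.sqrt(0.02**2 + 0.03**2) * 50_000 / 1e5  # loose
            assert row.change == pytest.approx(closed[row.group_id], abs=1.0)

    def test_totals_add_up_exactly(self):
        pop, base, cf = self.two_group_setup()
        res = om.run_scenario(pop, base, cf, n_sim=2_000, seed=7)
        assert res.total_change == pytest.approx(
            res.table["change"].sum(), abs=1e-9)
        assert res.total_baseline == pytest.approx(
            res.table["expected_baseline"].sum(), abs=1e-12)

    def test_doubling_population_doubles_changes(self):
        pop, base, cf = self.two_group_setup()
        double = om.SyntheticPopulation(pop.persons * 2)
        r1 = om.run_scenario(pop, base, cf, n_sim=2_000, seed=11)
        r2 = om.run_scenario(double, base, cf, n_sim=2_000, seed=11)
        assert np.allclose(r2.table["change"], 2 * r1.table["change"])
        assert r2.total_change == pytest.approx(2 * r1.total_change)
        assert r2.total_change_ci[0] == pytest.approx(
            2 * r1.total_change_ci[0])

    def test_uniformly_lower_rates_reduce_deaths(self):
        pop, base, cf = self.two_group_setup()
        res = om.run_scenario(pop, base, cf, n_sim=20_000, seed=2)
        assert res.total_change < 0
        assert res.total_change_ci[1] < 0  # clearly below zero here

    def test_groups_missing_in_one_table_dropped_like_for_like(self):
        pop = om.SyntheticPopulation(
            pd.Series({"a": 1000.0, "b": 1000.0, "c": 1000.0}))
        base = rate_table([("a", "A", 300.0, 20.0), ("b", "B", 500.0, 30.0),
                           ("c", "C", 400.0, 30.0)])
        cf = rate_table([("a", "A", 250.0, 15.0), ("b", "B", 400.0, 25.0)])
        with pytest.warns(UserWarning, match="'c'"):
            res = om.run_scenario(pop, base, cf, n_sim=500, seed=1)
        assert set(res.table["group_id"]) == {"a", "b"}

    def test_no_shared_groups_raises(self):
        pop = om.SyntheticPopulation(pd.Series({"a": 1000.0}))
        base = rate_table([("x", "X", 300.0, 20.0)])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no group"):
                om.run_scenario(pop, base, base, n_sim=500, seed=1)
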