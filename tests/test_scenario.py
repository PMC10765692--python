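"""Demand construction, allocation, species change and orchestration."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcbs import carbon_dynamics as cd
from fcbs import scenario as sc
from fcbs.forest_state import ForestState, Region, StandCohort, YieldCurve, YieldCurveSet
from fcbs.pools import MERCH, PoolVector

PARAMS = cd.default_params()
REGION = Region("R1", "one", 500.0, "Fir", 2030, True)
OAK_REGION = Region("R2", "two", 350.0, "Oak", 2025, False)


class TestCalamityFit:
    def test_noiseless_recovery(self):
        years = np.arange(2012, 2022)
        series = list(zip(years, 35.0 * np.exp(-((years - 2020.0) ** 2) / 8.0)))
        fit = sc.fit_calamity_curve(series)
        assert fit.amplitude == pytest.approx(35.0, abs=1e-6)
        assert fit.peak_year == pytest.approx(2020.0, abs=1e-6)
        assert fit.width == pytest.approx(2.0, abs=1e-6)

    def test_symmetric_series_centres_on_axis(self):
        years = np.arange(2015, 2024)
        vols = np.exp(-((years - 2019.0) ** 2) / 3.0) * 10.0
        fit = sc.fit_calamity_curve(list(zip(years, vols)))
        assert fit.peak_year == pytest.approx(2019.0, abs=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(0)
        years = np.arange(2012, 2022)
        truth = 35.0 * np.exp(-((years - 2020.0) ** 2) / 8.0)
        noisy = truth + rng.normal(0.0, 0.05 * 35.0, size=len(years))
        fit = sc.fit_calamity_curve(list(zip(years, noisy)))
        assert fit.amplitude == pytest.approx(35.0, rel=0.10)
        assert fit.peak_year == pytest.approx(2020.0, rel=0.10)
        assert fit.width == pytest.approx(2.0, rel=0.10)

    def test_degenerate_series_flagged(self):
        fit = sc.fit_calamity_curve([(y, 0.0) for y in range(2012, 2022)])
        assert fit.degenerate
        assert fit.amplitude == 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sc.fit_calamity_curve([(2012, 1.0), (2013, 2.0)])


class TestExtrapolateDemand:
    def test_direct_evaluation_and_decline(self):
        fit = sc.CalamityCurveFit("R1", 30.0, 2020.0, 2.0, 0.0)
        out = sc.extrapolate_demand({"R1": fit}, range(2022, 2031))
        assert out[(2026, "R1")] == pytest.approx(30.0 * np.exp(-4.5))
        vals = [out[(y, "R1")] for y in range(2022, 2031)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(v >= 0 for v in vals)

    def test_zero_amplitude_floors(self):
        fit = sc.CalamityCurveFit("R1", 0.0, 2020.0, 1.0, 0.0, degenerate=True)
        out = sc.extrapolate_demand({"R1": fit}, [2025], floors={"R1": 4.2})
        assert out[(2025, "R1")] == 4.2


class TestInterpolateShares:
    def test_equal_endpoints_constant(self):
        s = {"a": 0.7, "b": 0.3}
        for year in (2021, 2024, 2028, 2031):
            out = sc.interpolate_shares(s, s, year)
            assert out == pytest.approx(s)

    def test_midpoint_is_normalised_geometric_mean(self):
        start = {"a": 0.8, "b": 0.2}
        end = {"a": 0.2, "b": 0.8}
        out = sc.interpolate_shares(start, end, 2026)
        ga = np.sqrt(0.8 * 0.2)
        gb = np.sqrt(0.2 * 0.8)
        assert out["a"] == pytest.approx(ga / (ga + gb))
        assert out["b"] == pytest.approx(gb / (ga + gb))

    def test_boundaries_hit_exactly(self):
        start = {"a": 0.6, "b": 0.4}
        end = {"a": 0.1, "b": 0.9}
        assert sc.interpolate_shares(start, end, 2021) == pytest.approx(start)
        assert sc.interpolate_shares(start, end, 2031) == pytest.approx(end)

    def test_zero_start_share_floored(self):
        out = sc.interpolate_shares({"a": 0.0, "b": 1.0},
                                    {"a": 0.5, "b": 0.5}, 2026)
        assert 0.0 < out["a"] < 0.5

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            sc.interpolate_shares({"a": 1.0}, {"b": 1.0}, 2025)


def single_cohort_state(age=120, merch_ha=50.0, area=100.0, retained=False,
                        ft="SP"):
    pv = PoolVector()
    pv["merch_stem"] = merch_ha
    c = StandCohort("R1", ft, age, area, pv, retained=retained)
    return ForestState([c], {"R1": REGION})


FLAT_CURVES = YieldCurveSet({ft: YieldCurve(ft, [0, 100], [0, 400])
                             for ft in ("SP", "PI", "BE", "OA", "LLB", "SLB",
                                        "AA")})


class TestSustainablePotential:
    def test_no_eligible_stock_gives_nothing(self):
        # age 70: past the thinning window, and rotation age stays out of
        # reach within the 20-yr planning window
        state = single_cohort_state(age=70, merch_ha=5.0)
        assert sc.sustainable_potential(state, FLAT_CURVES) == {}

    def test_amortisation_oracle(self):
        # 100 ha x 50 t C/ha eligible merch over a 20-yr window
        state = single_cohort_state(age=120, merch_ha=50.0, area=100.0)
        pot = sc.sustainable_potential(state, FLAT_CURVES, window=20)
        assert pot[("R1", "SP")] == pytest.approx(250.0)

    def test_retained_cohorts_excluded(self):
        state = single_cohort_state(age=120, retained=True)
        assert sc.sustainable_potential(state, FLAT_CURVES) == {}

    def test_non_decreasing_on_growing_default_state(self, default_dataset):
        state = default_dataset["state"].copy()
        curves = default_dataset["curves"]
        prev = None
        for _ in range(8):
            total = sum(sc.sustainable_potential(state, curves).values())
            if prev is not None:
                assert total >= prev - 1e-6
            prev = total
            for c in state.cohorts:
                cd.step_cohort(c, curves[c.forest_type], PARAMS)


class TestDemandSchedule:
    def test_known_years_match_observations_for_all_scenarios(
            self, mini_spun, mini_curves, mini_obs):
        obs = mini_obs
        expected = {}
        for row in obs[obs["year"].between(2018, 2021)].itertuples():
            key = (int(row.year), row.region_id, row.forest_type,
                   str(row.dist_id))
            expected[key] = expected.get(key, 0.0) + (
                row.volume_mm3 * 1e6 * PARAMS.density(row.forest_type))
        schedules = {
            name: sc.build_demand_schedule(mk(), mini_spun, obs, mini_curves)
            for name, mk in sc.SCENARIOS.items()
        }
        for name, sched in schedules.items():
            got = {k: v for k, v in sched.data.items() if 2018 <= k[0] <= 2021}
            assert set(got) == set(expected), name
            for k in expected:
                assert got[k] == pytest.approx(expected[k], rel=1e-9), (name, k)

    def test_green_potential_regime_respects_target_and_cap(self, default_dataset):
        # static schedule: demand equals the potential where it is below
        # the 17 Mm3 target, and never exceeds the target
        d = default_dataset
        sched = sc.build_demand_schedule(sc.green(), d["state"], d["obs"],
                                         d["curves"])
        pot = sc.sustainable_potential(d["state"], d["curves"])
        pot_vol = sum(v / PARAMS.density(ft) for (_, ft), v in pot.items()) / 1e6
        for year in (2035, 2050, 2070):
            vol = sum(v / PARAMS.density(ft) / 1e6
                      for (y, r, ft, dd), v in sched.data.items() if y == year)
            assert vol == pytest.approx(min(17.0, pot_vol), rel=1e-6)

    def test_green_live_run_demand_reaches_target(self, default_runs):
        # with the potential recomputed annually, the growing stock lets
        # the demand reach the 17 Mm3 guiding level by mid-century
        for year in (2050, 2060, 2070):
            r = next(x for x in default_runs["green"] if x.year == year)
            vol = sum(v / PARAMS.density(ft) / 1e6
                      for (d, ft), v in r.demand.items())
            assert vol == pytest.approx(17.0, rel=0.01)

    def test_blackrep_episode_uses_mean_2018_2019_levels(
            self, mini_spun, mini_curves, mini_obs):
        sched = sc.build_demand_schedule(sc.black_rep(), mini_spun, mini_obs,
                                         mini_curves)
        obs = mini_obs
        sp = obs[(obs["forest_type"] == "SP") & (obs["year"].isin([2018, 2019]))
                 & (obs["dist_id"].isin(["2", "3a", "3b", "4"]))]
        for rid in mini_spun.regions:
            mean_mm3 = (sp[sp["region_id"] == rid]
                        .groupby("year")["volume_mm3"].sum()
                        .reindex([2018, 2019], fill_value=0.0).mean())
            expected = mean_mm3 * 1e6 * PARAMS.density("SP")
            got = sum(sched.data.get((2048, rid, "SP", d), 0.0)
                      for d in ("3a", "3b"))
            assert got == pytest.approx(expected, rel=1e-9)
            # episode harvest is sanitary only
            assert (2048, rid, "SP", "4") not in sched.data

    def test_blackrep_escalation_multiplies_planned_demand(self, default_dataset):
        d = default_dataset
        sched_b = sc.build_demand_schedule(sc.black(), d["state"], d["obs"],
                                           d["curves"])
        sched_r = sc.build_demand_schedule(sc.black_rep(), d["state"], d["obs"],
                                           d["curves"])
        year = 2050  # inside the +15% escalation period, outside episodes
        base = sum(v for (y, r, ft, dd), v in sched_b.data.items()
                   if y == year and ft == "OA" and dd in ("2", "4"))
        esc = sum(v for (y, r, ft, dd), v in sched_r.data.items()
                  if y == year and ft == "OA" and dd in ("2", "4"))
        assert esc == pytest.approx(1.15 * base, rel=1e-9)

    def test_escalation_requires_recurrence(self):
        with pytest.raises(ValueError, match="recurrence"):
            sc.ScenarioSpec(name="x", target_removal_mm3=16.0,
                            escalation=((2038, 2047, 1.1),))


class TestAllocation:
    def test_zero_demand_no_events(self, mini_state):
        events, deficits, fluxes = sc.allocate_harvest(
            mini_state, {}, sc.green(), PARAMS, year=2030)
        assert events == []
        assert deficits == {}

    def test_shortfall_becomes_deficit(self):
        state = single_cohort_state(age=120, merch_ha=6.0, area=10.0)  # 60 t C
        demand = {("R1", "SP", "3a"): 100.0}
        events, deficits, _ = sc.allocate_harvest(state, demand, sc.red(),
                                                  PARAMS, year=2030)
        assert sum(e.target for e in events) == pytest.approx(60.0)
        assert deficits[("R1", "SP", "3a")] == pytest.approx(40.0)

    def test_allocated_plus_deficit_equals_demand(self, mini_state):
        demand = {}
        for rid in mini_state.regions:
            demand[(rid, "SP", "3a")] = 5e4
            demand[(rid, "SP", "2")] = 2e4
            demand[(rid, "BE", "4")] = 1e4
        events, deficits, _ = sc.allocate_harvest(mini_state, demand, sc.red(),
                                                  PARAMS, year=2030)
        allocated = {}
        for e in events:
            key = (e.region_id, e.forest_type, e.dist_id)
            allocated[key] = allocated.get(key, 0.0) + e.target
        for key, dem in demand.items():
            assert allocated.get(key, 0.0) + deficits[key] == pytest.approx(
                dem, rel=1e-9)

    def test_retained_old_growth_untouched_under_unmet_demand(self):
        state = single_cohort_state(age=130, merch_ha=50.0, retained=True)
        demand = {("R1", "SP", "3a"): 100.0, ("R1", "SP", "4"): 100.0}
        events, deficits, _ = sc.allocate_harvest(state, demand, sc.green(),
                                                  PARAMS, year=2030)
        assert events == []
        assert deficits[("R1", "SP", "3a")] == 100.0
        assert deficits[("R1", "SP", "4")] == 100.0

    def test_oldest_cohorts_salvaged_first(self):
        pv1, pv2 = PoolVector(), PoolVector()
        pv1["merch_stem"] = 50.0
        pv2["merch_stem"] = 50.0
        old = StandCohort("R1", "SP", 110, 10.0, pv1)
        young = StandCohort("R1", "SP", 60, 10.0, pv2)
        state = ForestState([young, old], {"R1": REGION})
        demand = {("R1", "SP", "3a"): 500.0}
        sc.allocate_harvest(state, demand, sc.red(), PARAMS, year=2030)
        remaining = {c.age: c.area for c in state.cohorts
                     if c.forest_type == "SP"}
        assert 110 not in remaining         # old cohort fully cleared
        assert remaining[60] == pytest.approx(10.0)


class TestSpeciesChange:
    RULES = sc.SpeciesChangeRule()

    def _cleared(self, origin, trigger, area=100.0, region="R1"):
        pv = PoolVector()
        pv["ag_slow"] = 10.0
        return StandCohort(region, "CLEARCUT", 0, area, pv,
                           origin_type=origin, trigger=trigger)

    def test_sanitary_spruce_fir_region(self):
        out = sc.apply_species_change([self._cleared("SP", "sanitary")],
                                      self.RULES, {"R1": REGION})
        comp = {c.forest_type: c.area for c in out}
        assert comp == pytest.approx(
            {"AA": 30.0, "OA": 10.0, "BE": 20.0, "LLB": 20.0, "SLB": 20.0})

    def test_sanitary_spruce_oak_region(self):
        out = sc.apply_species_change(
            [self._cleared("SP", "sanitary", region="R2")],
            self.RULES, {"R2": OAK_REGION})
        comp = {c.forest_type: c.area for c in out}
        assert comp["OA"] == pytest.approx(30.0)
        assert comp["AA"] == pytest.approx(10.0)

    def test_final_cut_keeps_half_spruce(self):
        out = sc.apply_species_change([self._cleared("SP", "final")],
                                      self.RULES, {"R1": REGION})
        comp = {c.forest_type: c.area for c in out}
        assert comp == pytest.approx(
            {"SP": 50.0, "AA": 10.0, "BE": 20.0, "LLB": 20.0})

    def test_non_spruce_replanted_to_own_type(self):
        for trigger in ("sanitary", "final"):
            out = sc.apply_species_change([self._cleared("PI", trigger)],
                                          self.RULES, {"R1": REGION})
            assert [(c.forest_type, c.area) for c in out] == [("PI", 100.0)]

    def test_dom_inherited(self):
        out = sc.apply_species_change([self._cleared("SP", "sanitary")],
                                      self.RULES, {"R1": REGION})
        for c in out:
            assert c.pools["ag_slow"] == pytest.approx(10.0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            sc.SpeciesChangeRule(final={"SP": 0.5, "BE": 0.4})


class TestRunScenario:
    def test_empty_horizon_gives_empty_results(self, mini_spun, mini_curves,
                                               mini_obs):
        res = sc.run_scenario(mini_spun, sc.green(), mini_curves, mini_obs,
                              horizon=(2018, 2017))
        assert res == []

    def test_zero_demand_run_is_pure_dynamics(self, mini_spun, mini_curves,
                                              mini_obs):
        zero_obs = mini_obs.copy()
        zero_obs["volume_mm3"] = 0.0
        spec = sc.ScenarioSpec(name="green", target_removal_mm3=0.0)
        state = mini_spun.copy()
        state.cohorts = [c for c in state.cohorts if c.forest_type != "SPx"]
        res = sc.run_scenario(state, spec, mini_curves, zero_obs,
                              horizon=(2018, 2030))
        for r in res:
            assert r.total_harvest_c == 0.0
            delta = r.total_stock_change
            assert delta == pytest.approx(r.growth_c - r.atm_flux_c,
                                          rel=1e-9, abs=1e-6)

    def test_total_area_constant_every_year(self, mini_runs, mini_spun):
        total = mini_spun.total_area()
        for name, res in mini_runs.items():
            for r in res:
                assert sum(r.area_by_type.values()) == pytest.approx(
                    total, abs=1e-6), (name, r.year)

    def test_known_period_identical_across_scenarios(self, mini_runs):
        ref = None
        for name, res in mini_runs.items():
            early = {r.year: r.harvest_c for r in res if r.year <= 2021}
            if ref is None:
                ref = early
                continue
            for year, harvest in early.items():
                assert set(harvest) == set(ref[year]), (name, year)
                for k, v in harvest.items():
                    assert v == pytest.approx(ref[year][k], rel=1e-9), (name, year, k)

    def test_whole_run_mass_balance(self, mini_runs, mini_spun):
        start = mini_spun.total_carbon()
        for name, res in mini_runs.items():
            end = start + sum(r.total_stock_change for r in res)
            growth = sum(r.growth_c for r in res)
            removed = sum(r.products_c for r in res)
            atm = sum(r.atm_flux_c for r in res)
            assert (end - start) + removed + atm == pytest.approx(
                growth, rel=1e-6), name

    def test_deterministic_given_inputs(self, mini_spun, mini_curves, mini_obs):
        a = sc.run_scenario(mini_spun, sc.black(), mini_curves, mini_obs,
                            horizon=(2018, 2024))
        b = sc.run_scenario(mini_spun, sc.black(), mini_curves, mini_obs,
                            horizon=(2018, 2024))
        for ra, rb in zip(a, b):
            assert ra.stock_change == rb.stock_change
            assert ra.harvest_c == rb.harvest_c

    def test_snag_backlog_processed_with_one_year_delay(self, mini_runs):
        res = mini_runs["green"]
        backlog_years = {r.year for r in res
                         if any(d == "7" for d, _ in r.harvest_c)}
        assert backlog_years  # initial SPx stock and dist-6 mortality
        assert backlog_years <= set(range(2018, 2023))

    def test_retention_builds_old_growth_only_in_green(self, default_runs):
        green_old = sum(a for cls, a in
                        default_runs["green"][-1].area_by_age_class.items()
                        if cls >= 12)
        red_old = sum(a for cls, a in
                      default_runs["red"][-1].area_by_age_class.items()
                      if cls >= 12)
        assert green_old > red_old
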