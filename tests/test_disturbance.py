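"""Disturbance matrices, event application and mass balance."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcbs import carbon_dynamics as cd
from fcbs import disturbance as db
from fcbs.forest_state import Region, StandCohort
from fcbs.pools import MERCH, N_POOLS, SNAG_STEM, PoolVector

PARAMS = cd.default_params()
REGION = Region("R1", "one", 500.0, "Fir", 2030, True)


def live_cohort(merch=50.0, other=15.0, foliage=2.5, coarse=10.0, fine=1.0,
                ft="SP", age=80, area=10.0):
    pv = PoolVector()
    pv["merch_stem"] = merch
    pv["other_wood"] = other
    pv["foliage"] = foliage
    pv["coarse_roots"] = coarse
    pv["fine_roots"] = fine
    return StandCohort("R1", ft, age, area, pv)


class TestMatrices:
    @pytest.mark.parametrize("dist_id", db.DIST_IDS)
    def test_all_source_rows_sum_to_one(self, dist_id):
        matrix = db.build_disturbance_matrix(dist_id)
        for name, row in matrix.rows().items():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12), name

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            db.build_disturbance_matrix("9")

    def test_thinning_intensity_range_enforced(self):
        with pytest.raises(ValueError, match="intensity"):
            db.build_disturbance_matrix("2", {"affected_fraction": 0.4})
        m = db.build_disturbance_matrix("2", {"affected_fraction": 0.25})
        assert m.affected_fraction == 0.25

    def test_salvage_residue_extraction_default(self):
        assert db.build_disturbance_matrix("3a").residue_extraction == 0.20
        assert db.build_disturbance_matrix("4").residue_extraction == 0.25


class TestApplyDisturbance:
    def test_zero_target_is_identity(self):
        c = live_cohort()
        before = c.pools.a.copy()
        out, flux = db.apply_disturbance(c, db.DEFAULT_MATRICES["3a"], 0.0)
        assert out == [c]
        np.testing.assert_array_equal(c.pools.a, before)
        assert flux.products == flux.residues == flux.to_atmosphere == 0.0

    def test_salvage_clearcut_residue_split(self):
        # 100 t C of aboveground residues on the cleared hectare:
        # 20% extracted as products, the rest to DOM
        c = live_cohort(merch=50.0, other=80.0, foliage=20.0, coarse=0.0,
                        fine=0.0, area=1.0)
        out, flux = db.apply_disturbance(c, db.DEFAULT_MATRICES["3a"],
                                         50.0, year=2020)
        assert flux.products == pytest.approx(50.0)
        assert flux.residues == pytest.approx(20.0)
        assert flux.to_dom == pytest.approx(80.0)
        (cleared,) = out
        assert cleared.forest_type == "CLEARCUT"
        assert cleared.trigger == "sanitary"

    def test_final_cut_leaves_seed_trees(self):
        c = live_cohort(merch=100.0, area=1.0, age=120)
        out, flux = db.apply_disturbance(c, db.DEFAULT_MATRICES["4"], 95.0)
        assert flux.products == pytest.approx(95.0)
        (cleared,) = out
        assert cleared.forest_type == "CLEARCUT"
        assert cleared.trigger == "final"
        assert cleared.pools["merch_stem"] == pytest.approx(5.0)
        assert cleared.age == 0

    def test_partial_clearcut_splits_area(self):
        c = live_cohort(merch=50.0, area=10.0)
        out, _ = db.apply_disturbance(c, db.DEFAULT_MATRICES["3a"], 250.0)
        assert len(out) == 2
        orig, cleared = out
        assert orig.area == pytest.approx(5.0)
        assert cleared.area == pytest.approx(5.0)
        assert cleared.forest_type == "CLEARCUT"

    def test_selective_salvage_keeps_stand(self):
        c = live_cohort(merch=50.0, area=10.0)
        out, flux = db.apply_disturbance(c, db.DEFAULT_MATRICES["3b"], 100.0)
        assert out == [c]
        assert c.forest_type == "SP"
        assert c.pools["merch_stem"] == pytest.approx(50.0 * 0.8)
        assert flux.products == pytest.approx(100.0)

    def test_thinning_age_window_enforced(self):
        with pytest.raises(ValueError, match="age"):
            db.apply_disturbance(live_cohort(age=80),
                                 db.DEFAULT_MATRICES["2"], 1.0)
        with pytest.raises(ValueError, match="age"):
            db.apply_disturbance(live_cohort(age=10),
                                 db.DEFAULT_MATRICES["2"], 1.0)

    def test_thinning_above_affected_fraction_rejected(self):
        c = live_cohort(merch=50.0, area=1.0, age=40)
        with pytest.raises(ValueError, match="affected fraction"):
            db.apply_disturbance(c, db.DEFAULT_MATRICES["2"], 20.0)

    def test_standing_mortality_creates_spruce_snag(self):
        c = live_cohort(merch=50.0, area=10.0, ft="SP")
        out, flux = db.apply_disturbance(c, db.DEFAULT_MATRICES["6"], 10.0,
                                         year=2019)
        (dead,) = out
        assert dead.forest_type == "SPx"
        assert dead.created_year == 2019
        assert dead.pools["merch_stem"] == 0.0
        assert dead.pools["snag_stem"] == pytest.approx(50.0)
        assert flux.products == 0.0

    def test_snag_harvest_removes_from_snag_pool(self):
        pv = PoolVector()
        pv["snag_stem"] = 10.0
        c = StandCohort("R1", "SPx", 75, 1.0, pv)
        out, flux = db.apply_disturbance(c, db.DEFAULT_MATRICES["7"], 9.0)
        assert out == [c]
        assert c.pools["snag_stem"] == pytest.approx(1.0)
        assert flux.products == pytest.approx(9.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        dist_id=st.sampled_from(["2", "3a", "3b", "4", "5", "6", "7"]),
        merch=st.floats(1.0, 300.0),
        other=st.floats(0.0, 100.0),
        foliage=st.floats(0.0, 20.0),
        coarse=st.floats(0.0, 60.0),
        fine=st.floats(0.0, 10.0),
        snag=st.floats(0.0, 100.0),
        area=st.floats(0.1, 1000.0),
        frac=st.floats(0.01, 1.0),
    )
    def test_event_mass_balance(self, dist_id, merch, other, foliage, coarse,
                                fine, snag, area, frac):
        c = live_cohort(merch, other, foliage, coarse, fine,
                        age=40 if dist_id == "2" else 120, area=area)
        c.pools["snag_stem"] = snag
        matrix = db.DEFAULT_MATRICES[dist_id]
        before = c.total_carbon()
        if dist_id == "6":
            target = frac * area
        elif dist_id == "7":
            target = frac * snag * area
        else:
            cap = matrix.merch_to_products * merch * area
            if dist_id == "2":
                cap *= matrix.affected_fraction
            elif dist_id == "3b":
                cap *= matrix.affected_fraction
            target = frac * cap
        out, flux = db.apply_disturbance(c, matrix, target, year=2020)
        after = sum(x.total_carbon() for x in out)
        leaving = flux.products + flux.residues + flux.to_atmosphere
        assert after + leaving == pytest.approx(before, rel=1e-9, abs=1e-9)
        for x in out:
            assert np.all(x.pools.a >= -1e-9)

    def test_3b_never_resets_3a_4_always_reset(self):
        for dist, resets in (("3b", False), ("3a", True), ("4", True)):
            c = live_cohort(merch=50.0, area=10.0, age=120)
            out, _ = db.apply_disturbance(c, db.DEFAULT_MATRICES[dist], 40.0)
            made_clearcut = any(x.forest_type == "CLEARCUT" for x in out)
            assert made_clearcut == resets, dist


class TestSnagBacklog:
    def _state_with_spx(self, snag=10.0, created=2019, area=1.0):
        from fcbs.forest_state import ForestState

        pv = PoolVector()
        pv["snag_stem"] = snag
        c = StandCohort("R1", "SPx", 75, area, pv, created_year=created)
        return ForestState([c], {"R1": REGION})

    def test_no_spx_gives_empty_list(self, mini_spun):
        state = mini_spun.copy()
        state.cohorts = [c for c in state.cohorts if c.forest_type != "SPx"]
        assert db.process_snag_backlog(state, 2019) == []

    def test_removes_90_percent_of_last_years_snags(self):
        state = self._state_with_spx(snag=10.0, created=2019)
        (event,) = db.process_snag_backlog(state, 2020)
        assert event.dist_id == "7"
        assert event.target == pytest.approx(9.0)

    def test_window_and_delay_respected(self):
        state = self._state_with_spx(created=2019)
        assert db.process_snag_backlog(state, 2021) == []   # one-year delay only
        state2 = self._state_with_spx(created=2023)
        assert db.process_snag_backlog(state2, 2024) == []  # outside the window

    def test_residual_decays_by_snag_closed_form(self):
        state = self._state_with_spx(snag=10.0, created=2019)
        (event,) = db.process_snag_backlog(state, 2020)
        c = state.cohorts[0]
        db.apply_disturbance(c, db.DEFAULT_MATRICES["7"], event.target)
        assert c.pools["snag_stem"] == pytest.approx(1.0)
        rate = PARAMS.decay[SNAG_STEM].rate
        for _ in range(10):
            cd.decay_dom(c, PARAMS)
        assert c.pools["snag_stem"] == pytest.approx(1.0 * (1 - rate) ** 10,
                                                     rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(snag=st.floats(0.0, 500.0), area=st.floats(0.1, 100.0))
    def test_removal_never_exceeds_stock(self, snag, area):
        state = self._state_with_spx(snag=snag, area=area)
        events = db.process_snag_backlog(state, 2020)
        stock = snag * area
        for e in events:
            assert e.target <= stock * 0.9 + 1e-9


class TestReforest:
    def test_zero_area_gives_empty_list(self):
        assert db.reforest(0.0, {"BE": 1.0}, REGION) == []

    def test_even_split(self):
        out = db.reforest(100.0, {"BE": 0.5, "OA": 0.5}, REGION)
        assert [(c.forest_type, c.area, c.age) for c in out] == [
            ("BE", 50.0, 0), ("OA", 50.0, 0)]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            db.reforest(10.0, {"BE": 0.6, "OA": 0.5}, REGION)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1000.0),
           st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5))
    def test_area_conserved_for_random_compositions(self, area, weights):
        types = ["SP", "PI", "BE", "OA", "LLB"][: len(weights)]
        total = sum(weights)
        comp = {t: w / total for t, w in zip(types, weights)}
        comp[types[-1]] += 1.0 - sum(comp.values())  # exact renormalisation
        out = db.reforest(area, comp, REGION)
        assert sum(c.area for c in out) == pytest.approx(area, rel=1e-9,
                                                         abs=1e-9)

    def test_dom_inherited_per_hectare(self):
        dom = PoolVector()
        dom["ag_slow"] = 30.0
        out = db.reforest(10.0, {"BE": 1.0}, REGION, dom_per_ha=dom)
        assert out[0].pools["ag_slow"] == pytest.approx(30.0)
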