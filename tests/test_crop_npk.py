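"""Crop nutrient bookkeeping: demand, supply, uptake, transfers, indices."""

import pytest
from hypothesis import given, settings, strategies as st

from cassava_npk import (
    ConcentrationTable,
    ModelParameters,
    combine_npki,
    nutrient_equivalent_demand,
    nutrient_equivalent_supply,
    plant_amounts,
    uptake_rates,
)
from cassava_npk.config import NUTRIENTS, ORGANS
from cassava_npk.crop_npk import (
    PlantAmounts,
    allocate_uptake,
    nutrition_index,
    nutrition_indices,
    redistribution_rates,
    reroute_dead_leaf_nutrients,
)


def flat_table(cmin=0.01, cmax=0.04):
    return ConcentrationTable({(o, n): [(0.0, cmin, cmax)]
                               for o in ORGANS for n in NUTRIENTS})


def amounts_dict(value=0.0):
    return {(o, n): value for o in ORGANS for n in NUTRIENTS}


class TestPlantAmounts:
    def test_zero_weights_zero_everything(self):
        pa = plant_amounts({o: 0.0 for o in ORGANS}, amounts_dict(),
                           flat_table(), tsum=0.0, fr_max=0.8)
        for n in NUTRIENTS:
            assert pa.Act[n] == pa.Min[n] == pa.Max[n] == pa.Opt[n] == 0.0

    def test_opt_interpolates_min_max_with_fr_max(self):
        # Min = 2, Max = 10 per nutrient given 200 g DM at (0.01, 0.05)
        table = flat_table(cmin=0.01, cmax=0.05)
        weights = {"leaf": 200.0, "stem": 0.0, "storage": 0.0, "root": 0.0}
        pa = plant_amounts(weights, amounts_dict(), table, 0.0, fr_max=0.8)
        assert pa.Min["N"] == pytest.approx(2.0)
        assert pa.Max["N"] == pytest.approx(10.0)
        assert pa.Opt["N"] == pytest.approx(8.4)

    def test_single_organ_contribution(self):
        weights = {"leaf": 100.0, "stem": 0.0, "storage": 0.0, "root": 0.0}
        pa = plant_amounts(weights, amounts_dict(), flat_table(cmax=0.04),
                           0.0, fr_max=0.8)
        assert pa.Max["N"] == pytest.approx(4.0)

    def test_act_comes_from_stored_amounts_not_concentrations(self):
        amounts = amounts_dict()
        amounts[("stem", "N")] = 1.25
        pa = plant_amounts({o: 100.0 for o in ORGANS}, amounts, flat_table(),
                           0.0, fr_max=0.8)
        assert pa.Act["N"] == pytest.approx(1.25)


class TestNutrientEquivalents:
    MAX = {"N": 10.0, "P": 1.0, "K": 8.0}

    def test_demand_zero_at_saturation(self):
        assert nutrient_equivalent_demand(dict(self.MAX), dict(self.MAX)) == 0.0

    def test_demand_sums_scaled_gaps(self):
        act = {"N": 6.0, "P": 0.6, "K": 4.0}
        # 4 + (0.4/1)*10 + (4/8)*10 = 4 + 4 + 5
        assert nutrient_equivalent_demand(act, self.MAX) == pytest.approx(13.0)

    def test_single_deficiency(self):
        act = {"N": 10.0, "P": 1.0, "K": 4.0}
        assert nutrient_equivalent_demand(act, self.MAX) == pytest.approx(5.0)

    def test_supply_in_nitrogen_equivalents(self):
        a = {"N": 2.0, "P": 0.3, "K": 4.0}
        # 2 + (0.3/1)*10 + (4/8)*10 = 2 + 3 + 5
        assert nutrient_equivalent_supply(a, self.MAX) == pytest.approx(10.0)

    def test_supply_is_homogeneous(self):
        a = {"N": 2.0, "P": 0.3, "K": 4.0}
        doubled = {k: 2 * v for k, v in a.items()}
        assert nutrient_equivalent_supply(doubled, self.MAX) == \
            pytest.approx(2 * nutrient_equivalent_supply(a, self.MAX))

    def test_zero_max_terms_drop_out(self):
        act = {"N": 1.0, "P": 0.0, "K": 0.0}
        mx = {"N": 10.0, "P": 0.0, "K": 0.0}
        assert nutrient_equivalent_demand(act, mx) == pytest.approx(9.0)
        assert nutrient_equivalent_supply({"N": 2.0, "P": 5.0, "K": 5.0}, mx) == \
            pytest.approx(2.0)


class TestUptakeRates:
    def make(self, act, mx):
        mn = {n: 0.0 for n in NUTRIENTS}
        opt = {n: 0.8 * mx[n] for n in NUTRIENTS}
        return PlantAmounts(Act=act, Min=mn, Max=mx, Opt=opt)

    def test_ne_uptake_is_rne_times_binding_side(self, params):
        pa = self.make({"N": 6.0, "P": 0.6, "K": 4.0},
                       {"N": 10.0, "P": 1.0, "K": 8.0})
        available = {"N": 2.0, "P": 0.3, "K": 4.0}   # NES = 10 < NED = 13
        rates = uptake_rates(pa, available, params)
        assert rates.NEUP == pytest.approx(0.012 * 10.0)

    def test_empty_pool_blocks_uptake(self, params):
        pa = self.make({"N": 6.0, "P": 0.6, "K": 4.0},
                       {"N": 10.0, "P": 1.0, "K": 8.0})
        rates = uptake_rates(pa, {"N": 5.0, "P": 0.5, "K": 0.0}, params)
        assert rates.UP["K"] == 0.0

    def test_zero_demand_blocks_uptake(self, params):
        pa = self.make({"N": 10.0, "P": 0.6, "K": 4.0},
                       {"N": 10.0, "P": 1.0, "K": 8.0})
        rates = uptake_rates(pa, {"N": 100.0, "P": 0.5, "K": 4.0}, params)
        assert rates.UP["N"] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(act_frac=st.floats(0.0, 1.0), a_n=st.floats(0.0, 30.0),
           a_p=st.floats(0.0, 5.0), a_k=st.floats(0.0, 30.0))
    def test_uptake_bounded_by_demand_and_pool(self, params, act_frac,
                                               a_n, a_p, a_k):
        mx = {"N": 10.0, "P": 1.0, "K": 8.0}
        act = {n: act_frac * mx[n] for n in NUTRIENTS}
        available = {"N": a_n, "P": a_p, "K": a_k}
        rates = uptake_rates(self.make(act, mx), available, params)
        for n in NUTRIENTS:
            assert rates.UP[n] >= 0.0
            assert rates.UP[n] * params.DELT <= available[n] + 1e-12
            assert rates.UP[n] * params.DELT <= mx[n] - act[n] + 1e-12


class TestAllocation:
    def test_proportional_to_weight(self):
        weights = {"leaf": 100.0, "stem": 50.0, "storage": 50.0, "root": 0.0}
        alloc = allocate_uptake({"N": 1.0, "P": 0.0, "K": 0.0}, weights)
        assert alloc[("leaf", "N")] == pytest.approx(0.5)
        assert alloc[("stem", "N")] == pytest.approx(0.25)
        assert alloc[("storage", "N")] == pytest.approx(0.25)
        assert alloc[("root", "N")] == pytest.approx(0.0, abs=1e-15)

    def test_equal_weights_split_evenly(self):
        alloc = allocate_uptake({"N": 1.0, "P": 1.0, "K": 1.0},
                                {o: 25.0 for o in ORGANS})
        for n in NUTRIENTS:
            for o in ORGANS:
                assert alloc[(o, n)] == pytest.approx(0.25)

    def test_single_organ_takes_all(self):
        weights = {"leaf": 0.0, "stem": 80.0, "storage": 0.0, "root": 0.0}
        alloc = allocate_uptake({"N": 0.7, "P": 0.0, "K": 0.0}, weights)
        assert alloc[("stem", "N")] == pytest.approx(0.7)

    def test_zero_biomass_allocates_nothing(self):
        alloc = allocate_uptake({"N": 1.0, "P": 1.0, "K": 1.0},
                                {o: 0.0 for o in ORGANS})
        assert all(v == 0.0 for v in alloc.values())

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(up=st.floats(0.0, 5.0),
           w=st.lists(st.floats(0.0, 500.0), min_size=4, max_size=4))
    def test_increments_sum_to_uptake_exactly(self, up, w):
        weights = dict(zip(ORGANS, w))
        if sum(w) == 0.0:
            return
        alloc = allocate_uptake({"N": up, "P": 0.0, "K": 0.0}, weights)
        assert sum(alloc[(o, "N")] for o in ORGANS) == pytest.approx(up, abs=1e-15)


class TestRedistribution:
    def test_balanced_amounts_do_not_move(self):
        weights = {o: 100.0 for o in ORGANS}
        act = {"N": 4.0, "P": 4.0, "K": 4.0}
        amounts = amounts_dict(1.0)   # equal share per organ = the target
        rates = redistribution_rates(weights, amounts, act, flat_table(),
                                     0.0, tc_npk=10.0)
        assert all(abs(v) < 1e-12 for v in rates.values())

    def test_imbalance_relaxes_at_tc_rate(self):
        # two identical organs, amounts (8, 2): targets are (5, 5)
        weights = {"leaf": 100.0, "stem": 100.0, "storage": 0.0, "root": 0.0}
        amounts = amounts_dict()
        amounts[("leaf", "N")] = 8.0
        amounts[("stem", "N")] = 2.0
        rates = redistribution_rates(weights, amounts, {"N": 10.0, "P": 0, "K": 0},
                                     flat_table(), 0.0, tc_npk=10.0)
        assert rates[("leaf", "N")] == pytest.approx(-0.3)
        assert rates[("stem", "N")] == pytest.approx(0.3)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(vals=st.lists(st.floats(0.0, 10.0), min_size=4, max_size=4),
           weights=st.lists(st.floats(0.1, 300.0), min_size=4, max_size=4))
    def test_transfers_conserve_totals(self, vals, weights):
        w = dict(zip(ORGANS, weights))
        amounts = amounts_dict()
        for o, v in zip(ORGANS, vals):
            amounts[(o, "N")] = v
        act = {"N": sum(vals), "P": 0.0, "K": 0.0}
        rates = redistribution_rates(w, amounts, act, flat_table(), 0.0, 10.0)
        assert sum(rates[(o, "N")] for o in ORGANS) == pytest.approx(0.0, abs=1e-12)


class TestDeadLeafRerouting:
    def test_no_death_no_transfer(self):
        out = reroute_dead_leaf_nutrients(0.0, {"N": 1.0, "P": 0.1, "K": 0.5})
        assert all(v == 0.0 for v in out.values())

    def test_nitrogen_to_stem_pk_to_storage(self):
        leaf = {"N": 10.0, "P": 1.0, "K": 5.0}
        out = reroute_dead_leaf_nutrients(0.1, leaf)
        assert out[("stem", "N")] == pytest.approx(1.0)
        assert out[("storage", "P")] == pytest.approx(0.1)
        assert out[("storage", "K")] == pytest.approx(0.5)
        assert out[("leaf", "N")] == pytest.approx(-1.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(frac=st.floats(0.0, 1.0), n=st.floats(0.0, 5.0),
           p=st.floats(0.0, 1.0), k=st.floats(0.0, 5.0))
    def test_whole_plant_totals_unchanged(self, frac, n, p, k):
        out = reroute_dead_leaf_nutrients(frac, {"N": n, "P": p, "K": k})
        for nutrient in NUTRIENTS:
            assert sum(out[(o, nutrient)] for o in ORGANS) == \
                pytest.approx(0.0, abs=1e-12)


class TestNutritionIndices:
    def test_worked_example_two_decimals(self):
        """The calibrated combination rule maps an index product of 0.8 to 0.77."""
        assert round(combine_npki(0.8, k_ni=6.1, kmax=4.0), 2) == 0.77

    @pytest.mark.parametrize("k_ni,kmax", [
        (0.5, 4.0), (2.0, 4.0), (4.0, 4.0),      # first branch
        (6.1, 4.0), (10.0, 4.0), (4.01, 4.0),    # second branch
    ])
    def test_no_stress_is_exactly_one_on_both_branches(self, k_ni, kmax):
        assert combine_npki(1.0, k_ni, kmax) == 1.0

    def test_full_stress_is_zero(self):
        assert combine_npki(0.0, 6.1, 4.0) == 0.0
        assert combine_npki(0.0, 2.0, 4.0) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(pi=st.floats(0.0, 1.0), k_ni=st.floats(0.1, 12.0))
    def test_bounded_and_monotone(self, pi, k_ni):
        value = combine_npki(pi, k_ni, 4.0)
        assert 0.0 <= value <= 1.0
        assert combine_npki(min(1.0, pi + 0.05), k_ni, 4.0) >= value - 1e-12

    def test_index_clamps_to_unit_interval(self):
        assert nutrition_index(act=5.0, mn=2.0, opt=4.0) == 1.0   # luxury uptake
        assert nutrition_index(act=1.0, mn=2.0, opt=4.0) == 0.0
        assert nutrition_index(act=3.0, mn=2.0, opt=4.0) == pytest.approx(0.5)

    def test_degenerate_span(self):
        assert nutrition_index(act=1.0, mn=1.0, opt=1.0) == 1.0
        assert nutrition_index(act=0.5, mn=1.0, opt=1.0) == 0.0

    def test_thermal_time_gate_forces_one(self, params):
        pa = PlantAmounts(Act={n: 0.0 for n in NUTRIENTS},
                          Min={n: 0.0 for n in NUTRIENTS},
                          Max={n: 10.0 for n in NUTRIENTS},
                          Opt={n: 8.0 for n in NUTRIENTS})
        gated = nutrition_indices(pa, tsum=100.0, params=params)
        open_ = nutrition_indices(pa, tsum=272.0, params=params)
        assert gated.NPKI == 1.0
        assert open_.NPKI == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(act=st.floats(0.0, 12.0), bump=st.floats(0.0, 3.0))
    def test_monotone_in_actual_content(self, params, act, bump):
        def npki_of(a):
            pa = PlantAmounts(Act={n: a for n in NUTRIENTS},
                              Min={n: 2.0 for n in NUTRIENTS},
                              Max={n: 10.0 for n in NUTRIENTS},
                              Opt={n: 8.4 for n in NUTRIENTS})
            return nutrition_indices(pa, tsum=500.0, params=params).NPKI
        assert npki_of(act + bump) >= npki_of(act) - 1e-12
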