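import math

import pytest
from hypothesis import given, settings, strategies as st

import swardsim as ss
from swardsim.canopy import _clamp01
from swardsim.errors import ConfigError, DomainError
from swardsim.management import PartitionFractions


class TestFractionIntercepted:
    @pytest.mark.parametrize(
        "lai,expected",
        [(0.0, 0.0), (4.0, 1.0 - math.exp(-2.4)), (1000.0, 1.0)],
    )
    def test_beers_law_values(self, lai, expected):
        assert ss.fraction_intercepted(lai, 0.6) == pytest.approx(expected, abs=1e-9)

    def test_negative_lai_rejected(self):
        with pytest.raises(DomainError):
            ss.fraction_intercepted(-0.1)

    @given(st.floats(0.0, 20.0), st.floats(0.0, 20.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_lai(self, a, b):
        lo, hi = sorted((a, b))
        assert ss.fraction_intercepted(lo) <= ss.fraction_intercepted(hi) + 1e-15


class TestTemperatureFactor:
    def test_zero_at_base_temperature(self, canopy_params):
        assert ss.temperature_factor(canopy_params.t_base, canopy_params) == 0.0

    def test_one_at_table_optimum(self, canopy_params):
        assert ss.temperature_factor(15.0, canopy_params) == 1.0

    def test_midpoint_interpolates_linearly(self, canopy_params):
        # halfway between the (3, 0) and (10, 1) anchors
        assert ss.temperature_factor(6.5, canopy_params) == pytest.approx(0.5)

    def test_clamped_outside_anchors(self, canopy_params):
        assert ss.temperature_factor(-20.0, canopy_params) == 0.0
        assert ss.temperature_factor(50.0, canopy_params) == 0.0


class TestCO2Factor:
    def test_unity_at_reference(self, canopy_params):
        assert ss.co2_factor(360.0, canopy_params) == pytest.approx(1.0)

    def test_doubling_log_response(self, canopy_params):
        assert ss.co2_factor(720.0, canopy_params) == pytest.approx(
            1.0 + 0.8 * math.log(2.0)
        )

    def test_disabled_response_flat(self):
        params = ss.CanopyParameters(co2_beta=0.0)
        for co2 in (100.0, 360.0, 900.0):
            assert ss.co2_factor(co2, params) == 1.0

    def test_non_positive_co2_rejected(self, canopy_params):
        with pytest.raises(DomainError):
            ss.co2_factor(0.0, canopy_params)


class TestSourceLimitedGrowth:
    def test_no_light_no_growth(self, canopy_params):
        assert ss.source_limited_growth(0.0, 3.0, 1, 1, 1, 1, canopy_params) == 0.0

    def test_full_interception_limit(self, canopy_params):
        g = ss.source_limited_growth(10.0, 1e6, 1, 1, 1, 1, canopy_params)
        assert g == pytest.approx(300.0)  # 10 MJ x 10 x LUE 3.0

    def test_liebig_minimum_of_water_and_n(self, canopy_params):
        full = ss.source_limited_growth(10.0, 3.0, 1, 1, 1.0, 1.0, canopy_params)
        half_w = ss.source_limited_growth(10.0, 3.0, 1, 1, 0.5, 1.0, canopy_params)
        half_n = ss.source_limited_growth(10.0, 3.0, 1, 1, 1.0, 0.5, canopy_params)
        assert half_w == pytest.approx(0.5 * full)
        assert half_n == pytest.approx(0.5 * full)


class TestSinkLimitedGrowth:
    def test_cold_day_zero(self, canopy_params):
        state = ss.CanopyState(tillers=5000.0)
        assert ss.sink_limited_growth(state, 0.0, canopy_params) == 0.0

    def test_no_tillers_zero(self, canopy_params):
        state = ss.CanopyState(tillers=0.0)
        assert ss.sink_limited_growth(state, 10.0, canopy_params) == 0.0

    def test_linear_in_tillers(self, canopy_params):
        s1 = ss.sink_limited_growth(ss.CanopyState(tillers=4000.0), 8.0, canopy_params)
        s2 = ss.sink_limited_growth(ss.CanopyState(tillers=8000.0), 8.0, canopy_params)
        assert s2 == pytest.approx(2.0 * s1)


class TestAllocateWithReserves:
    def test_surplus_tops_up_reserves(self, canopy_params):
        growth, reserves, discarded = ss.allocate_with_reserves(
            100.0, 60.0, 0.0, canopy_params, shoot_dm=10000.0
        )
        assert (growth, reserves, discarded) == (60.0, 40.0, 0.0)

    def test_deficit_withdrawn_within_remob_cap(self, canopy_params):
        growth, reserves, discarded = ss.allocate_with_reserves(
            20.0, 60.0, 100.0, canopy_params, shoot_dm=10000.0
        )
        assert (growth, reserves, discarded) == (60.0, 60.0, 0.0)

    def test_balanced_source_sink_leaves_reserves(self, canopy_params):
        growth, reserves, _ = ss.allocate_with_reserves(
            50.0, 50.0, 30.0, canopy_params, shoot_dm=1000.0
        )
        assert growth == 50.0 and reserves == 30.0

    def test_remob_rate_caps_withdrawal(self, canopy_params):
        growth, reserves, _ = ss.allocate_with_reserves(
            0.0, 500.0, 500.0, canopy_params, shoot_dm=10000.0
        )
        assert growth == pytest.approx(canopy_params.remob_rate)
        assert reserves == pytest.approx(500.0 - canopy_params.remob_rate)

    def test_cap_binding_discards_surplus(self, canopy_params):
        # cap = 0.2 x 1000 = 200; room = 100
        growth, reserves, discarded = ss.allocate_with_reserves(
            400.0, 100.0, 100.0, canopy_params, shoot_dm=1000.0
        )
        assert growth == 100.0
        assert reserves == 200.0
        assert discarded == pytest.approx(200.0)

    @given(
        st.floats(0, 500), st.floats(0, 500), st.floats(0, 400), st.floats(0, 20000)
    )
    @settings(max_examples=100, derandomize=True)
    def test_mass_balance_exact(self, source, sink, reserves0, shoot):
        params = ss.CanopyParameters()
        growth, reserves, discarded = ss.allocate_with_reserves(
            source, sink, reserves0, params, shoot_dm=shoot
        )
        assert growth >= 0 and reserves >= 0 and discarded >= 0
        assert growth + (reserves - reserves0) + discarded == pytest.approx(
            source, abs=1e-9
        )
        assert growth <= max(source, sink) + 1e-12


class TestLeafDeathRate:
    def test_no_stress_no_death(self, canopy_params):
        assert ss.leaf_death_rate(2.0, 1.0, canopy_params) == 0.0

    def test_double_critical_lai_maximal(self, canopy_params):
        assert ss.leaf_death_rate(8.0, 1.0, canopy_params) == canopy_params.rdr_max

    def test_full_drought_maximal_any_lai(self, canopy_params):
        assert ss.leaf_death_rate(0.5, 0.0, canopy_params) == canopy_params.rdr_max

    def test_bounded_by_rdr_max(self, canopy_params):
        for lai in (0.0, 4.0, 6.0, 20.0):
            for wf in (0.0, 0.3, 1.0):
                assert 0.0 <= ss.leaf_death_rate(lai, wf, canopy_params) <= canopy_params.rdr_max


class TestUpdateTillers:
    def test_open_sward_non_decreasing(self, canopy_params):
        state = ss.CanopyState(lai=2.0, tillers=4000.0)
        assert ss.update_tillers(state, 10.0, canopy_params) >= 4000.0

    def test_exactly_critical_lai_unchanged(self, canopy_params):
        state = ss.CanopyState(lai=canopy_params.lai_crit, tillers=4000.0)
        assert ss.update_tillers(state, 10.0, canopy_params) == 4000.0

    def test_shaded_cold_day_exponential_decline(self, canopy_params):
        state = ss.CanopyState(lai=6.0, tillers=4000.0)
        shading = (6.0 - 4.0) / 4.0
        expected = 4000.0 * (1.0 - canopy_params.tiller_death_max * shading)
        assert ss.update_tillers(state, 0.0, canopy_params) == pytest.approx(expected)


class TestApplyCanopyFluxes:
    def test_identity_when_nothing_happens(self, canopy_params):
        state = ss.CanopyState(lai=2.0, tillers=4000.0, w_leaf_green=800.0)
        frac = PartitionFractions(1.0, 0.0, 0.0)
        new = ss.apply_canopy_fluxes(state, 0.0, frac, 0.0, 5.0, canopy_params)
        assert new.w_leaf_green == state.w_leaf_green
        assert new.lai == state.lai
        assert new.tt_since_cut == state.tt_since_cut + 5.0

    def test_death_conserves_leaf_mass(self, canopy_params):
        state = ss.CanopyState(lai=5.0, tillers=4000.0, w_leaf_green=1000.0)
        frac = PartitionFractions(1.0, 0.0, 0.0)
        new = ss.apply_canopy_fluxes(state, 0.0, frac, 0.05, 0.0, canopy_params)
        assert new.w_leaf_dead == pytest.approx(50.0)
        assert new.w_leaf_green + new.w_leaf_dead == pytest.approx(1000.0)

    def test_single_sink_all_growth_to_leaf(self):
        params = ss.CanopyParameters(frac_root=0.0)
        state = ss.CanopyState(lai=1.0, tillers=4000.0, w_leaf_green=400.0)
        frac = PartitionFractions(1.0, 0.0, 0.0)
        new = ss.apply_canopy_fluxes(state, 100.0, frac, 0.0, 0.0, params)
        assert new.w_leaf_green == pytest.approx(500.0)
        assert new.lai == pytest.approx(1.0 + 100.0 * params.sla)

    def test_bad_fractions_rejected(self, canopy_params):
        state = ss.CanopyState()
        bad = PartitionFractions.__new__(PartitionFractions)
        object.__setattr__(bad, "f_leaf", 0.5)
        object.__setattr__(bad, "f_stem", 0.2)
        object.__setattr__(bad, "f_seed", 0.2)
        with pytest.raises(ConfigError):
            ss.apply_canopy_fluxes(state, 10.0, bad, 0.0, 0.0, canopy_params)

    @given(
        st.floats(0, 300), st.floats(0, 0.05), st.floats(0, 3000), st.floats(0, 15)
    )
    @settings(max_examples=100, derandomize=True)
    def test_daily_dry_matter_conservation(self, growth, rdr, green0, dtt):
        params = ss.CanopyParameters()
        state = ss.CanopyState(
            lai=green0 * params.sla, tillers=4000.0, w_leaf_green=green0,
            w_stem=200.0, w_root=100.0,
        )
        frac = PartitionFractions(0.6, 0.3, 0.1)
        new = ss.apply_canopy_fluxes(state, growth, frac, rdr, dtt, params)
        before = state.w_leaf_green + state.w_leaf_dead + state.w_stem + state.w_seed + state.w_root
        after = new.w_leaf_green + new.w_leaf_dead + new.w_stem + new.w_seed + new.w_root
        assert after - before == pytest.approx(growth, abs=1e-6)


def test_clamp01_bounds():
    assert _clamp01(-1.0) == 0.0 and _clamp01(2.0) == 1.0 and _clamp01(0.3) == 0.3
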