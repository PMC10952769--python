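import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

import swardsim as ss
from swardsim.errors import ConfigError, DomainError
from swardsim.management import (
    DEAD_LEAF_PLATEAU,
    DEFAULT_PARTITION_TABLE,
    build_schedule,
    check_harvest_trigger,
    dead_leaf_harvest_fraction,
    execute_harvest,
    partition_fractions,
)


class TestDeadLeafHarvestFraction:
    @pytest.mark.parametrize(
        "interval,expected",
        [(14, 0.0), (21, 0.0), (41, 0.07), (70, 0.1715), (100, 0.1715)],
    )
    def test_piecewise_rule(self, interval, expected):
        assert dead_leaf_harvest_fraction(interval) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("breakpoint", [21.0, 70.0])
    def test_continuity_at_breakpoints(self, breakpoint):
        eps = 1e-9
        below = dead_leaf_harvest_fraction(breakpoint - eps)
        at = dead_leaf_harvest_fraction(breakpoint)
        above = dead_leaf_harvest_fraction(breakpoint + eps)
        assert abs(at - below) < 1e-8 and abs(above - at) < 1e-8

    def test_non_positive_interval_rejected(self):
        with pytest.raises(DomainError):
            dead_leaf_harvest_fraction(0)

    @given(st.floats(1, 200), st.floats(1, 200))
    @settings(max_examples=50, derandomize=True)
    def test_non_decreasing_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        f_lo, f_hi = dead_leaf_harvest_fraction(lo), dead_leaf_harvest_fraction(hi)
        assert 0.0 <= f_lo <= f_hi <= DEAD_LEAF_PLATEAU + 1e-15


class TestPartitionFractions:
    def test_anchor_at_zero_thermal_time(self):
        f = partition_fractions(0.0)
        assert (f.f_leaf, f.f_stem, f.f_seed) == DEFAULT_PARTITION_TABLE[0][1:]

    def test_held_beyond_last_anchor(self):
        last = DEFAULT_PARTITION_TABLE[-1]
        f = partition_fractions(last[0] + 500.0)
        assert (f.f_leaf, f.f_stem, f.f_seed) == last[1:]

    @given(st.floats(0, 2000))
    @settings(max_examples=100, derandomize=True)
    def test_sums_to_one_everywhere(self, tt):
        f = partition_fractions(tt)
        assert f.f_leaf + f.f_stem + f.f_seed == pytest.approx(1.0, abs=1e-9)
        assert min(f.f_leaf, f.f_stem, f.f_seed) >= 0.0

    def test_midpoint_interpolates(self):
        (t0, l0, s0, d0), (t1, l1, s1, d1) = DEFAULT_PARTITION_TABLE[:2]
        f = partition_fractions(0.5 * (t0 + t1))
        assert f.f_leaf == pytest.approx(0.5 * (l0 + l1), abs=1e-9)

    def test_leaf_share_declines_with_thermal_time(self):
        shares = [partition_fractions(tt).f_leaf for tt in (0, 200, 400, 700, 1000)]
        assert shares == sorted(shares, reverse=True)

    def test_malformed_table_rejected(self):
        with pytest.raises(ConfigError):
            partition_fractions(100.0, table=((0.0, 0.5, 0.4, 0.0),))


class TestHarvestTrigger:
    def test_weight_mode_at_threshold_fires(self):
        rule = build_schedule(
            ss.HarvestRule(mode="weight_threshold", threshold=1500.0), 2021
        )
        assert check_harvest_trigger(rule, dt.date(2021, 6, 1), 1500.0, 10)
        assert not check_harvest_trigger(rule, dt.date(2021, 6, 1), 1499.9, 10)

    def test_interval_mode_off_schedule(self):
        rule = build_schedule(ss.HarvestRule(mode="fixed_interval", interval_days=20), 2021)
        assert not check_harvest_trigger(rule, dt.date(2021, 6, 1), 5000.0, 19)
        assert check_harvest_trigger(rule, dt.date(2021, 6, 1), 5000.0, 20)

    def test_outside_window_never_fires(self):
        rule = build_schedule(
            ss.HarvestRule(mode="weight_threshold", threshold=1500.0), 2021
        )
        assert not check_harvest_trigger(rule, dt.date(2021, 1, 15), 9000.0, 40)

    def test_final_clearing_cut_on_window_end(self):
        rule = build_schedule(ss.HarvestRule(mode="fixed_interval", interval_days=60), 2021)
        assert check_harvest_trigger(rule, rule.window_end, 100.0, 13)

    def test_date_list_exact_dates_only(self):
        dates = (dt.date(2021, 5, 15), dt.date(2021, 7, 1))
        rule = build_schedule(ss.HarvestRule(mode="date_list", dates=dates), 2021)
        assert check_harvest_trigger(rule, dt.date(2021, 5, 15), 0.0, 5)
        assert not check_harvest_trigger(rule, dt.date(2021, 5, 16), 9000.0, 6)


class TestBuildSchedule:
    def test_date_list_sorted(self):
        dates = (dt.date(2021, 8, 20), dt.date(2021, 5, 15), dt.date(2021, 7, 1))
        rule = build_schedule(ss.HarvestRule(mode="date_list", dates=dates), 2021)
        assert list(rule.dates) == sorted(dates)

    def test_duplicate_dates_rejected(self):
        dates = (dt.date(2021, 5, 15), dt.date(2021, 5, 15))
        with pytest.raises(ConfigError):
            build_schedule(ss.HarvestRule(mode="date_list", dates=dates), 2021)

    def test_empty_date_list_rejected(self):
        with pytest.raises(ConfigError):
            build_schedule(ss.HarvestRule(mode="date_list", dates=()), 2021)

    def test_out_of_year_date_rejected(self):
        with pytest.raises(ConfigError):
            build_schedule(
                ss.HarvestRule(mode="date_list", dates=(dt.date(2020, 5, 1),)), 2021
            )

    def test_default_window_applied(self):
        rule = build_schedule(ss.HarvestRule(mode="fixed_interval", interval_days=20), 2021)
        assert rule.window_start == dt.date(2021, 4, 1)
        assert rule.window_end == dt.date(2021, 10, 31)

    def test_threshold_must_exceed_residual(self):
        with pytest.raises(ConfigError):
            ss.HarvestRule(mode="weight_threshold", threshold=400.0, residual_weight=500.0)


class TestExecuteHarvest:
    @staticmethod
    def _sward(green=1500.0, stem=0.0, dead=0.0, seed=0.0, n_crop=50.0):
        canopy = ss.CanopyState(
            lai=green * 0.0025, tillers=5000.0, w_leaf_green=green,
            w_stem=stem, w_leaf_dead=dead, w_seed=seed,
        )
        nstate = ss.NitrogenState(n_mineral=10.0, n_org_remaining=0.0, n_crop=n_crop)
        return canopy, nstate

    def test_residual_proportion_leaf_only_sward(self):
        canopy, nstate = self._sward(green=1500.0)
        new_c, _, ev = execute_harvest(canopy, nstate, dt.date(2021, 6, 1), 28, 500.0)
        assert ev.removed_green_leaf == pytest.approx(1000.0)
        assert new_c.w_leaf_green == pytest.approx(500.0)
        assert new_c.tt_since_cut == 0.0

    def test_stems_cut_at_same_proportion(self):
        canopy, nstate = self._sward(green=1200.0, stem=800.0)
        new_c, _, ev = execute_harvest(canopy, nstate, dt.date(2021, 6, 1), 30, 500.0)
        p = (2000.0 - 500.0) / 2000.0
        assert ev.removed_green_leaf == pytest.approx(p * 1200.0)
        assert ev.removed_stem == pytest.approx(p * 800.0)
        assert new_c.w_leaf_green + new_c.w_stem == pytest.approx(500.0)

    def test_short_interval_no_dead_bycatch(self):
        canopy, nstate = self._sward(green=1500.0, dead=400.0)
        _, _, ev = execute_harvest(canopy, nstate, dt.date(2021, 6, 1), 14, 500.0)
        assert ev.removed_dead_leaf == 0.0

    def test_dead_bycatch_follows_interval_rule(self):
        canopy, nstate = self._sward(green=1500.0, dead=1000.0)
        _, _, ev = execute_harvest(canopy, nstate, dt.date(2021, 6, 1), 41, 500.0)
        assert ev.removed_dead_leaf == pytest.approx(0.07 * ev.removed_green_leaf)

    def test_dead_bycatch_capped_at_standing(self):
        canopy, nstate = self._sward(green=5000.0, dead=10.0)
        new_c, _, ev = execute_harvest(canopy, nstate, dt.date(2021, 6, 1), 80, 500.0)
        assert ev.removed_dead_leaf == pytest.approx(10.0)
        assert new_c.w_leaf_dead == pytest.approx(0.0)

    def test_below_residual_noop(self):
        canopy, nstate = self._sward(green=300.0)
        new_c, new_n, ev = execute_harvest(canopy, nstate, dt.date(2021, 6, 1), 28, 500.0)
        assert ev.removed_total == 0.0
        assert new_c.w_leaf_green == 300.0
        assert new_n.n_crop == nstate.n_crop

    def test_nitrogen_exported_pro_rata(self):
        canopy, nstate = self._sward(green=2000.0, n_crop=60.0)
        _, new_n, ev = execute_harvest(canopy, nstate, dt.date(2021, 6, 1), 28, 500.0)
        p = 1500.0 / 2000.0
        assert ev.removed_n == pytest.approx(p * 60.0)
        assert new_n.n_crop == pytest.approx((1 - p) * 60.0)

    @given(
        st.floats(0, 4000), st.floats(0, 3000), st.floats(0, 2000),
        st.integers(1, 120), st.floats(0, 1000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_removed_plus_residual_conserved(self, green, stem, dead, interval, residual):
        canopy, nstate = self._sward(green=green, stem=stem, dead=dead)
        new_c, _, ev = execute_harvest(
            canopy, nstate, dt.date(2021, 6, 1), interval, residual
        )
        assert new_c.w_leaf_green + ev.removed_green_leaf == pytest.approx(green, abs=1e-9)
        assert new_c.w_stem + ev.removed_stem == pytest.approx(stem, abs=1e-9)
        assert new_c.w_leaf_dead + ev.removed_dead_leaf == pytest.approx(dead, abs=1e-9)
        assert min(new_c.w_leaf_green, new_c.w_stem, new_c.w_leaf_dead) >= -1e-12
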