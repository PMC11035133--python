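"""Thermal time, photoperiod response, sowing rule, stage machine, and
photoperiod-slope calibration."""

from dataclasses import replace

import numpy as np
import pytest

import malisorghum as ms
from malisorghum.phenology import (
    DOY_JUN1,
    DOY_JUL15,
    Stage,
    UnidentifiableSlopeError,
)

from conftest import make_constant_weather


class TestThermalTime:
    def test_zero_at_base_temperature(self, csm63e):
        assert ms.daily_thermal_time(11.0, 11.0, csm63e) == 0.0

    def test_linear_between_base_and_optimum(self, csm63e):
        # mean (30+22)/2 = 26, base 11 -> 15 degCd
        assert ms.daily_thermal_time(30.0, 22.0, csm63e) == pytest.approx(15.0)

    def test_peak_at_optimum_and_zero_at_maximum(self, csm63e):
        assert ms.daily_thermal_time(30.0, 30.0, csm63e) == pytest.approx(19.0)
        assert ms.daily_thermal_time(42.0, 42.0, csm63e) == 0.0

    def test_declines_above_optimum(self, csm63e):
        assert 0 < ms.daily_thermal_time(38.0, 34.0, csm63e) < 19.0

    def test_inverted_range_rejected(self, csm63e):
        with pytest.raises(ValueError):
            ms.daily_thermal_time(20.0, 25.0, csm63e)


class TestPhotoperiodResponse:
    def test_base_duration_below_ppcrit1_both_cultivars(self, csm63e, csm335):
        """Below the minimum photoperiod both cultivars share the 50 degCd
        base duration of the juvenile-to-initiation phase."""
        assert ms.endjuv_to_init_duration(11.0, csm63e) == pytest.approx(50.0)
        assert ms.endjuv_to_init_duration(11.0, csm335) == pytest.approx(50.0)

    def test_linear_segment_value(self, csm63e):
        # 50 + 126 * (13.5 - 11.5) = 302
        assert ms.endjuv_to_init_duration(13.5, csm63e) == pytest.approx(302.0)

    def test_plateau_above_ppcrit2(self, csm63e, csm335):
        for cv in (csm63e, csm335):
            assert ms.endjuv_to_init_duration(14.5, cv) == pytest.approx(
                ms.endjuv_to_init_duration(13.5, cv))

    def test_monotone_and_flat_outside_critical_range(self, csm335):
        pps = np.linspace(9.0, 16.0, 57)
        vals = [ms.endjuv_to_init_duration(p, csm335) for p in pps]
        assert all(b - a >= -1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[0] == vals[1] == pytest.approx(50.0)  # flat below
        assert vals[-1] == vals[-2]  # flat above

    def test_photoperiod_domain(self, csm63e):
        with pytest.raises(ValueError):
            ms.endjuv_to_init_duration(0.0, csm63e)


class TestLeafNumber:
    def test_zero_thermal_time_gives_embryo_leaves(self, csm63e):
        assert ms.total_leaf_number(0.0, csm63e) == csm63e.embryo_leaves

    def test_arithmetic(self, csm63e):
        # 4 + 408/34 = 16
        assert ms.total_leaf_number(408.0, csm63e) == 16

    def test_rounding_ties_up(self, csm63e):
        # 4 + 391/34 = 15.5 -> 16
        assert ms.total_leaf_number(391.0, csm63e) == 16

    def test_monotone(self, csm335):
        tts = np.linspace(0, 900, 40)
        counts = [ms.total_leaf_number(t, csm335) for t in tts]
        assert counts == sorted(counts)


def brute_force_sowing(rain: np.ndarray, asw_ok: bool,
                       window_start: int, window_end: int) -> int:
    """Oracle: exhaustive scan of the trailing 7-day rain sums."""
    for doy in range(window_start, window_end + 1):
        if rain[max(0, doy - 7):doy].sum() >= 20.0 and asw_ok:
            return doy
    return window_end


class TestSowingRule:
    def _initial(self, profile, fraction=1.0):
        return ms.reset_fractional_asw(profile, fraction)

    def test_dry_season_forces_last_window_day(self, high_soil):
        wx = make_constant_weather(rain=0.0)
        doy = ms.sowing_date(wx, self._initial(high_soil, 0.0))
        assert doy == DOY_JUL15

    def test_steady_drizzle_triggers_on_day_seven(self, high_soil):
        """3 mm/day from 1 June: the 7-day sum first reaches 21 >= 20 mm on
        7 June (with ample stored water)."""
        wx = make_constant_weather(rain=0.0)
        wx.rain[DOY_JUN1 - 1:] = 3.0
        doy = ms.sowing_date(wx, self._initial(high_soil))
        assert doy == DOY_JUN1 + 6

    def test_matches_exhaustive_scan_oracle(self, high_soil):
        rng = np.random.default_rng(42)
        for _ in range(10):
            wx = make_constant_weather(rain=0.0)
            wet = rng.random(365) < 0.3
            wx.rain[:] = np.where(wet, rng.gamma(1.0, 8.0, 365), 0.0)
            wx.rain[:DOY_JUN1 - 10] = 0.0  # full profile keeps ASW >= 10
            expected = brute_force_sowing(wx.rain, True, DOY_JUN1, DOY_JUL15)
            assert ms.sowing_date(wx, self._initial(high_soil)) == expected

    def test_rain_alone_insufficient_when_soil_dry(self, low_soil):
        """25 mm over 3-7 June meets the rain rule; an empty profile that
        cannot hold 10 mm defers sowing past those days."""
        wx = make_constant_weather(rain=0.0, radiation=25.0, tmax=40.0, tmin=25.0)
        wx.rain[DOY_JUN1 + 1:DOY_JUN1 + 6] = 5.0
        tiny = replace(low_soil, drainage_coeff=1.0)
        state = ms.reset_fractional_asw(tiny, 0.0)
        doy_wet = ms.sowing_date(wx, ms.reset_fractional_asw(tiny, 1.0))
        # rain rule first satisfied on the oracle's day (6 June: 4 x 5 mm)
        assert doy_wet == brute_force_sowing(wx.rain, True, DOY_JUN1, DOY_JUL15)
        assert doy_wet == DOY_JUN1 + 5
        # with a bone-dry start, 25 mm minus evaporation leaves < 10 mm ASW
        doy_dry = ms.sowing_date(wx, state)
        assert doy_dry > doy_wet

    def test_window_not_covered_rejected(self, high_soil):
        wx = make_constant_weather()
        with pytest.raises(ValueError, match="window"):
            ms.sowing_date(wx, self._initial(high_soil), 300, 400)


class TestStageMachine:
    def test_flowering_to_maturity_thermal_targets(self, csm63e, csm335, high_soil):
        """Under constant forcing the thermal time attributed between the
        flowering and maturity transitions equals the cultivar coefficient
        exactly (484 / 518 degCd)."""
        wx = make_constant_weather()
        for cv, expected in ((csm63e, 484.0), (csm335, 518.0)):
            res = ms.simulate_season(wx, high_soil, cv)
            f = res.phenology.transition_tt(Stage.FLOWERING)
            m = res.phenology.transition_tt(Stage.MATURITY)
            assert m - f == pytest.approx(expected, abs=1e-9)

    def test_flowering_to_maturity_day_count(self, csm63e):
        """Started at flowering with zero carry-in, 15 degCd/day reaches
        maturity in ceil(484/15) = 33 days."""
        state = ms.new_phenology(csm63e)
        state.stage = Stage.FLOWERING
        days = 0
        while state.stage < Stage.MATURITY:
            state = ms.advance_phenology(state, 15.0, 12.0, doy=days)
            days += 1
        assert days == 33

    def test_stages_never_skip_or_reorder(self, csm335):
        state = ms.new_phenology(csm335, sow_doy=150)
        seen = [Stage.SOWING]
        for day in range(150, 365):
            state = ms.advance_phenology(state, 16.0, 12.8, doy=day)
            for stage, (doy, _) in state.transitions.items():
                if stage not in seen:
                    seen.append(stage)
        assert seen == sorted(seen)
        doys = [state.transitions[s][0] for s in sorted(state.transitions)]
        assert doys == sorted(doys)

    def test_stage_thermal_budget_conserved(self, csm63e):
        """Completed phase targets plus the current phase's accumulation
        equal the total thermal time accrued."""
        state = ms.new_phenology(csm63e, sow_doy=150)
        for day in range(150, 250):
            state = ms.advance_phenology(state, 13.7, 12.5, doy=day)
            if state.stage >= Stage.RIPE:
                break
            total = state.transitions[sorted(state.transitions)[-1]][1]
            assert total + state.tt_in_stage == pytest.approx(state.cum_tt)

    def test_ppslope_zero_makes_flowering_photoperiod_independent(self, csm63e):
        insensitive = replace(csm63e, Ppslope=0.0)
        flower_tts = []
        for pp_series in (np.full(365, 11.8), np.full(365, 13.2),
                          ms.daylength(12.5, np.arange(1, 366), 2.2)):
            state = ms.new_phenology(insensitive, sow_doy=150)
            for day in range(150, 365):
                state = ms.advance_phenology(state, 16.0,
                                             float(pp_series[day - 1]), doy=day)
                if Stage.FLOWERING in state.transitions:
                    break
            flower_tts.append(state.transition_tt(Stage.FLOWERING))
        assert len(set(np.round(flower_tts, 9))) == 1

    def test_sensitive_cultivar_flowers_later_under_long_days(
            self, csm63e, csm335, wet_weather, high_soil):
        early = ms.simulate_season(wet_weather, high_soil, csm63e)
        late = ms.simulate_season(wet_weather, high_soil, csm335)
        assert late.flowering_doy > early.flowering_doy

    def test_photoperiod_sensitivity_compresses_flowering_dates(self, csm335):
        """Across sowing dates spanning 1 June - 15 July at 12.5 degN, the
        flowering-date spread is smaller with the real photoperiod slope
        than for an insensitive control — the agronomic point of
        photoperiodism."""
        pps = ms.daylength(12.5, np.arange(1, 366), 2.2)
        spreads = {}
        for slope in (226.0, 0.0):
            cv = replace(ms.cultivar_preset("CSM335"), Ppslope=slope)
            flowering = []
            for sow in range(DOY_JUN1, DOY_JUL15 + 1, 5):
                state = ms.new_phenology(cv, sow_doy=sow)
                for day in range(sow, 365):
                    state = ms.advance_phenology(state, 16.0,
                                                 float(pps[day - 1]), doy=day)
                    if Stage.FLOWERING in state.transitions:
                        break
                flowering.append(state.transition_doy(Stage.FLOWERING))
            spreads[slope] = np.std(flowering)
        assert spreads[226.0] < spreads[0.0]


class TestSlopeCalibration:
    def test_noiseless_exact_recovery(self, csm335):
        pps = np.linspace(11.6, 13.4, 10)
        tts = [ms.endjuv_to_init_duration(p, csm335) for p in pps]
        slope, base = ms.fit_ppslope(list(zip(pps, tts)))
        assert slope == pytest.approx(226.0, abs=1e-9)
        assert base == pytest.approx(50.0, abs=1e-6)

    @pytest.mark.parametrize("name,true_slope", [
        ("CSM63E", 126.0), ("CSM335", 226.0)])
    def test_noisy_recovery_within_5pct(self, name, true_slope):
        cv = ms.cultivar_preset(name)
        rng = np.random.default_rng(7)
        pps = rng.uniform(11.6, 13.4, 20)
        tts = np.array([ms.endjuv_to_init_duration(p, cv) for p in pps])
        tts = tts + rng.normal(0.0, 10.0, 20)
        slope, _ = ms.fit_ppslope(np.column_stack([pps, tts]))
        assert slope == pytest.approx(true_slope, rel=0.05)

    def test_degenerate_design_unidentifiable(self):
        with pytest.raises(UnidentifiableSlopeError):
            ms.fit_ppslope([(12.5, 276.0), (12.5, 280.0)])

    def test_out_of_range_photoperiods_unidentifiable(self):
        with pytest.raises(UnidentifiableSlopeError):
            ms.fit_ppslope([(11.0, 50.0), (14.0, 302.0)])

    def test_estimator_interface(self):
        est = ms.PhotoperiodSlopeRegression()
        assert est.get_params() == {"ppcrit1": 11.5, "ppcrit2": 13.5}
        est.set_params(ppcrit1=11.0)
        assert est.ppcrit1 == 11.0
        est = ms.PhotoperiodSlopeRegression()
        pps = np.linspace(11.6, 13.4, 8)
        est.fit(pps, 50.0 + 126.0 * (pps - 11.5))
        np.testing.assert_allclose(
            est.predict([11.0, 12.5, 14.0]),
            [50.0, 50.0 + 126.0, 50.0 + 126.0 * 2.0], atol=1e-8)
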