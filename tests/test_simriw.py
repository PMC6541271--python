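"""Crop simulator: analytic identities, monotonicity, oracle equivalence."""

import dataclasses
import math

import numpy as np
import pytest

from cropdistill.simriw import (
    HEAT_DVI_WINDOW,
    SimulationError,
    conversion_efficiency,
    cooling_degree_sum,
    dry_matter_increment,
    dvr_grain_filling,
    dvr_pre_heading,
    harvest_index,
    lai_and_absorption,
    simulate_season,
    sterility_cool,
    sterility_heat,
)
from cropdistill.weather import OCT05_INDEX, SEASON_DAYS

from conftest import constant_weather


class TestDevelopmentalRate:
    def test_half_rate_at_th(self, params):
        # at the half-rate temperature the logistic equals 1/2 exactly
        assert dvr_pre_heading(params.Th, 12.0, 0.1, params) == 1.0 / (2 * params.Gv)

    def test_saturates_at_inverse_gv(self, params):
        assert dvr_pre_heading(1e6, 12.0, 0.1, params) == pytest.approx(
            1.0 / params.Gv, rel=1e-12)

    def test_long_days_block_development_after_sensitivity_onset(self, params):
        dvi = params.DVI_star + 0.1
        assert dvr_pre_heading(25.0, params.Lc + 0.5, dvi, params) == 0.0
        # at the critical day length the photoperiod factor itself vanishes
        assert dvr_pre_heading(25.0, params.Lc, dvi, params) == 0.0

    def test_photoperiod_factor_reduces_rate(self, params):
        dvi = params.DVI_star + 0.1
        insensitive = dvr_pre_heading(25.0, 14.5, params.DVI_star, params)
        sensitive = dvr_pre_heading(25.0, 14.5, dvi, params)
        assert 0.0 < sensitive < insensitive

    def test_grain_filling_rate(self, params):
        assert dvr_grain_filling(params.Tcr, params) == 0.0
        assert dvr_grain_filling(params.Tcr - 5.0, params) == 0.0  # floored
        assert dvr_grain_filling(1e6, params) == pytest.approx(
            1.0 / params.Gr, rel=1e-12)
        # one e-folding above the base temperature
        assert dvr_grain_filling(params.Tcr + 1.0 / params.Kr, params) == (
            pytest.approx((1.0 - math.exp(-1.0)) / params.Gr, rel=1e-12))


class TestCanopyAndGrowth:
    def test_no_canopy_absorbs_nothing(self, params):
        lai, ss = lai_and_absorption(20.0, 0.0, params)
        assert lai == 0.0 and ss == 0.0

    def test_absorption_bounded_by_incident(self, params):
        for dvi in (0.3, 0.8, 1.0, 1.5, 2.0):
            _, ss = lai_and_absorption(20.0, dvi, params)
            assert 0.0 <= ss <= 20.0

    def test_lai_peaks_at_heading(self, params):
        lai, _ = lai_and_absorption(10.0, 1.0, params)
        assert lai == pytest.approx(params.LAI_max, rel=1e-12)
        for dvi in (0.5, 1.5):
            assert lai_and_absorption(10.0, dvi, params)[0] < params.LAI_max

    def test_conversion_efficiency_co2_response(self, params):
        # at the 330 ppm reference the CO2 factor is exactly 1
        assert conversion_efficiency(0.5, 330.0, params) == params.C0
        # asymptote 1 + Rm at high CO2
        assert conversion_efficiency(0.5, 1e12, params) == pytest.approx(
            params.C0 * (1.0 + params.Rm), rel=1e-6)

    def test_conversion_efficiency_declines_during_grain_fill(self, params):
        assert (conversion_efficiency(2.0, 350.0, params)
                < conversion_efficiency(1.0, 350.0, params))

    def test_dry_matter_increment(self):
        assert dry_matter_increment(0.0, 10.0) == 0.0
        assert dry_matter_increment(1.5, 0.0) == 0.0
        assert dry_matter_increment(1.5, 10.0) == 15.0


class TestSterility:
    def test_cooling_sum_zero_at_base_temperature(self):
        tmean = np.full(10, 22.0)
        dvi = np.linspace(0.8, 1.1, 10)
        assert cooling_degree_sum(tmean, dvi) == 0.0

    def test_cooling_sum_hand_computed(self):
        tmean = np.array([20.0] * 5 + [25.0] * 5)
        dvi = np.full(10, 1.0)  # all inside the sensitive window
        assert cooling_degree_sum(tmean, dvi) == pytest.approx(10.0)

    def test_warm_days_clamped_to_zero_contribution(self):
        tmean = np.full(10, 25.0)
        dvi = np.full(10, 1.0)
        assert cooling_degree_sum(tmean, dvi) == 0.0

    def test_window_boundaries_excluded(self):
        tmean = np.full(4, 10.0)
        dvi = np.array([0.75, 1.2, 0.5, 1.5])  # all outside the open window
        assert cooling_degree_sum(tmean, dvi) == 0.0

    def test_misaligned_series_error(self):
        with pytest.raises(SimulationError):
            cooling_degree_sum(np.zeros(5), np.zeros(6))

    def test_cool_sterility_response(self, params):
        assert sterility_cool(0.0, params) == params.gamma0
        assert sterility_cool(1e9, params) == 1.0
        linear = dataclasses.replace(params, gamma0=0.0, Kq=0.01, aq=1.0)
        assert sterility_cool(10.0, linear) == pytest.approx(0.1, rel=1e-12)
        qs = np.linspace(0.0, 200.0, 50)
        gl = [sterility_cool(q, params) for q in qs]
        assert np.all(np.diff(gl) >= 0)

    def test_heat_sterility_logistic(self):
        assert sterility_heat(36.6) == 0.5
        assert sterility_heat(0.0) < 1e-13
        # frozen value of 1 / (1 + exp(-0.853 * (40 - 36.6)))
        assert sterility_heat(40.0) == pytest.approx(0.9478563, abs=1e-6)
        ths = np.linspace(20.0, 45.0, 60)
        gh = [sterility_heat(t) for t in ths]
        assert np.all(np.diff(gh) > 0)
        assert all(0.0 < g < 1.0 for g in gh)


class TestHarvestIndex:
    def test_zero_at_development_offset(self, params):
        assert harvest_index(1.22, 0.0, params) == 0.0

    def test_zero_at_full_sterility(self, params):
        assert harvest_index(2.0, 1.0, params) == 0.0

    def test_approaches_hm(self, params):
        assert harvest_index(1e6, 0.0, params) == pytest.approx(
            params.hm, rel=1e-12)

    def test_monotone_decreasing_in_sterility(self, params):
        hs = [harvest_index(2.0, g, params) for g in np.linspace(0, 1, 20)]
        assert np.all(np.diff(hs) <= 0)
        assert all(0.0 <= h <= params.hm for h in hs)


class TestSimulateSeason:
    def test_favorable_season_matures(self, params, favorable_weather):
        r = simulate_season(favorable_weather, params)
        assert r.final_dvi == 2.0
        assert r.maturity_day is not None and not r.excluded
        assert r.heading_day < r.maturity_day

    def test_cold_season_excluded(self, params, cold_weather):
        r = simulate_season(cold_weather, params)
        assert r.excluded
        assert r.final_dvi < 2.0
        assert r.dvi_by_day[OCT05_INDEX] < 2.0

    def test_yield_and_sterility_identities(self, params, mixed_series):
        for w in mixed_series:
            r = simulate_season(w, params)
            assert r.yg == r.h * r.wt_final
            assert r.gamma == max(r.gammaL, r.gammaH)
            assert 0.0 <= r.h <= params.hm

    def test_trajectories_monotone(self, params, mixed_series):
        for w in mixed_series:
            r = simulate_season(w, params)
            assert np.all(np.diff(r.dvi_by_day) >= 0)
            assert np.all(np.diff(r.wt_by_day) >= 0)
            assert np.all(r.dvi_by_day <= 2.0)

    def test_pure_function_bit_identical(self, params, mixed_series):
        a = simulate_season(mixed_series[1], params)
        b = simulate_season(mixed_series[1], params)
        np.testing.assert_array_equal(a.dvi_by_day, b.dvi_by_day)
        np.testing.assert_array_equal(a.wt_by_day, b.wt_by_day)
        assert a.yg == b.yg

    def test_heat_wave_in_anthesis_window_raises_sterility(self, params):
        w = constant_weather(tmean=26.0, tmax=31.0)
        base = simulate_season(w, params)
        lo, hi = HEAT_DVI_WINDOW
        window_days = (base.dvi_by_day > lo) & (base.dvi_by_day <= hi)
        assert window_days.any()
        hot = constant_weather(tmean=26.0, tmax=31.0)
        hot.tmax = hot.tmax.copy()
        hot.tmax[window_days] += 5.0
        heated = simulate_season(hot, params)
        assert heated.gammaH > base.gammaH
        assert heated.yg <= base.yg
        # development is temperature-mean driven, so DVI path is unchanged
        np.testing.assert_array_equal(heated.dvi_by_day, base.dvi_by_day)

    def test_boundary_final_dvi_two_is_kept(self, params, favorable_weather):
        r = simulate_season(favorable_weather, params)
        assert r.final_dvi == 2.0 and not r.excluded


# --- independent reference implementation --------------------------------

def reference_season(w, p):
    """Straight-line re-implementation of the daily loop, kept deliberately
    naive (scalar math, no shared helpers beyond parameter access)."""
    dvi = 0.0
    wt = 0.0
    dvis, wts = [], []
    for t in range(SEASON_DAYS):
        if dvi < 2.0:
            if dvi <= 1.0:
                denom = p.Gv * (1.0 + math.exp(-p.A * (w.tmean[t] - p.Th)))
                if dvi <= p.DVI_star:
                    dvr = 1.0 / denom
                elif w.day_len[t] <= p.Lc:
                    dvr = (1.0 - math.exp(p.Bp * (w.day_len[t] - p.Lc))) / denom
                else:
                    dvr = 0.0
            else:
                dvr = max(0.0, 1.0 - math.exp(-p.Kr * (w.tmean[t] - p.Tcr))) / p.Gr
            dvi = min(2.0, dvi + dvr)
            if dvi <= 0:
                lai = 0.0
            elif dvi <= 1.0:
                lai = p.LAI_max * dvi ** p.lai_rise_exp
            else:
                lai = p.LAI_max * math.exp(-p.lai_decline_rate * (dvi - 1.0))
            ss = w.s_incident[t] * (1.0 - math.exp(-p.k_beer * lai))
            if dvi < 1.0:
                c0 = p.C0
            else:
                c0 = p.Cf * (1 + p.Bf) / (1 + p.Bf * math.exp((dvi - 1.0) / p.tf))
            cs = max(0.0, c0 * (1.0 + p.Rm * (w.co2[t] - 330.0)
                                / ((w.co2[t] - 330.0) + p.Kc)))
            wt += cs * ss
        dvis.append(dvi)
        wts.append(wt)
    qt = sum(max(0.0, 22.0 - w.tmean[t])
             for t in range(SEASON_DAYS) if 0.75 < dvis[t] < 1.2)
    gl = min(1.0, max(0.0, p.gamma0 + p.Kq * qt ** p.aq))
    th_days = [t for t in range(SEASON_DAYS) if 0.96 < dvis[t] <= 1.22]
    gh = (1.0 / (1.0 + math.exp(-0.853 * (
        sum(w.tmax[t] for t in th_days) / len(th_days) - 36.6)))
        if th_days else 0.0)
    gamma = max(gl, gh)
    h = max(0.0, p.hm * (1.0 - gamma) * (1.0 - math.exp(-p.Kh * (dvis[-1] - 1.22))))
    return np.array(dvis), np.array(wts), gl, gh, h * wts[-1]


def test_oracle_equivalence_on_fixed_series(params, mixed_series):
    """Full per-day trajectories match the naive reference to 1e-9 relative."""
    assert len(mixed_series) == 5
    for w in mixed_series:
        r = simulate_season(w, params)
        dvis, wts, gl, gh, yg = reference_season(w, params)
        np.testing.assert_allclose(r.dvi_by_day, dvis, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(r.wt_by_day, wts, rtol=1e-9, atol=1e-9)
        assert r.gammaL == pytest.approx(gl, rel=1e-9)
        assert r.gammaH == pytest.approx(gh, rel=1e-9, abs=1e-12)
        assert r.yg == pytest.approx(yg, rel=1e-9, abs=1e-9)
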