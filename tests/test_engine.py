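"""Weekly engine: interpolation, response curves, stresses, EI composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecoclimex import (MonthlyClimate, accumulate_stress, annual_growth_index,
                       annual_stress_index, default_fornicatus_params,
                       degree_days_and_generations, interpolate_weekly,
                       moisture_index, run_location, spin_up_soil_moisture,
                       temperature_index, update_soil_moisture,
                       weekly_evaporation)

from conftest import balanced_constant_climate


# --- monthly -> weekly interpolation ---------------------------------------

def test_interpolation_preserves_constants():
    assert np.allclose(interpolate_weekly([7.25] * 12), 7.25, rtol=0, atol=0)


def test_interpolation_conserves_precipitation_totals():
    rng = np.random.default_rng(0)
    monthly = rng.uniform(0, 300, size=(40, 12))
    weekly = interpolate_weekly(monthly, conserve_total=True)
    assert np.allclose(weekly.sum(axis=-1), monthly.sum(axis=-1), rtol=1e-9)


def test_interpolation_sawtooth_matches_hand_linear_oracle():
    # months all 0 except December = 12; month midpoints sit at
    # (m + 0.5) * 52/12 weeks, week w samples at w + 0.5.  The two weeks
    # straddling the December midpoint (49.833): week 49 lies 12/13 of the
    # way from the November midpoint, week 50 lies 2/13 past December.
    monthly = [0.0] * 11 + [12.0]
    weekly = interpolate_weekly(monthly)
    assert weekly[49] == pytest.approx(12 * 12 / 13, rel=1e-12)
    assert weekly[50] == pytest.approx(12 * 11 / 13, rel=1e-12)


def test_interpolation_rejects_non_finite():
    with pytest.raises(ValueError):
        interpolate_weekly([np.nan] + [0.0] * 11)


# --- response curves --------------------------------------------------------

@pytest.mark.parametrize("tavg,expected", [
    (15.0, 0.0),      # development ceases at the lower threshold
    (26.0, 1.0), (30.0, 1.0), (35.0, 1.0),   # optimal range
    (20.5, 0.5),      # midpoint of the rising edge
    (37.5, 0.5),      # midpoint of the falling edge
    (40.0, 0.0), (45.0, 0.0),
])
def test_temperature_index_trapezoid(tavg, expected, params):
    assert temperature_index(tavg, params) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("sm,expected", [
    (0.05, 0.0), (0.3, 1.0), (1.0, 1.0), (2.5, 0.0),
    (0.175, 0.5), (1.75, 0.5),
])
def test_moisture_index_trapezoid(sm, expected, params):
    assert moisture_index(sm, params) == pytest.approx(expected, abs=1e-12)


def test_evaporation_floor_saturation_and_closed_form():
    assert weekly_evaporation(-5.0, 50.0, 50.0) == 0.0
    assert weekly_evaporation(25.0, 100.0, 100.0) == 0.0
    assert weekly_evaporation(10.0, 50.0, 50.0) == pytest.approx(28.0)


# --- soil moisture ----------------------------------------------------------

def test_bucket_balance_and_floor():
    assert update_soil_moisture(0.4, 20.0, 20.0, 100.0) == pytest.approx(0.4)
    assert update_soil_moisture(0.1, 0.0, 500.0, 100.0) == 0.0
    with pytest.raises(ValueError):
        update_soil_moisture(0.5, 1.0, 1.0, 0.0)


def test_spin_up_saturates_under_constant_surplus():
    # +10 mm/week into a 100 mm bucket pins the year at the waterlogging cap
    sm = spin_up_soil_moisture(np.full(52, 20.0), np.full(52, 10.0),
                               capacity=100.0, sm_cap=3.5, sm_init=0.0)
    assert np.all(sm == 3.5)


def test_spin_up_periodic_state_independent_of_initial_level():
    rng = np.random.default_rng(3)
    rain = rng.uniform(0, 60, size=(30, 52))
    evap = rng.uniform(0, 60, size=(30, 52))
    a = spin_up_soil_moisture(rain, evap, sm_init=0.0)
    b = spin_up_soil_moisture(rain, evap, sm_init=3.2)
    assert np.abs(a - b).max() < 1e-5


# --- annual indices ---------------------------------------------------------

def test_annual_growth_index_arithmetic():
    ones = np.ones(52)
    assert annual_growth_index(ones, ones) == pytest.approx(100.0)
    assert annual_growth_index(np.zeros(52), ones) == 0.0
    half = np.r_[np.ones(26), np.zeros(26)]
    assert annual_growth_index(ones, half) == pytest.approx(50.0)


def test_stress_closed_form_and_cap():
    safe = np.full(52, 20.0)
    assert accumulate_stress(safe, -10.0, -0.005, "below") == 0.0
    # 2 degree-weeks of exceedance for 52 weeks at |rate| 0.005
    cold = np.full(52, -12.0)
    assert accumulate_stress(cold, -10.0, -0.005, "below") == pytest.approx(52.0)
    assert accumulate_stress(np.full(52, -60.0), -10.0, -0.005, "below") == 100.0
    with pytest.raises(ValueError):
        accumulate_stress(safe, -10.0, -0.005, "sideways")


def test_annual_stress_index_product():
    assert annual_stress_index(0, 0, 0, 0) == 1.0
    assert annual_stress_index(100, 0, 0, 0) == 0.0
    assert annual_stress_index(50, 50, 0, 0) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        annual_stress_index(120, 0, 0, 0)


def test_degree_days_and_generations(params):
    dd, gen = degree_days_and_generations(np.full(52, 15.0), params)
    assert dd == 0.0 and gen == 0.0
    dd, gen = degree_days_and_generations(np.full(52, 25.0), params)
    assert dd == pytest.approx(3640.0)
    assert gen == pytest.approx(3640.0 / 373.0)


# --- full engine ------------------------------------------------------------

def test_ideal_constant_climate_is_highly_favourable(params):
    # optimal temperature, balanced water budget: no stress, EI = GI_A = 100
    r = run_location(balanced_constant_climate(30.0), params)
    assert r.cs == r.hs == r.ds == r.ws == 0.0
    assert r.gi_a == pytest.approx(100.0, rel=1e-9)
    assert r.ei == pytest.approx(100.0, rel=1e-9)
    assert r.ei > 20
    assert r.limiting_flags == ()


def test_deep_cold_sets_cs_flag_and_zero_ei(params):
    mc = MonthlyClimate(tmax=[-50.0] * 12, tmin=[-60.0] * 12,
                        precip=[50.0] * 12, rh09=[70.0] * 12, rh15=[50.0] * 12)
    r = run_location(mc, params)
    assert r.cs == 100.0 and r.si == 0.0 and r.ei == 0.0
    assert "CS_GE_100" in r.limiting_flags


def test_threshold_temperature_gives_zero_generations_flag(params):
    r = run_location(balanced_constant_climate(15.0), params)
    assert r.generations == 0.0
    assert r.ei == 0.0
    assert "GEN_LT_1" in r.limiting_flags


def test_flags_record_every_satisfied_condition(params):
    # cold enough for lethal cold stress AND no development AND zero TI
    mc = MonthlyClimate(tmax=[0.0] * 12, tmin=[-60.0] * 12,
                        precip=[100.0] * 12, rh09=[70.0] * 12, rh15=[50.0] * 12)
    r = run_location(mc, params)
    assert {"GEN_LT_1", "CS_GE_100", "TI_ZERO"} <= set(r.limiting_flags)


def test_ei_equals_gi_a_when_unstressed(params):
    r = run_location(balanced_constant_climate(24.0), params)
    assert r.cs == r.hs == r.ds == r.ws == 0.0
    assert r.generations >= 1
    assert r.ei == pytest.approx(r.gi_a, rel=1e-12)


def _closed_form_ei(tavg, diurnal, rh, p):
    """Independent scalar oracle for a balanced constant climate."""
    def trap(x, a, b, c, d):
        if x <= a or x >= d:
            return 0.0
        if x < b:
            return (x - a) / (b - a)
        if x <= c:
            return 1.0
        return (d - x) / (d - c)

    ti = trap(tavg, p.dv0, p.dv1, p.dv2, p.dv3)
    mi = trap(0.5, p.sm0, p.sm1, p.sm2, p.sm3)
    tmin, tmax = tavg - diurnal / 2, tavg + diurnal / 2
    cs = min(100.0, 100 * abs(p.thcs) * 52 * max(0.0, p.ttcs - tmin))
    hs = min(100.0, 100 * abs(p.thhs) * 52 * max(0.0, tmax - p.tths))
    si = (1 - cs / 100) * (1 - hs / 100)
    gi_a = 100.0 * ti * mi
    gen = max(0.0, tavg - p.dv0) * 7 * 52 / p.pdd
    ei = gi_a * si
    if gen < 1 or cs >= 100 or ti == 0:
        ei = 0.0
    return ei


@pytest.mark.parametrize("tavg", [10.0, 17.0, 22.0, 30.0, 36.0, 38.5, 41.0])
def test_constant_climate_matches_closed_form(tavg, params):
    r = run_location(balanced_constant_climate(tavg), params)
    assert r.ei == pytest.approx(_closed_form_ei(tavg, 10.0, 75.0, params),
                                 abs=1e-9)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    base=st.floats(-30, 35),
    amp=st.floats(0, 25),
    diurnal=st.floats(0, 15),
    precip=st.floats(0, 400),
    rh=st.floats(0, 100),
)
def test_ei_always_within_bounds(base, amp, diurnal, precip, rh, params):
    m = np.arange(12)
    tavg = base + amp * np.cos(2 * np.pi * (m - 6) / 12)
    mc = MonthlyClimate(tmax=tavg + diurnal / 2, tmin=tavg - diurnal / 2,
                        precip=[precip] * 12, rh09=[rh] * 12, rh15=[rh] * 12)
    r = run_location(mc, params)
    assert 0.0 <= r.ei <= 100.0
    if r.limiting_flags:
        assert r.ei == 0.0


def test_raising_dv0_never_raises_ei(params, current_grid):
    """Lifting the development threshold can only shrink growth and DD."""
    from ecoclimex import run_suitability
    sub = current_grid
    eis = []
    for dv0 in (13.0, 15.0, 17.0, 19.0):
        sg = run_suitability(sub, params.replace(dv0=dv0))
        eis.append(sg.ei.mean())
    assert all(a >= b - 1e-12 for a, b in zip(eis, eis[1:]))


def test_weekly_series_export(params):
    r = run_location(balanced_constant_climate(30.0), params, return_weekly=True)
    w = r.weekly
    assert list(w.columns) == ["week", "tavg", "tmin", "tmax", "rain", "sm",
                               "ti", "mi", "gi"]
    assert len(w) == 52
    assert w.ti.between(0, 1).all() and w.mi.between(0, 1).all()


def test_monthly_climate_invariants():
    with pytest.raises(ValueError):
        MonthlyClimate(tmax=[10.0] * 6, tmin=[0.0] * 12, precip=[0.0] * 12,
                       rh09=[50.0] * 12, rh15=[50.0] * 12)
    mc = MonthlyClimate(tmax=[5.0] * 12, tmin=[10.0] * 12, precip=[0.0] * 12,
                        rh09=[50.0] * 12, rh15=[50.0] * 12)
    assert any("tmax < tmin" in v for v in mc.violations())
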