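"""The redox-switch master equation and its derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from redoxkin import (
    RateConstants,
    SwitchParams,
    ThresholdPolicy,
    dynamic_range,
    h2o2_for_ox,
    integrate_time_course,
    ox_steady_state,
    response_time,
    response_time_at_ox,
    solve_time_course,
    sweep_dose_response,
    time_to_half_reduced,
)

k_ox_st = st.floats(min_value=10.0, max_value=1e8)
k_off_st = st.floats(min_value=1e-4, max_value=10.0)
h_st = st.floats(min_value=1e-9, max_value=1e-3)
ox_st = st.floats(min_value=1e-6, max_value=1.0 - 1e-6)


def make_rc(k_ox, k_off):
    return RateConstants("test", k_ox, k_off)


class TestOxSteadyState:
    def test_half_oxidation_at_matched_rates(self):
        rc = make_rc(100.0, 5e-3)
        assert ox_steady_state(rc, rc.k_switchoff / rc.k_ox) == pytest.approx(0.5, rel=1e-14)

    def test_zero_input_zero_oxidation(self):
        assert ox_steady_state(make_rc(24.0, 2e-3), 0.0) == 0.0

    def test_ptp1b_ninety_percent_at_750_uM(self, registry):
        rc = registry.lookup_switch("PTP1B")
        assert ox_steady_state(rc, 750e-6) == pytest.approx(0.90, abs=5e-4)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            ox_steady_state(make_rc(1.0, 1.0), -1e-9)


class TestH2O2ForOx:
    def test_ptp1b_co2_half_oxidation(self, registry):
        rc = registry.lookup_switch("PTP1B+CO2")
        assert h2o2_for_ox(rc, 0.5) == pytest.approx(5.05e-6, rel=1e-3)

    def test_prx2_ninety_percent(self, registry):
        rc = registry.lookup_switch("Prx2")
        assert h2o2_for_ox(rc, 0.9) == pytest.approx(1.8e-6, rel=1e-12)

    @given(k_ox=k_ox_st, k_off=k_off_st)
    def test_half_oxidation_is_rate_ratio(self, k_ox, k_off):
        assert h2o2_for_ox(make_rc(k_ox, k_off), 0.5) == pytest.approx(k_off / k_ox, rel=1e-12)

    @pytest.mark.parametrize("ox", [0.0, 1.0, -0.1, 1.5])
    def test_saturation_not_invertible(self, ox):
        with pytest.raises(ValueError):
            h2o2_for_ox(make_rc(1.0, 1.0), ox)

    @given(k_ox=k_ox_st, k_off=k_off_st, h=h_st)
    def test_inverse_identity(self, k_ox, k_off, h):
        rc = make_rc(k_ox, k_off)
        ox = ox_steady_state(rc, h)
        # near saturation 1-ox is limited by the fraction's own double-precision
        # resolution (spacing eps near 1), which floors the achievable accuracy
        rel = max(1e-10, 4 * np.finfo(float).eps / (1.0 - ox))
        assert h2o2_for_ox(rc, ox) == pytest.approx(h, rel=rel)


class TestDynamicRange:
    @pytest.mark.parametrize(
        "name,low_um,high_um",
        [
            ("PTP1B", 9.26, 750.0),
            ("SHP-2", 11.1, 900.0),
            ("Prx5", 0.74, 60.0),
        ],
    )
    def test_literature_ranges(self, registry, name, low_um, high_um):
        dr = dynamic_range(registry.lookup_switch(name))
        assert dr.h_low * 1e6 == pytest.approx(low_um, rel=1e-2)
        assert dr.h_high * 1e6 == pytest.approx(high_um, rel=1e-2)

    @given(k_ox=k_ox_st, k_off=k_off_st)
    def test_eightyone_fold_span(self, k_ox, k_off):
        dr = dynamic_range(make_rc(k_ox, k_off))
        assert dr.span == pytest.approx(81.0, rel=1e-12)
        assert 0 < dr.h_low < dr.h_high

    def test_span_follows_threshold_odds(self):
        pol = ThresholdPolicy(ox_low=0.2, ox_high=0.8)
        dr = dynamic_range(make_rc(100.0, 1e-2), pol)
        assert dr.span == pytest.approx(16.0, rel=1e-12)

    def test_fixed_ratio_law(self):
        # same k_switchoff/k_ox -> identical dynamic range, exactly
        a = dynamic_range(make_rc(24.0, 2e-3))
        b = dynamic_range(make_rc(24000.0, 2.0))
        assert (a.h_low, a.h_high) == (b.h_low, b.h_high)


class TestTimeCourse:
    def test_initial_condition_and_complement(self):
        params = SwitchParams(make_rc(396.0, 2e-3), h2o2=5e-6, rd0=0.8)
        course = solve_time_course(params, np.linspace(0.0, 1000.0, 11))
        assert course.rd[0] == pytest.approx(0.8, rel=1e-14)
        np.testing.assert_allclose(course.rd + course.ox, 1.0, rtol=1e-14)

    def test_relaxes_to_steady_state(self):
        rc = make_rc(396.0, 2e-3)
        h = 5e-6
        lam = rc.k_ox * h + rc.k_switchoff
        course = solve_time_course(SwitchParams(rc, h), [0.0, 20.0 / lam, 40.0 / lam])
        rd_ss = rc.k_switchoff / lam
        assert abs(course.rd[-1] - rd_ss) < 1e-8

    @pytest.mark.parametrize(
        "k_ox,k_off,h,rd0",
        [
            (24.0, 2e-3, 5e-6, 1.0),
            (1e7, 2.0, 1e-6, 1.0),
            (396.0, 2e-3, 1e-4, 0.3),
            (1e8, 10.0, 1e-3, 0.0),
        ],
    )
    def test_closed_form_matches_numeric_integration(self, k_ox, k_off, h, rd0):
        params = SwitchParams(make_rc(k_ox, k_off), h2o2=h, rd0=rd0)
        lam = k_ox * h + k_off
        times = np.linspace(0.0, 10.0 / lam, 40)
        closed = solve_time_course(params, times)
        numeric = integrate_time_course(params, times)
        assert np.max(np.abs(closed.rd - numeric.rd)) < 1e-6

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            solve_time_course(SwitchParams(make_rc(1.0, 1.0), 1e-6), [0.0, 2.0, 1.0])


class TestResponseTime:
    def test_reduction_only_limit(self):
        rc = make_rc(24.0, 2e-3)
        assert response_time(rc, 0.0) == pytest.approx(math.log(2) / 2e-3, rel=1e-12)

    def test_ptp1b_at_half_oxidation(self, registry):
        rc = registry.lookup_switch("PTP1B")
        t = response_time(rc, h2o2_for_ox(rc, 0.5))
        assert t == pytest.approx(173.3, rel=1e-3)

    def test_prx2_at_one_micromolar(self, registry):
        rc = registry.lookup_switch("Prx2")
        assert response_time(rc, 1e-6) == pytest.approx(math.log(2) / 12.0, rel=1e-12)

    @pytest.mark.parametrize(
        "k_off,expected",
        [(2e-3, 173.3), (2.0, 0.1733)],
    )
    def test_half_time_at_fifty_percent_depends_only_on_k_switchoff(self, k_off, expected):
        assert response_time_at_ox(make_rc(123.0, k_off), 0.5) == pytest.approx(expected, rel=1e-3)

    @given(k_ox=k_ox_st, k_off=k_off_st, ox=ox_st)
    def test_two_forms_agree(self, k_ox, k_off, ox):
        rc = make_rc(k_ox, k_off)
        assert response_time_at_ox(rc, ox) == pytest.approx(
            response_time(rc, h2o2_for_ox(rc, ox)), rel=1e-10
        )

    def test_sum_law(self):
        # permuting the (k_ox*H, k_off) contributions at fixed sum leaves t unchanged
        t1 = response_time(make_rc(1000.0, 0.5), 2e-3)  # 1000*2e-3 + 0.5 = 2.5
        t2 = response_time(make_rc(500.0, 2.0), 1e-3)  # 500*1e-3 + 2.0 = 2.5
        assert t1 == pytest.approx(t2, rel=1e-12)
        assert t1 == pytest.approx(math.log(2) / 2.5, rel=1e-12)


class TestTimeToHalfReduced:
    def test_matches_trajectory_crossing(self):
        params = SwitchParams(make_rc(396.0, 2e-3), h2o2=100e-6)  # ox_ss ~ 0.95
        t_half = time_to_half_reduced(params)
        course = solve_time_course(params, [0.0, t_half])
        assert course.rd[-1] == pytest.approx(0.5, rel=1e-10)

    def test_undefined_below_half_oxidation(self):
        rc = make_rc(396.0, 2e-3)
        params = SwitchParams(rc, h2o2=h2o2_for_ox(rc, 0.5))  # plateau exactly 50%
        with pytest.raises(ValueError, match="never"):
            time_to_half_reduced(params)


class TestSweep:
    def test_endpoint_oxidations(self, registry):
        rc = registry.lookup_switch("PTP1B")
        df = sweep_dose_response(rc, np.array([9.26e-6, 750e-6]))
        np.testing.assert_allclose(df["ox_ss"], [0.10, 0.90], atol=5e-4)
        assert df["in_dynamic_range"].all()

    def test_monotone_in_dose(self, registry):
        rc = registry.lookup_switch("Prx5")
        df = sweep_dose_response(rc, np.logspace(-8, -3, 30))
        assert (np.diff(df["ox_ss"]) > 0).all()
        assert (np.diff(df["t_half_s"]) < 0).all()

    def test_range_scales_with_k_switchoff(self):
        # dynamic range shifts proportionally to the reduction rate
        lows = [dynamic_range(make_rc(3e5, k)).h_low for k in (0.2, 2.0, 20.0)]
        assert lows[1] / lows[0] == pytest.approx(10.0, rel=1e-12)
        assert lows[2] / lows[1] == pytest.approx(10.0, rel=1e-12)

    def test_invalid_grid_rejected(self, registry):
        rc = registry.lookup_switch("PTP1B")
        with pytest.raises(ValueError):
            sweep_dose_response(rc, np.array([1e-6, 1e-6]))
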