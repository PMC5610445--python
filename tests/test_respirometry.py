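"""Calibration, Lighton mass balance, STP correction and RMR extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoneutral.respirometry import (
    CalibrationError,
    CalibrationPair,
    RespirometryTrace,
    TraceTooShortError,
    VO2Series,
    calibrate_trace,
    compute_vo2,
    extract_rmr,
    stp_correct,
    trace_to_vo2,
)


def make_trace(raw, t=None, **kw):
    raw = np.asarray(raw, dtype=float)
    if t is None:
        t = np.arange(raw.size, dtype=float)
    kw.setdefault("chamber_temp_c", 22.0)
    return RespirometryTrace(timestamps=t, raw_o2=raw, **kw)


class TestCalibration:
    def test_span_gas_maps_to_span_fraction(self):
        cal = CalibrationPair(0.1, 0.9, 0.0)
        frac, _ = calibrate_trace(make_trace([0.9, 0.9]), cal,
                                  CalibrationPair(0.1, 0.9, 1.0))
        assert frac == pytest.approx([0.2095, 0.2095])

    def test_zero_gas_maps_to_zero(self):
        cal = CalibrationPair(0.1, 0.9, 0.0)
        frac, _ = calibrate_trace(make_trace([0.1, 0.1]), cal,
                                  CalibrationPair(0.1, 0.9, 1.0))
        assert frac == pytest.approx([0.0, 0.0])

    def test_drift_interpolated_at_midpoint(self):
        # zero drifts 0.10 -> 0.12, span 0.90 -> 0.92; at the midpoint the
        # effective pair is (0.11, 0.91): 0.2095 * (0.52-0.11) / 0.80
        trace = make_trace([0.5, 0.52, 0.5], t=[0.0, 50.0, 100.0])
        frac, _ = calibrate_trace(trace, CalibrationPair(0.10, 0.90, 0.0),
                                  CalibrationPair(0.12, 0.92, 100.0))
        assert frac[1] == pytest.approx(0.2095 * 0.41 / 0.80, abs=1e-12)
        assert frac[1] == pytest.approx(0.10737, abs=5e-6)

    def test_out_of_band_samples_flagged(self):
        cal = CalibrationPair(0.0, 1.0, 0.0)
        trace = make_trace([0.5, 2.0, -0.2])
        frac, out = calibrate_trace(trace, cal, CalibrationPair(0.0, 1.0, 2.0))
        assert out.tolist() == [False, True, True]

    def test_span_not_above_zero_rejected(self):
        with pytest.raises(CalibrationError):
            CalibrationPair(0.9, 0.9, 0.0)

    def test_missing_end_pair_warns_and_uses_start_only(self):
        trace = make_trace([0.9, 0.9])
        with pytest.warns(UserWarning, match="no end calibration"):
            frac, _ = calibrate_trace(trace, CalibrationPair(0.1, 0.9, 0.0))
        assert frac == pytest.approx([0.2095, 0.2095])


class TestLightonAndStp:
    @pytest.mark.parametrize(
        "fi,fe,flow,expected",
        [
            (0.2095, 0.2095, 350.0, 0.0),
            (0.2095, 0.2050, 350.0, 350 * 0.0045 / 0.795),
            (0.2095, 0.2100, 350.0, 350 * -0.0005 / 0.79),
        ],
    )
    def test_mass_balance(self, fi, fe, flow, expected):
        assert compute_vo2(fi, fe, flow) == pytest.approx(expected, abs=1e-9)

    def test_worked_example_printed_value(self):
        assert compute_vo2(0.2095, 0.2050, 350.0) == pytest.approx(1.9811, abs=1e-4)

    def test_negative_drawdown_flagged_downstream(self):
        trace = make_trace([0.9, 1.0, 0.9], flow_ml_min=350.0)
        trace.chamber_temp_c[:] = 0.0  # STP factor 1
        series = trace_to_vo2(trace, CalibrationPair(0.1, 0.9, 0.0),
                              CalibrationPair(0.1, 0.9, 2.0))
        assert series.negative_drawdown.tolist() == [False, True, False]
        assert series.vo2_ml_min[1] < 0

    def test_excurrent_fraction_one_is_domain_error(self):
        with pytest.raises(ValueError):
            compute_vo2(0.2095, 1.0, 350.0)

    @pytest.mark.parametrize(
        "vo2,temp,press,expected",
        [
            (1.0, 0.0, 101.325, 1.0),
            (100.0, 22.0, 101.325, 100 * 273.15 / 295.15),
            (1.0, 0.0, 50.6625, 0.5),
        ],
    )
    def test_stp_correction(self, vo2, temp, press, expected):
        assert stp_correct(vo2, temp, press) == pytest.approx(expected, rel=1e-9)

    def test_stp_rejects_nonphysical_inputs(self):
        with pytest.raises(ValueError):
            stp_correct(1.0, -300.0, 101.325)
        with pytest.raises(ValueError):
            stp_correct(1.0, 20.0, 0.0)


def series_from(vo2, flags=None):
    vo2 = np.asarray(vo2, dtype=float)
    return VO2Series(np.arange(vo2.size, dtype=float), vo2,
                     out_of_calibration=flags)


def brute_force_min_window(series, w, first, cv_max):
    """Independent window scan used as the oracle for extract_rmr."""
    x, bad = series.vo2_ml_min, series.flagged
    best = None
    for s in range(first, x.size - w + 1):
        win = x[s:s + w]
        if bad[s:s + w].any():
            continue
        m = win.mean()
        if m <= 0 or win.std() / m > cv_max:
            continue
        if best is None or m < best:
            best = m
    return best


class TestExtractRmr:
    def test_constant_trace(self):
        res = extract_rmr(series_from(np.full(3600, 2.0)), 100.0)
        assert res.valid
        assert res.rmr_ml_h == pytest.approx(120.0)
        assert res.msrmr == pytest.approx(1.2)
        assert res.window_cv == pytest.approx(0.0, abs=1e-12)

    def test_plateau_minimum(self):
        vo2 = np.r_[np.full(1200, 3.0), np.full(2400, 1.5)]
        res = extract_rmr(series_from(vo2), 100.0, acclimation_s=0.0)
        assert res.rmr_ml_h == pytest.approx(90.0)
        assert res.window_start_s >= 1200

    def test_linear_ramp_picks_final_window(self):
        vo2 = np.linspace(2.0, 1.0, 3600)
        s = series_from(vo2)
        res = extract_rmr(s, 100.0, acclimation_s=0.0)
        oracle = brute_force_min_window(s, 600, 0, 0.10)
        assert res.rmr_ml_h / 60.0 == pytest.approx(oracle, rel=1e-12)
        assert res.rmr_ml_h / 60.0 == pytest.approx(1.0833, abs=2e-3)
        assert res.window_end_s == pytest.approx(3599.0 + 1.0, abs=1.0)

    def test_msrmr_is_rmr_over_mass_exactly(self):
        res = extract_rmr(series_from(np.full(3600, 1.7)), 85.0)
        assert res.msrmr == res.rmr_ml_h / 85.0

    def test_flagged_samples_exclude_windows(self):
        vo2 = np.full(3600, 2.0)
        vo2[2000:2100] = 0.1  # artificially low but flagged
        flags = np.zeros(3600, bool)
        flags[2000:2100] = True
        res = extract_rmr(series_from(vo2, flags), 100.0, acclimation_s=0.0)
        assert res.valid
        assert res.rmr_ml_h == pytest.approx(120.0)

    def test_no_clean_window_reports_reason(self):
        flags = np.ones(3600, bool)
        res = extract_rmr(series_from(np.full(3600, 2.0), flags), 100.0,
                          acclimation_s=0.0)
        assert not res.valid and res.reason == "no-clean-window"

    def test_unstable_trace_reports_reason(self):
        rng = np.random.default_rng(0)
        vo2 = rng.uniform(0.1, 4.0, 3600)  # CV far above threshold
        res = extract_rmr(series_from(vo2), 100.0, acclimation_s=0.0,
                          stability_cv=0.05)
        assert not res.valid and res.reason == "no-stable-window"

    def test_too_short_raises(self):
        with pytest.raises(TraceTooShortError):
            extract_rmr(series_from(np.full(500, 2.0)), 100.0,
                        acclimation_s=0.0)
        with pytest.raises(TraceTooShortError):
            extract_rmr(series_from(np.full(2000, 2.0)), 100.0,
                        acclimation_s=1800.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_global_minimality_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1500, 2500))
        vo2 = np.abs(rng.normal(2.0, 0.05, n)) + 0.5
        flags = rng.random(n) < 0.01
        s = series_from(vo2, flags)
        oracle = brute_force_min_window(s, 600, 0, 0.10)
        res = extract_rmr(s, 100.0, acclimation_s=0.0)
        if oracle is None:
            assert not res.valid
        else:
            assert res.rmr_ml_h / 60.0 == pytest.approx(oracle, rel=1e-12)
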