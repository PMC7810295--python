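"""Landmark extraction: interpolation, roll-off detection, tie-breaking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfacurve import DataError, ImpedanceCurve, NoRolloffError, extract_parameters
from rfacurve.params import (
    detect_rolloff,
    estimate_initial_impedance,
    value_at_time,
)


def curve(t, z, sid="c"):
    return ImpedanceCurve(sid, np.asarray(t, float), np.asarray(z, float))


class TestValueAtTime:
    @pytest.mark.parametrize(
        "t, z, tq, expected",
        [
            ([0, 5, 10], [100, 90, 80], 5, 90.0),   # exact sample hit
            ([0, 5, 10], [100, 90, 80], 0, 100.0),  # endpoint identity
            ([0, 2, 4], [100, 70, 90], 3, 80.0),    # midpoint of a segment
            ([0, 5, 10], [100, 90, 80], 2.5, 95.0),
        ],
    )
    def test_linear_interpolation(self, t, z, tq, expected):
        assert value_at_time(curve(t, z), tq) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(DataError):
            value_at_time(curve([0, 5, 10], [100, 90, 80]), 11.0)


class TestInitialImpedance:
    def test_default_is_first_sample(self):
        c = curve([0, 1, 2], [100, 102, 98])
        assert estimate_initial_impedance(c) == 100.0

    def test_mean_of_first_k(self):
        c = curve([0, 1, 2], [100, 102, 98])
        assert estimate_initial_impedance(c, k=3) == pytest.approx(100.0)

    @pytest.mark.parametrize("k", [0, 4])
    def test_bad_k(self, k):
        with pytest.raises(ValueError):
            estimate_initial_impedance(curve([0, 1, 2], [1, 2, 3]), k=k)


class TestDetectRolloff:
    def test_threshold_crossing_interpolated(self):
        c = curve([0, 10, 20], [100, 80, 200])
        t_end, z_end = detect_rolloff(c, mode="threshold", Z_initial=100.0)
        # crossing of 150 ohm on the [10, 20] segment
        assert t_end == pytest.approx(10 + 10 * (150 - 80) / (200 - 80))
        assert z_end == pytest.approx(150.0)

    def test_log_end_is_last_sample(self):
        c = curve([0, 10, 20], [100, 80, 200])
        assert detect_rolloff(c, mode="log_end") == (20.0, 200.0)

    def test_no_crossing_reports_max(self):
        c = curve([0, 10, 20], [100, 80, 120])
        with pytest.raises(NoRolloffError) as exc:
            detect_rolloff(c, mode="threshold", Z_initial=100.0)
        assert exc.value.max_impedance == 120.0

    def test_threshold_ignores_early_high_readings(self):
        # averaged Z_initial of 100 -> level 150; the early 160-ohm spike
        # precedes the minimum and must not trigger
        c = curve([0, 1, 2, 3, 4, 5], [160, 40, 30, 35, 100, 200])
        t_end, z_end = detect_rolloff(c, mode="threshold", Z_initial=100.0)
        assert t_end > 4.0 and z_end == 150.0


class TestExtractParameters:
    def test_direct_landmark_reading(self, simple_curve):
        p = extract_parameters(simple_curve, mode="log_end")
        assert (p.t_end, p.t_half, p.t_minimum) == (100.0, 50.0, 50.0)
        assert (p.Z_initial, p.Z_half, p.Z_minimum, p.Z_end) == (100, 80, 80, 150)

    def test_symmetric_v_curve_minimum_at_half(self):
        t = np.arange(0.0, 101.0)
        z = 50.0 + np.abs(t - 50.0)
        p = extract_parameters(curve(t, z))
        assert p.t_minimum == p.t_half == 50.0

    def test_monotone_rise_minimum_at_start(self):
        t = np.arange(0.0, 10.0)
        p = extract_parameters(curve(t, 100.0 + 10 * t))
        assert p.t_minimum == 0.0
        assert p.Z_minimum == p.Z_initial == 100.0

    def test_tie_break_earliest_minimum(self):
        base = curve([0, 10, 20, 30, 40], [100, 80, 90, 80, 150])
        p = extract_parameters(base)
        assert p.t_minimum == 10.0

    def test_time_offset_invariance(self, simple_curve):
        shifted = ImpedanceCurve("s", simple_curve.t + 37.5, simple_curve.Z)
        a = extract_parameters(simple_curve)
        b = extract_parameters(shifted)
        for f in ("t_end", "t_half", "t_minimum", "Z_initial", "Z_half",
                  "Z_minimum", "Z_end"):
            assert getattr(a, f) == getattr(b, f)

    def test_mode_consistency_when_log_ends_at_threshold(self):
        # last sample sits exactly at 1.5 * Z_initial
        c = curve([0, 10, 20, 30], [100, 70, 100, 150])
        a = extract_parameters(c, mode="log_end")
        b = extract_parameters(c, mode="threshold")
        assert a.t_end == pytest.approx(b.t_end)
        assert a.Z_end == pytest.approx(b.Z_end)

    def test_threshold_mode_pins_z_end(self):
        c = curve([0, 10, 20, 30], [100, 70, 120, 300])
        p = extract_parameters(c, mode="threshold", factor=1.5)
        assert p.Z_end == pytest.approx(1.5 * p.Z_initial)
        assert p.t_end < 30.0

    def test_median_filter_requires_odd_window(self, simple_curve):
        with pytest.raises(ValueError):
            extract_parameters(simple_curve, median_window=4)

    @settings(max_examples=25, deadline=None)
    @given(
        t_min_frac=st.floats(min_value=0.15, max_value=0.85),
        z_init=st.floats(min_value=66, max_value=117),
        drop=st.floats(min_value=0.05, max_value=0.5),
    )
    def test_analytic_oracle_on_dense_parabola(self, t_min_frac, z_init, drop):
        """A dense parabolic valley's landmarks match closed form: times to
        one sampling interval, impedances to 0.5%."""
        t_end, dt = 200.0, 0.25
        t_min = t_min_frac * t_end
        z_min = z_init * (1 - drop)
        t = np.arange(0.0, t_end + dt / 2, dt)
        a = (z_init - z_min) / t_min**2
        z = z_min + a * (t - t_min) ** 2
        p = extract_parameters(curve(t, z))
        assert abs(p.t_minimum - t_min) <= dt
        assert p.Z_minimum == pytest.approx(z_min, rel=5e-3)
        assert p.Z_initial == pytest.approx(z_init, rel=5e-3)
        z_half_true = z_min + a * (t_end / 2 - t_min) ** 2
        assert p.Z_half == pytest.approx(z_half_true, rel=5e-3)
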