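"""Absorbance → loading / cumulative-release quantitation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import releasefit as rf
from releasefit.errors import (
    DomainError,
    InsufficientDataError,
    OrderingError,
    ValidationError,
)


def cal(k=0.04, b=0.002):
    return rf.CalibrationLine(k, b, wavelength_nm=254.0)


class TestLoadingCapacity:
    @pytest.mark.parametrize(
        "k, b, A, V, G, expected",
        [
            (0.05, 0.0, 0.0, 0.25, 1.0, 0.0),       # zero absorbance, zero intercept
            (0.04, 0.002, 0.5, 0.25, 2.0, 0.00275),  # hand arithmetic
            (1.0, 0.0, 1.0, 1.0, 1.0, 1.0),          # identity case
        ],
    )
    def test_values(self, k, b, A, V, G, expected):
        la = rf.loading_capacity(
            rf.CalibrationLine(k, b), rf.LoadingMeasurement(A, V, G)
        )
        assert la == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(DomainError):
            rf.LoadingMeasurement(0.5, 0.25, 0.0)

    def test_negative_concentration_is_flagged_not_raised(self):
        with pytest.warns(UserWarning, match="below the calibration range"):
            la = rf.loading_capacity(
                rf.CalibrationLine(0.04, -0.5), rf.LoadingMeasurement(0.1, 0.25, 1.0)
            )
        assert la < 0

    @given(A=st.floats(0.0, 5.0))
    def test_linearity_in_absorbance(self, A):
        c = rf.CalibrationLine(0.05, 0.0)
        one = rf.loading_capacity(c, rf.LoadingMeasurement(A, 0.25, 1.0))
        two = rf.loading_capacity(c, rf.LoadingMeasurement(2 * A, 0.25, 1.0))
        assert two == pytest.approx(2 * one, abs=1e-12)


class TestCumulativeRelease:
    def test_full_release_is_100_percent(self):
        # released mass (k·At+b)·V1 exactly equals LA·G1
        q = rf.cumulative_release(
            rf.CalibrationLine(0.1, 0.0), rf.ReleaseMeasurement(30.0, 2.0),
            volume_V1=0.1, fabric_mass_G1=2.0, LA=0.01,
        )
        assert q == pytest.approx(100.0)

    def test_half_release_hand_value(self):
        q = rf.cumulative_release(
            cal(), rf.ReleaseMeasurement(10.0, 0.5), 0.15, 1.0, LA=0.0066
        )
        assert q == pytest.approx(50.0)

    def test_zero_concentration_gives_zero(self):
        c = rf.CalibrationLine(0.04, -0.002)  # At = -b/k = 0.05 → zero conc
        q = rf.cumulative_release(c, rf.ReleaseMeasurement(5.0, 0.05), 0.15, 1.0, 0.01)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_no_loading_rejected(self):
        with pytest.raises(DomainError):
            rf.cumulative_release(cal(), rf.ReleaseMeasurement(5.0, 0.1), 0.15, 1.0, 0.0)

    @given(LA=st.floats(1e-4, 1.0))
    def test_absolute_released_mass_independent_of_normaliser(self, LA):
        rm = rf.ReleaseMeasurement(5.0, 0.8)
        q = rf.cumulative_release(cal(), rm, 0.15, 1.0, LA)
        assert q * LA == pytest.approx(
            cal().concentration(0.8) * 0.15 / 1.0 * 100.0, rel=1e-12
        )


class TestBuildReleaseCurve:
    def series(self, absorbances, times=None):
        times = times if times is not None else np.arange(1.0, len(absorbances) + 1)
        return [rf.ReleaseMeasurement(t, a) for t, a in zip(times, absorbances)]

    def test_constant_absorbance_gives_constant_release(self):
        curve = rf.build_release_curve(self.series([0.3] * 5), cal(), 0.15, 1.0, 0.02)
        assert len(curve) == 5
        assert np.ptp(curve.qt) == 0.0

    def test_out_of_range_release_fails_validation(self):
        # one reading implying 115 % release
        c = rf.CalibrationLine(1.0, 0.0)
        bad = self.series([0.1, 0.2, 0.3, 1.15])
        with pytest.raises(ValidationError, match="exceeds"):
            rf.build_release_curve(bad, c, 1.0, 1.0, 1.0)

    def test_short_or_empty_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            rf.build_release_curve([], cal(), 0.15, 1.0, 0.02)
        with pytest.raises(InsufficientDataError):
            rf.build_release_curve(self.series([0.1] * 3), cal(), 0.15, 1.0, 0.02)

    def test_nonincreasing_times_rejected(self):
        bad = self.series([0.1, 0.2, 0.3, 0.4], times=[1.0, 2.0, 2.0, 3.0])
        with pytest.raises(OrderingError):
            rf.build_release_curve(bad, cal(), 0.15, 1.0, 0.02)

    def test_length_preserved_when_all_points_validate(self):
        curve = rf.build_release_curve(
            self.series(np.linspace(0.05, 0.5, 8)), cal(), 0.15, 1.0, 0.02
        )
        assert len(curve) == 8


class TestReleaseCurveContainer:
    def test_overshoot_band_warns_but_passes(self):
        with pytest.warns(UserWarning, match="above 100"):
            curve = rf.ReleaseCurve("x", [1.0, 2.0], [50.0, 105.0])
        assert curve.qt[-1] == 105.0

    def test_csv_round_trip(self, tmp_path, simple_curve):
        path = tmp_path / "demo.csv"
        simple_curve.to_csv(path)
        back = rf.read_curve_csv(path, drug_id="demo")
        np.testing.assert_allclose(back.times, simple_curve.times)
        np.testing.assert_allclose(back.qt, simple_curve.qt)

    def test_calibration_line_validation(self):
        with pytest.raises(ValidationError):
            rf.CalibrationLine(-0.1)
        with pytest.raises(ValidationError):
            rf.CalibrationLine(0.1, wavelength_nm=500.0)

    def test_estimate_calibration_recovers_line(self):
        absorb = np.linspace(0.1, 1.0, 6)
        conc = 0.04 * absorb + 0.002
        fitted = rf.estimate_calibration(conc, absorb)
        assert fitted.slope_k == pytest.approx(0.04)
        assert fitted.intercept_b == pytest.approx(0.002, abs=1e-12)
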