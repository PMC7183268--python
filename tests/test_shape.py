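"""Sphericity statistic, classification and grid aggregation."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsize import datasets
from capsize.core import CapsuleBatch, CapsuleMeasurement, ConditionGrid, ValidationError
from capsize.shape import (
    AggregateCurve,
    GridAxis,
    ShapeClass,
    batch_summary,
    classify,
    grid_average,
    percent_change,
    sphericity_factor,
    threshold_crossing,
)
from capsize.synthetic import gen_capsule_batch

diameters = st.floats(min_value=0.1, max_value=100.0,
                      allow_nan=False, allow_infinity=False)


class TestSphericityFactor:
    @pytest.mark.parametrize(
        "d_max,d_min,expected",
        [
            (4.0, 4.0, 0.0),
            (3.0, 1.0, 0.5),           # (3−1)/(3+1)
            (4.4, 4.0, 1.0 / 21.0),    # 0.4/8.4
        ],
    )
    def test_values(self, d_max, d_min, expected):
        assert sphericity_factor(d_max, d_min) == pytest.approx(expected)

    @pytest.mark.parametrize("d_max,d_min", [(4.0, 0.0), (4.0, -1.0), (3.0, 3.5)])
    def test_domain_errors(self, d_max, d_min):
        with pytest.raises(ValidationError):
            sphericity_factor(d_max, d_min)

    @settings(deadline=None, derandomize=True)
    @given(a=diameters, b=diameters,
           k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, a, b, k):
        d_max, d_min = max(a, b), min(a, b)
        assert sphericity_factor(k * d_max, k * d_min) == pytest.approx(
            sphericity_factor(d_max, d_min), rel=1e-9, abs=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(d=diameters, eps=st.floats(min_value=1e-3, max_value=1.0))
    def test_strictly_increasing_in_d_max(self, d, eps):
        assert sphericity_factor(d + eps, d) > sphericity_factor(d, d)

    @settings(deadline=None, derandomize=True)
    @given(d=diameters, eps=st.floats(min_value=1e-3, max_value=0.05))
    def test_strictly_decreasing_in_d_min(self, d, eps):
        d_max = d * 1.2
        assert sphericity_factor(d_max, d * (1 - eps)) > sphericity_factor(d_max, d)


class TestClassify:
    @pytest.mark.parametrize(
        "sf,expected",
        [
            (0.087, ShapeClass.DEFORMED),   # measured pear-shaped batch
            (0.069, ShapeClass.SPHERICAL),
            (0.07, ShapeClass.DEFORMED),    # strict inequality at the boundary
            (0.0, ShapeClass.SPHERICAL),
        ],
    )
    def test_threshold(self, sf, expected):
        assert classify(sf) is expected

    @settings(deadline=None, derandomize=True)
    @given(sf=st.floats(min_value=0.0, max_value=0.99))
    def test_never_spherical_at_or_above_threshold(self, sf):
        if classify(sf) is ShapeClass.SPHERICAL:
            assert sf < 0.07

    def test_negative_sf_rejected(self):
        with pytest.raises(ValidationError):
            classify(-0.01)


class TestBatchSummary:
    def test_identical_capsules_sd_zero(self):
        batch = CapsuleBatch(
            tuple(CapsuleMeasurement(4.2, 4.0) for _ in range(15))
        )
        s = batch_summary(batch)
        assert s.sd_sf == 0.0 and s.sd_d == 0.0 and s.n == 15

    def test_two_capsule_mean(self):
        batch = CapsuleBatch(
            (CapsuleMeasurement(4.4, 4.0), CapsuleMeasurement(4.2, 4.2))
        )
        s = batch_summary(batch)
        assert s.mean_sf == pytest.approx(1.0 / 42.0)  # mean of 1/21 and 0
        assert s.mean_d == pytest.approx(4.1)

    def test_singleton_sd_missing(self):
        s = batch_summary(CapsuleBatch((CapsuleMeasurement(4.4, 4.0),)))
        assert s.sd_sf is None and s.sd_d is None and s.n == 1

    def test_monte_carlo_recovery(self):
        # 10⁴ capsules at 2% multiplicative noise: mean d within 3 SE
        true_d, sigma, n = 4.0, 0.02, 10_000
        batch = gen_capsule_batch(true_d, 0.05, n=n, sigma=sigma, rng=11)
        s = batch_summary(batch)
        se = true_d * sigma / math.sqrt(n)
        assert abs(s.mean_d - true_d) < 3 * se


class TestGridAverage:
    def test_measured_sf_column_endpoints(self):
        curve = grid_average(datasets.sphericity_grid(), GridAxis.OVER_CORE_VISCOSITY)
        assert curve.x[0] == 16.2 and curve.x[-1] == 265.5
        assert curve.mean[0] == pytest.approx(0.02925)
        assert curve.mean[-1] == pytest.approx(0.28875)
        assert list(curve.n) == [4, 4, 4, 4, 4]  # the unformed row is skipped

    def test_measured_diameter_column_endpoints(self):
        curve = grid_average(datasets.diameter_grid(), GridAxis.OVER_CORE_VISCOSITY)
        assert curve.mean[0] == pytest.approx(4.41825)
        assert curve.mean[-1] == pytest.approx(3.2125)

    def test_partial_missing_column(self):
        grid = ConditionGrid(
            core_viscosities=np.array([1.0, 2.0, 3.0, 4.0]),
            bath_viscosities=np.array([10.0]),
            values=np.array([[0.1], [np.nan], [0.3], [np.nan]]),
        )
        curve = grid_average(grid, GridAxis.OVER_CORE_VISCOSITY)
        assert curve.mean[0] == pytest.approx(0.2)  # mean over the 2 formed cells
        assert curve.n[0] == 2

    def test_all_missing_column_dropped_with_warning(self, caplog):
        grid = ConditionGrid(
            core_viscosities=np.array([1.0, 2.0]),
            bath_viscosities=np.array([10.0, 20.0]),
            values=np.array([[np.nan, 0.1], [np.nan, 0.2]]),
        )
        with caplog.at_level(logging.WARNING, logger="capsize"):
            curve = grid_average(grid, GridAxis.OVER_CORE_VISCOSITY)
        assert list(curve.x) == [20.0]
        assert any("dropped" in r.message for r in caplog.records)

    def test_single_row_grid_equals_row(self):
        grid = ConditionGrid(
            core_viscosities=np.array([1.0]),
            bath_viscosities=np.array([10.0, 20.0, 30.0]),
            values=np.array([[0.1, 0.2, 0.3]]),
        )
        curve = grid_average(grid, GridAxis.OVER_CORE_VISCOSITY)
        np.testing.assert_allclose(curve.mean, [0.1, 0.2, 0.3])
        assert list(curve.n) == [1, 1, 1]

    def test_transposed_axis(self):
        curve = grid_average(datasets.sphericity_grid(), GridAxis.OVER_BATH_VISCOSITY)
        assert curve.x[0] == 56.7  # the 20.0 mPa·s row never formed capsules
        assert curve.mean[0] == pytest.approx(np.mean([0.067, 0.086, 0.258, 0.394, 0.371]))


class TestThresholdCrossing:
    def test_measured_sf_curve_crossing(self):
        # linear interpolation between (33.6, 0.0295) and (72.0, 0.10975)
        curve = grid_average(datasets.sphericity_grid(), GridAxis.OVER_CORE_VISCOSITY)
        x = threshold_crossing(curve, 0.07)
        expected = 33.6 + (0.07 - 0.0295) / (0.10975 - 0.0295) * (72.0 - 33.6)
        assert x == pytest.approx(expected)
        assert x == pytest.approx(52.9794392523, rel=1e-9)

    def test_never_crossing_returns_none(self):
        curve = AggregateCurve(x=[1.0, 2.0], mean=[0.01, 0.02], sd=[0, 0], n=[1, 1])
        assert threshold_crossing(curve, 0.07) is None

    def test_exact_point_is_the_crossing(self):
        curve = AggregateCurve(x=[1.0, 2.0, 3.0], mean=[0.01, 0.07, 0.2],
                               sd=[0, 0, 0], n=[1, 1, 1])
        assert threshold_crossing(curve, 0.07) == 2.0

    def test_multiple_crossings_first_reported(self, caplog):
        curve = AggregateCurve(
            x=[1.0, 2.0, 3.0, 4.0], mean=[0.01, 0.1, 0.05, 0.2],
            sd=[0] * 4, n=[1] * 4,
        )
        with caplog.at_level(logging.INFO, logger="capsize"):
            x = threshold_crossing(curve, 0.07)
        assert 1.0 < x < 2.0

    def test_short_curve_rejected(self):
        curve = AggregateCurve(x=[1.0], mean=[0.01], sd=[0.0], n=[1])
        with pytest.raises(ValidationError):
            threshold_crossing(curve)


class TestPercentChange:
    @pytest.mark.parametrize(
        "first,last,expected",
        [(4.418, 3.213, 27.3), (2.0, 2.0, 0.0), (2.0, 1.0, 50.0)],
    )
    def test_values(self, first, last, expected):
        assert percent_change(first, last) == pytest.approx(expected, abs=0.05)

    def test_requires_positive_first(self):
        with pytest.raises(ValidationError):
            percent_change(0.0, 1.0)
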