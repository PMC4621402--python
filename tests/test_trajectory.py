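import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from scctraj.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
)
from scctraj.trajectory import (
    MeasurementSeries,
    ShapeLabel,
    classify_shape,
    fit_log_trajectory,
    fluctuation_rmse,
)

series_strategy = hst.lists(
    hst.floats(min_value=12, max_value=60, allow_nan=False), min_size=2, max_size=9
)


def normal_equations_fit(scores):
    """Independent OLS on the (1, ln t) design via explicit 2x2 solve."""
    y = np.asarray(scores, float)
    x = np.log(np.arange(1, len(y) + 1))
    n = len(y)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    det = n * sxx - sx * sx
    a = (sy * sxx - sx * sxy) / det
    b = (n * sxy - sx * sy) / det
    resid = y - (a + b * x)
    return a, b, math.sqrt(float(resid @ resid) / n)


def rule_oracle(scores, rci=3.48):
    """Regex-style reimplementation of the five shape rules."""
    cats = "".join(
        "+" if b - a > rci else ("-" if a - b > rci else "0")
        for a, b in zip(scores, scores[1:])
    )
    if "+" not in cats and "-" not in cats:
        return ShapeLabel.PLATEAU
    if "-" not in cats:
        return ShapeLabel.MONOTONIC_INCREASE
    if "+" not in cats:
        return ShapeLabel.MONOTONIC_DECREASE
    if cats.count("-") == 1 and "-+" in cats:
        return ShapeLabel.V_SHAPE
    return ShapeLabel.DISCONTINUOUS_OTHER


class TestLogTrendFit:
    def test_recovers_exact_log_curve(self):
        scores = [30 + 5 * math.log(t) for t in range(1, 6)]
        fit = fit_log_trajectory(scores)
        assert fit.slope == pytest.approx(5.0)
        assert fit.intercept == pytest.approx(30.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_flat_series_has_zero_slope_and_rmse(self):
        fit = fit_log_trajectory([40, 40, 40, 40])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(40.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        scores = [30, 36, 35, 39]
        fit = fit_log_trajectory(scores)
        a, b, rmse = normal_equations_fit(scores)
        assert fit.intercept == pytest.approx(a, abs=1e-9)
        assert fit.slope == pytest.approx(b, abs=1e-9)
        assert fit.rmse == pytest.approx(rmse, abs=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_log_trajectory([40])

    def test_week_time_axis(self):
        s = MeasurementSeries("s", scores=(30, 35, 37, 38), weeks=(1, 3, 5, 7))
        fit = fit_log_trajectory(s, time_from="week")
        x = np.log([1, 3, 5, 7])
        coef = np.polyfit(x, [30, 35, 37, 38], 1)
        assert fit.slope == pytest.approx(coef[0])
        with pytest.raises(InvalidArgumentError):
            fit_log_trajectory([30, 35], time_from="week")


class TestFluctuationRmse:
    def test_location_invariance(self):
        base = [30.0, 36.0, 35.0, 39.0]
        r0 = fluctuation_rmse(base)
        assert fluctuation_rmse([v + 7.5 for v in base]) == pytest.approx(r0, abs=1e-9)

    def test_equals_population_sd_of_residuals(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            scores = rng.uniform(12, 60, size=rng.integers(3, 10))
            fit = fit_log_trajectory(scores)
            resid = np.asarray(scores) - np.asarray(fit.fitted)
            two_pass = math.sqrt(np.mean((resid - 0.0) ** 2))
            assert fit.rmse == pytest.approx(two_pass, abs=1e-9)


class TestClassifyShape:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([40, 45, 46], ShapeLabel.MONOTONIC_INCREASE),
            ([38, 33, 39], ShapeLabel.V_SHAPE),
            ([35, 36, 34, 37], ShapeLabel.PLATEAU),
            ([40, 35, 41, 36], ShapeLabel.DISCONTINUOUS_OTHER),
            ([46, 41, 40], ShapeLabel.MONOTONIC_DECREASE),
            # drop at the last transition cannot rebound -> not a V
            ([35, 40, 34], ShapeLabel.DISCONTINUOUS_OTHER),
            # a change of exactly the threshold is not reliable
            ([40, 43.48, 43.48], ShapeLabel.PLATEAU),
        ],
    )
    def test_rule_examples(self, scores, expected):
        assert classify_shape(scores) is expected

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            classify_shape([40])
        with pytest.raises(InvalidArgumentError):
            classify_shape([40, 45], rci=0)

    def test_exhaustive_small_window_matches_oracle(self):
        window = range(36, 44)  # 8-point window, k <= 4
        for k in (2, 3, 4):
            for s in itertools.product(window, repeat=k):
                assert classify_shape(s) is rule_oracle(s)

    @settings(derandomize=True, max_examples=300)
    @given(series_strategy)
    def test_total_function_and_oracle_agreement(self, scores):
        label = classify_shape(scores)
        assert isinstance(label, ShapeLabel)
        assert label is rule_oracle(scores)

    @settings(derandomize=True, max_examples=200)
    @given(series_strategy, hst.floats(min_value=-20, max_value=20, allow_nan=False))
    def test_shift_invariance(self, scores, shift):
        assert classify_shape(scores) is classify_shape([v + shift for v in scores])

    @settings(derandomize=True, max_examples=200)
    @given(series_strategy)
    def test_negation_swaps_monotone_labels(self, scores):
        label = classify_shape(scores)
        neg = classify_shape([-v for v in scores])
        swap = {
            ShapeLabel.MONOTONIC_INCREASE: ShapeLabel.MONOTONIC_DECREASE,
            ShapeLabel.MONOTONIC_DECREASE: ShapeLabel.MONOTONIC_INCREASE,
            ShapeLabel.PLATEAU: ShapeLabel.PLATEAU,
        }
        if label in swap:
            assert neg is swap[label]
        else:
            # V and other discontinuous series stay in the two-sided family;
            # the oracle decides which member
            assert neg is rule_oracle([-v for v in scores])


class TestMeasurementSeries:
    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            MeasurementSeries("s", scores=(30, 31), occasions=(1,))
        with pytest.raises(InvalidArgumentError):
            MeasurementSeries("s", scores=(30, 31), occasions=(2, 2))
        with pytest.raises(InvalidArgumentError):
            MeasurementSeries("s", scores=(30, 31), occasions=(0, 1))

    def test_out_of_study_range_warns_not_raises(self):
        with pytest.warns(UserWarning, match="outside the study-like range"):
            MeasurementSeries("s", scores=(30, 31, 32))

    def test_occasion_gap_warns(self):
        with pytest.warns(UserWarning, match="gap"):
            MeasurementSeries("s", scores=(30, 31, 33, 36), occasions=(1, 2, 4, 5))
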