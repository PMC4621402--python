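import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from scctraj.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidCohortError,
    InvalidTableError,
    UndefinedCorrelationError,
)
from scctraj.outcome_stats import (
    FourfoldTable,
    change_score,
    fit_interaction_model,
    g_test_2x2,
    improvement_flag,
    shape_frequency_tests,
    subgroup_correlation,
    two_way_anova,
    variance_components_null,
)


def algebraic_g(a, b, c, d):
    """Independent G computation: 2 n sum p ln(p / (row col))."""
    n = a + b + c + d
    g = 0.0
    for obs, row, col in [
        (a, a + b, a + c), (b, a + b, b + d),
        (c, c + d, a + c), (d, c + d, b + d),
    ]:
        if obs > 0:
            p = obs / n
            g += p * math.log(p / ((row / n) * (col / n)))
    return 2 * n * g


class TestChangeAndImprovement:
    @pytest.mark.parametrize("pre, post, expected", [
        (300, 300, 0), (339, 236, 103), (200, 260, -60),
    ])
    def test_change_sign_convention(self, pre, post, expected):
        assert change_score(pre, post) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            change_score(-5, 100)
        with pytest.raises(InvalidArgumentError):
            change_score(100, 600)

    @pytest.mark.parametrize("change, expected", [
        (57, True), (56.6, False), (-100, False), (56.61, True),
    ])
    def test_improvement_is_strict(self, change, expected):
        assert improvement_flag(change) is expected


class TestGTest:
    def test_whole_sample_v_shape_value(self):
        res = g_test_2x2(FourfoldTable(20, 19, 9, 37))
        assert res.statistic == pytest.approx(9.59, abs=0.01)
        assert res.df == 1

    def test_zero_cell_convention(self):
        res = g_test_2x2(FourfoldTable(0, 39, 15, 31))
        assert res.statistic == pytest.approx(21.13, abs=0.01)

    def test_exact_independence_gives_zero(self):
        res = g_test_2x2(FourfoldTable(10, 10, 10, 10))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_agrees_with_algebraic_form(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            tab = FourfoldTable(int(a), int(b), int(c), int(d))
            if any(m == 0 for m in tab.margins()):
                continue
            assert g_test_2x2(tab).statistic == pytest.approx(
                algebraic_g(a, b, c, d), abs=1e-9)

    def test_invariant_under_transposition_and_swaps(self):
        g0 = g_test_2x2(FourfoldTable(20, 19, 9, 37)).statistic
        assert g_test_2x2(FourfoldTable(20, 9, 19, 37)).statistic == pytest.approx(g0)
        assert g_test_2x2(FourfoldTable(9, 37, 20, 19)).statistic == pytest.approx(g0)
        assert g_test_2x2(FourfoldTable(19, 20, 37, 9)).statistic == pytest.approx(g0)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidTableError):
            g_test_2x2(FourfoldTable(0, 0, 15, 31))
        with pytest.raises(InvalidTableError):
            FourfoldTable(0, 0, 0, 0)


def synthetic_table(n=60, seed=5):
    rng = np.random.default_rng(seed)
    shapes = rng.choice(
        ["monotonic_increase", "v_shape", "discontinuous_other",
         "plateau", "monotonic_decrease"], size=n)
    disps = rng.choice(
        ["integrated_functional", "integrated_dysfunctional",
         "disintegrated_functional", "disintegrated_dysfunctional"], size=n)
    rmse = rng.gamma(4, 0.5, size=n)
    change = rng.normal(40, 80, size=n)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "unit_id": rng.choice(["U1", "U2", "U3"], size=n),
        "group_id": rng.choice([f"G{j}" for j in range(1, 8)], size=n),
        "shape": shapes, "disposition": disps, "rmse": rmse,
        "change": change, "improved": change > 56.6,
    })


class TestShapeFrequencyTests:
    def test_25_strata_shape_combinations(self):
        res = shape_frequency_tests(synthetic_table(200))
        assert len(res) == 25
        strata = {r.stratum for r in res}
        assert strata == {"whole_sample", "integrated_functional",
                          "integrated_dysfunctional", "disintegrated_functional",
                          "disintegrated_dysfunctional"}

    def test_zero_margin_strata_are_skipped_not_fatal(self):
        df = synthetic_table(40)
        df.loc[:, "shape"] = "v_shape"  # all other shapes have empty columns
        res = shape_frequency_tests(df)
        skipped = [r for r in res if r.skipped]
        assert skipped and all(r.result is None for r in skipped)


class TestSubgroupCorrelation:
    def test_hand_computed_three_points(self):
        df = pd.DataFrame({
            "rmse": [1, 2, 3], "change": [2, 1, 3],
            "disposition": ["integrated_functional"] * 3,
        })
        r, n, p = subgroup_correlation(df, "whole")
        # cov = 1/2... direct arithmetic: r = 0.5
        assert r == pytest.approx(0.5)
        assert n == 3

    def test_perfect_linear_pair(self):
        df = pd.DataFrame({
            "rmse": np.arange(10.0), "change": 3 * np.arange(10.0) + 1,
            "disposition": ["integrated_dysfunctional"] * 10,
        })
        r, _, p = subgroup_correlation(df, "other_three")
        assert r == pytest.approx(1.0)

    def test_independent_variables_have_small_r(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "rmse": rng.normal(size=1000), "change": rng.normal(size=1000),
            "disposition": ["integrated_functional"] * 1000,
        })
        r, _, _ = subgroup_correlation(df, "whole")
        assert abs(r) < 0.1

    def test_degenerate_inputs(self):
        df = pd.DataFrame({"rmse": [1.0, 1.0, 1.0], "change": [1, 2, 3],
                           "disposition": ["integrated_functional"] * 3})
        with pytest.raises(UndefinedCorrelationError):
            subgroup_correlation(df, "whole")
        with pytest.raises(InsufficientDataError):
            subgroup_correlation(df.iloc[:2], "whole")


class TestInteractionModel:
    def test_noise_free_slopes_recovered_exactly(self):
        rmse = np.tile(np.linspace(0.5, 4.0, 8), 2)
        pd_fi = np.repeat([1.0, 0.0], 8)
        change = 10 + 30 * rmse - 48 * pd_fi * rmse + 5 * pd_fi
        df = pd.DataFrame({
            "rmse": rmse, "change": change,
            "disposition": np.where(pd_fi == 1, "integrated_functional",
                                    "disintegrated_dysfunctional"),
        })
        fit = fit_interaction_model(df)
        assert fit.params["rmse"] == pytest.approx(30.0)
        assert fit.params["rmse:pd_fi"] == pytest.approx(-48.0)
        assert fit.params["pd_fi"] == pytest.approx(5.0)
        assert fit.total_r2 == pytest.approx(1.0)

    def test_matches_normal_equations_on_hand_dataset(self):
        df = pd.DataFrame({
            "rmse": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            "change": [12.0, 35.0, 41.0, 8.0, 2.0, -5.0],
            "disposition": ["disintegrated_functional"] * 3
                           + ["integrated_functional"] * 3,
        })
        fit = fit_interaction_model(df)
        fi = np.array([0, 0, 0, 1, 1, 1.0])
        X = np.column_stack([np.ones(6), df["rmse"], fi, df["rmse"] * fi])
        beta = np.linalg.solve(X.T @ X, X.T @ df["change"].to_numpy())
        for name, value in zip(["Intercept", "rmse", "pd_fi", "rmse:pd_fi"], beta):
            assert fit.params[name] == pytest.approx(value, abs=1e-9)

    def test_sequential_r2_sums_to_total(self):
        df = synthetic_table(120, seed=9)
        fit = fit_interaction_model(df)
        assert sum(fit.incremental_r2.values()) == pytest.approx(fit.total_r2, abs=1e-9)
        assert 0 <= fit.total_r2 <= 1

    def test_single_stratum_rejected(self):
        df = synthetic_table(50)
        df["disposition"] = "integrated_functional"
        with pytest.raises(InvalidCohortError):
            fit_interaction_model(df)


class TestTwoWayAnova:
    def test_null_design_has_near_zero_eta2(self):
        df = synthetic_table(400, seed=13)  # cell means all equal by construction
        res = two_way_anova(df)
        assert res.table.loc["shape", "partial_eta2"] < 0.05
        assert res.table.loc["shape:pd_fi", "partial_eta2"] < 0.05

    def test_balanced_2x2_matches_hand_sums_of_squares(self):
        # 2 shapes x 2 dispositions, n = 2 per cell
        data = {
            ("v_shape", "integrated_functional"): [10.0, 14.0],
            ("v_shape", "disintegrated_dysfunctional"): [30.0, 34.0],
            ("plateau", "integrated_functional"): [20.0, 16.0],
            ("plateau", "disintegrated_dysfunctional"): [12.0, 8.0],
        }
        rows = []
        for (shape, disp), ys in data.items():
            for y in ys:
                rows.append({"shape": shape, "disposition": disp, "change": y,
                             "rmse": 1.0, "improved": False,
                             "unit_id": "U1", "group_id": "G1"})
        df = pd.DataFrame(rows)
        res = two_way_anova(df)
        y = df["change"].to_numpy()
        cells = np.array([np.mean(v) for v in data.values()]).reshape(2, 2)
        grand = y.mean()
        ss_a = 4 * np.sum((cells.mean(axis=1) - grand) ** 2)   # shape
        ss_b = 4 * np.sum((cells.mean(axis=0) - grand) ** 2)   # pd_fi
        ss_cells = 2 * np.sum((cells - grand) ** 2)
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum((np.array(v) - np.mean(v)) @ (np.array(v) - np.mean(v))
                     for v in data.values())
        assert res.table.loc["shape", "sum_sq"] == pytest.approx(ss_a, abs=1e-8)
        assert res.table.loc["pd_fi", "sum_sq"] == pytest.approx(ss_b, abs=1e-8)
        assert res.table.loc["shape:pd_fi", "sum_sq"] == pytest.approx(ss_ab, abs=1e-8)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(ss_err, abs=1e-8)
        eta = ss_ab / (ss_ab + ss_err)
        assert res.table.loc["shape:pd_fi", "partial_eta2"] == pytest.approx(eta)
        assert set(res.dropped_levels) == {
            "monotonic_increase", "discontinuous_other", "monotonic_decrease"}

    def test_cell_stats_reported(self):
        df = synthetic_table(100, seed=17)
        res = two_way_anova(df)
        assert {"mean", "sd", "n"} <= set(res.cell_stats.columns)
        assert res.cell_stats["n"].sum() == 100


def nested_layout(n, seed=0):
    groups = [f"G{j}" for j in range(1, 8)]
    unit_of = {"G1": "U1", "G2": "U1", "G3": "U1", "G4": "U2",
               "G5": "U2", "G6": "U3", "G7": "U3"}
    g = [groups[i % 7] for i in range(n)]
    return pd.DataFrame({"group_id": g, "unit_id": [unit_of[x] for x in g]})


class TestVarianceComponents:
    def test_constant_outcome_gives_zero_components(self):
        df = nested_layout(30)
        df["change"] = 50.0
        vc = variance_components_null(df)
        assert vc.residual == 0 and vc.var_group == 0 and vc.var_unit == 0

    def test_balanced_two_level_matches_anova_estimators(self):
        # one unit -> unit component dropped; 6 groups x 5 subjects
        rng = np.random.default_rng(21)
        J, m = 6, 5
        eff = rng.normal(0, 4, size=J)
        rows = []
        for j in range(J):
            for _ in range(m):
                rows.append({"group_id": f"G{j}", "unit_id": "U1",
                             "change": 10 + eff[j] + rng.normal(0, 3)})
        df = pd.DataFrame(rows)
        vc = variance_components_null(df, reml=True)
        y = df["change"].to_numpy().reshape(J, m)
        msw = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2) / (J * (m - 1))
        msb = m * np.sum((y.mean(axis=1) - y.mean()) ** 2) / (J - 1)
        assert vc.var_unit == 0.0
        assert "var_unit: single level, component fixed at 0" in vc.notes
        assert vc.residual == pytest.approx(msw, abs=1e-6)
        assert vc.var_group == pytest.approx((msb - msw) / m, abs=1e-6)

    def test_residual_only_structure_recovered(self):
        rng = np.random.default_rng(33)
        resids, others = [], []
        for _ in range(10):
            df = nested_layout(85)
            df["change"] = rng.normal(0, np.sqrt(7000), size=85)
            vc = variance_components_null(df)
            resids.append(vc.residual)
            others.append(vc.var_group + vc.var_unit)
        assert abs(np.mean(resids) - 7000) / 7000 < 0.25
        assert np.mean(others) < 0.15 * np.mean(resids)

    def test_wald_statistics_present_and_sane(self, cohort_table):
        vc = variance_components_null(cohort_table)
        w = vc.wald["residual"]
        assert w.estimate == pytest.approx(vc.residual)
        assert w.se > 0 and w.z > 0 and 0 <= w.p <= 1
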