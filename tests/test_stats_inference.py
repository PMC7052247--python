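"""Regression and test battery against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from ccvmotor.stats_inference import (
    CCVAggregate,
    aggregate_by_ccv,
    one_way_anova,
    ols_regression,
    two_sample_ttest,
    wls_regression,
)


def make_aggregates(x, y, sems):
    return [
        CCVAggregate(
            ccv=f"c{i}", n=10,
            means={"y": float(yi), "x": float(xi)},
            sems={"y": float(si), "x": 0.1},
        )
        for i, (xi, yi, si) in enumerate(zip(x, y, sems))
    ]


class TestOLS:
    def test_exact_line_recovered_with_zero_residual(self):
        x = np.arange(10.0)
        res = ols_regression(2 * x, {"x": x})
        assert res.term("x").estimate == pytest.approx(2.0)
        assert res.term("x").p < 1e-10

    def test_orthogonal_predictor_has_near_zero_t(self, rng):
        x = np.tile([-1.0, 1.0], 50)
        y = rng.standard_normal(100)
        y -= x * (x @ y) / (x @ x)  # project out any accidental overlap
        res = ols_regression(y, {"x": x})
        assert abs(res.term("x").statistic) < 1e-8

    def test_matches_normal_equation_oracle(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.standard_normal(40)
        res = ols_regression(y, {"a": X[:, 0], "b": X[:, 1]})
        Xc = np.column_stack([np.ones(40), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        assert res.term("a").estimate == pytest.approx(beta[1], abs=1e-10)
        assert res.term("b").estimate == pytest.approx(beta[2], abs=1e-10)
        assert res.term("a").df == 40 - 2 - 1

    def test_singular_design_rejected(self):
        x = np.ones(10)
        with pytest.raises(ValueError):
            ols_regression(np.arange(10.0), {"x": x})


class TestWLS:
    def test_equal_weights_reduce_to_ols(self, rng):
        x = rng.standard_normal(15)
        y = 1.0 + 0.5 * x + rng.standard_normal(15)
        aggs = make_aggregates(x, y, np.full(15, 2.0))
        wls = wls_regression(aggs, "y", "x")
        ols = ols_regression(y, {"x": x})
        assert wls.term("x").estimate == pytest.approx(ols.term("x").estimate, abs=1e-12)
        assert wls.term("x").statistic == pytest.approx(ols.term("x").statistic, abs=1e-10)

    def test_infinite_sem_point_has_no_influence(self, rng):
        x = np.arange(10.0)
        y = 3.0 + 2.0 * x
        sems = np.ones(10)
        aggs = make_aggregates(x, y, sems)
        x2 = np.append(x, 5.0)
        y2 = np.append(y, 1000.0)
        sems2 = np.append(sems, 1e9)
        aggs2 = make_aggregates(x2, y2, sems2)
        a = wls_regression(aggs, "y", "x").term("x").estimate
        b = wls_regression(aggs2, "y", "x").term("x").estimate
        assert a == pytest.approx(b, rel=1e-9)

    def test_fifteen_aggregates_give_thirteen_df(self, rng):
        x = rng.standard_normal(15)
        aggs = make_aggregates(x, x, np.ones(15))
        assert wls_regression(aggs, "y", "x").term("x").df == 13

    def test_planted_slope_recovered_within_two_se(self):
        """Coverage: the 2-SE interval captures the true slope in at
        least 93 of 100 simulated aggregate sets."""
        rng = np.random.default_rng(2024)
        hits = 0
        x = np.linspace(0, 1, 15)
        sems = np.full(15, 0.2)
        for _ in range(100):
            y = 1.0 + 0.5 * x + rng.normal(0, sems)
            res = wls_regression(make_aggregates(x, y, sems), "y", "x")
            t = res.term("x")
            hits += abs(t.estimate - 0.5) <= 2 * t.se
        assert hits >= 93

    def test_zero_sem_rejected(self):
        aggs = make_aggregates([0, 1, 2], [0, 1, 2], [1.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            wls_regression(aggs, "y", "x")


class TestPooledTTest:
    def test_identical_samples_are_null(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        t = res.terms[0]
        assert t.statistic == 0.0 and t.p == 1.0

    def test_hand_computed_example(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        t = res.terms[0]
        assert t.statistic == pytest.approx(-1.224744871, abs=1e-8)
        assert t.df == 4

    def test_matches_textbook_formula_on_random_pairs(self, rng):
        from scipy import stats as sps

        for _ in range(100):
            a = rng.standard_normal(rng.integers(3, 20))
            b = rng.standard_normal(rng.integers(3, 20)) + rng.normal()
            res = two_sample_ttest(a, b).terms[0]
            sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
                a.size + b.size - 2
            )
            t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
            p_oracle = 2 * sps.t.sf(abs(t_oracle), a.size + b.size - 2)
            assert res.statistic == pytest.approx(t_oracle, abs=1e-10)
            assert res.p == pytest.approx(p_oracle, abs=1e-10)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ZeroDivisionError):
            two_sample_ttest([1.0, 1.0], [2.0, 2.0])


class TestANOVA:
    def test_equal_group_means_give_near_zero_f(self):
        g = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 1.0, 3.0])]
        res = one_way_anova(g)
        assert res.terms[0].statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(15) + 0.5
        f = one_way_anova([a, b]).terms[0].statistic
        t = two_sample_ttest(a, b).terms[0].statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_matches_sum_of_squares_oracle(self, rng):
        groups = [rng.standard_normal(n) + m for n, m in ((8, 0.0), (10, 0.3), (9, -0.2))]
        res = one_way_anova(groups).terms[0]
        grand = np.concatenate(groups).mean()
        ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = 3, sum(g.size for g in groups)
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
        assert res.df == n - k

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], [3.0]])


class TestAggregation:
    def test_two_trials_mean_and_sem(self):
        df = pd.DataFrame({"ccv": "bda", "ffd": [10.0, 20.0]})
        (agg,) = aggregate_by_ccv(df, ["ffd"])
        assert agg.means["ffd"] == 15.0
        assert agg.sems["ffd"] == pytest.approx(5.0)

    def test_fifteen_ccvs_in_fifteen_aggregates_out(self, rng):
        from ccvmotor.effort import analysis_ccvs

        labels = [c.label for c in analysis_ccvs()]
        df = pd.DataFrame(
            {"ccv": np.repeat(labels, 4), "ffd": rng.normal(200, 20, 60)}
        )
        assert len(aggregate_by_ccv(df, ["ffd"])) == 15

    def test_matches_two_pass_oracle(self, rng):
        vals = rng.normal(100, 15, 30)
        df = pd.DataFrame({"ccv": "gta", "tau_norm": vals})
        (agg,) = aggregate_by_ccv(df, ["tau_norm"])
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        assert agg.means["tau_norm"] == pytest.approx(mean)
        assert agg.sems["tau_norm"] == pytest.approx(np.sqrt(var / len(vals)))

    def test_undersized_ccv_dropped_with_warning(self):
        df = pd.DataFrame({"ccv": ["bda", "bda", "gta"], "ffd": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            aggs = aggregate_by_ccv(df, ["ffd"])
        assert [a.ccv for a in aggs] == ["bda"]
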