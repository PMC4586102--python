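import numpy as np
import pandas as pd
import pytest

from semscan import (
    PathModel,
    ValidationError,
    correlation_ratio,
    impute_missing,
    rubin_pool,
    standardized_regression,
    z_transform,
)
from semscan.association import age_range_labels


class TestZTransform:
    def test_simple_triplet(self):
        assert np.allclose(z_transform([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = z_transform(rng.normal(5, 3, 100))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=50)
        assert np.allclose(z_transform(v), z_transform(3.2 * v - 7))

    def test_constant_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            z_transform([2, 2, 2])


class TestCorrelationRatio:
    def test_all_between_group_variance(self):
        assert correlation_ratio([("A", [1, 1]), ("B", [3, 3])]) == pytest.approx(1.0)

    def test_equal_means_give_zero(self):
        assert correlation_ratio([("A", [0, 2]), ("B", [1, 1])]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # SS_between = 1, SS_total = 5
        eta = correlation_ratio([("A", [0, 2]), ("B", [1, 3])])
        assert eta == pytest.approx(np.sqrt(1 / 5))

    def test_equals_abs_pearson_on_group_mean_encoding(self):
        rng = np.random.default_rng(2)
        groups = [(g, rng.normal(loc=m, size=20)) for g, m in
                  [("a", 0.0), ("b", 1.0), ("c", 3.0)]]
        eta = correlation_ratio(groups)
        x, y = [], []
        for _, v in groups:
            x.extend([v.mean()] * len(v))
            y.extend(v)
        r = abs(np.corrcoef(x, y)[0, 1])
        assert eta == pytest.approx(r, abs=1e-12)

    def test_identical_values_rejected(self):
        with pytest.raises(ValidationError):
            correlation_ratio([("A", [1, 1]), ("B", [1, 1])])


class TestStandardizedRegression:
    def test_perfect_fit(self):
        t = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [2.0, 4, 6, 8]})
        res = standardized_regression("y", ["x"], t)
        assert res.iloc[0]["beta_std"] == pytest.approx(1.0)
        assert res.iloc[0]["p"] < 1e-10

    def test_orthogonal_predictors_equal_marginal_correlations(self):
        rng = np.random.default_rng(3)
        n = 400
        x1 = z_transform(rng.normal(size=n))
        x2 = z_transform(rng.normal(size=n))
        # orthogonalise x2 against x1 exactly
        x2 = z_transform(x2 - x1 * (x1 @ x2) / (x1 @ x1))
        y = 0.5 * x1 - 0.3 * x2 + rng.normal(0, 0.3, n)
        t = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        res = standardized_regression("y", ["x1", "x2"], t).set_index("term")
        zy = z_transform(y)
        r1 = (zy @ z_transform(x1)) / (n - 1)
        r2 = (zy @ z_transform(x2)) / (n - 1)
        assert res.at["x1", "beta_std"] == pytest.approx(r1, abs=1e-9)
        assert res.at["x2", "beta_std"] == pytest.approx(r2, abs=1e-9)

    def test_null_coefficient_within_sampling_error(self):
        rng = np.random.default_rng(4)
        n = 10_000
        t = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
        res = standardized_regression("y", ["x"], t).iloc[0]
        se = (res["ci_high"] - res["ci_low"]) / (2 * 1.96)
        assert abs(res["beta_std"]) < 3 * se

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        t = pd.DataFrame({"y": rng.normal(size=50), "a": x, "b": 2 * x})
        with pytest.raises(ValidationError, match="collinear"):
            standardized_regression("y", ["a", "b"], t)

    def test_complete_case_handling(self):
        t = pd.DataFrame({
            "y": [1.0, 2, 3, 4, 5, np.nan],
            "x": [1.0, 2, 3, 4, 5, 6],
        })
        res = standardized_regression("y", ["x"], t)
        assert res.iloc[0]["n"] == 5


class TestPathModel:
    def test_single_edge_equals_plain_regression(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame({"x": rng.normal(size=80)})
        t["y"] = 0.6 * t["x"] + rng.normal(0, 0.5, 80)
        edge = PathModel(t, [("x", "y")]).fit().edge("x", "y")
        reg = standardized_regression("y", ["x"], t).iloc[0]
        assert edge["beta_std"] == pytest.approx(reg["beta_std"])
        assert edge["p"] == pytest.approx(reg["p"])

    def test_perfect_mediation_deterministic(self):
        # y equals the mediator exactly; a sliver of noise on m keeps the
        # two-predictor design numerically identified
        x = np.arange(40, dtype=float)
        m = x + 0.1 * np.random.default_rng(7).normal(size=40)
        y = m.copy()
        t = pd.DataFrame({"x": x, "m": m, "y": y})
        res = PathModel(t, [("x", "m"), ("x", "y"), ("m", "y")]).fit()
        assert res.edge("m", "y")["beta_std"] == pytest.approx(1.0, abs=1e-6)
        assert res.edge("x", "y")["beta_std"] == pytest.approx(0.0, abs=1e-6)

    def test_full_mediation_recovery(self):
        # y depends on x only through m; the marginal x~y association is
        # strong, the conditional one is null
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        m = 0.8 * x + rng.normal(0, 0.6, n)
        y = 0.7 * m + rng.normal(0, 0.7, n)
        t = pd.DataFrame({"x": x, "m": m, "y": y})
        res = PathModel(t, [("x", "m"), ("x", "y"), ("m", "y")]).fit()
        assert res.edge("x", "m")["significant"]
        assert res.edge("m", "y")["significant"]
        direct = res.edge("x", "y")
        se = (direct["ci_high"] - direct["ci_low"]) / (2 * 1.959964)
        assert abs(direct["beta_std"]) < 3 * se
        marginal = standardized_regression("y", ["x"], t).iloc[0]
        assert marginal["p"] < 0.05 and marginal["beta_std"] > 0.3

    def test_independent_variables_nominal_type_one_error(self):
        rng = np.random.default_rng(9)
        hits = 0
        reps = 200
        for _ in range(reps):
            t = pd.DataFrame(rng.normal(size=(60, 2)), columns=["x", "y"])
            hits += PathModel(t, [("x", "y")]).fit().edge("x", "y")["significant"]
        # binomial(200, 0.05): mean 10, 3 SD ~ 9.2
        assert abs(hits - 10) <= 10

    def test_cyclic_specification_rejected(self):
        t = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
        with pytest.raises(ValidationError, match="cyclic"):
            PathModel(t, [("x", "y"), ("y", "x")])

    def test_summary_lists_every_edge(self):
        rng = np.random.default_rng(10)
        t = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        res = PathModel(t, [("a", "b"), ("a", "c"), ("b", "c")]).fit()
        text = res.summary()
        assert "a" in text and "->" in text
        assert len(res.edges) == 3


class TestImputation:
    def _table(self, n=200, missing=True, seed=11):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        t = pd.DataFrame({
            "x": x,
            "y": 0.5 * x + rng.normal(0, 1, n),
            "z": rng.normal(size=n),
        })
        if missing:
            t.loc[rng.random(n) < 0.2, "z"] = np.nan
        return t

    def test_no_missing_gives_identical_copies(self):
        t = self._table(missing=False)
        out = impute_missing(t, m=3, seed=0)
        assert len(out) == 3
        for o in out:
            pd.testing.assert_frame_equal(o, t)

    def test_deterministic_given_seed(self):
        t = self._table()
        a = impute_missing(t, m=2, seed=42)
        b = impute_missing(t, m=2, seed=42)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_different_imputations_differ(self):
        t = self._table()
        a, b = impute_missing(t, m=2, seed=1)
        assert not a["z"].equals(b["z"])

    def test_entirely_missing_variable_rejected(self):
        t = self._table()
        t["w"] = np.nan
        with pytest.raises(ValidationError, match="w"):
            impute_missing(t, m=2, seed=0)

    def test_pooled_slope_recovers_truth_under_mcar(self):
        # planted slope on a variable missing completely at random at 20%
        rng = np.random.default_rng(12)
        n = 500
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(0, 1, n)
        t = pd.DataFrame({"x": x, "y": y})
        t.loc[rng.random(n) < 0.2, "y"] = np.nan
        ests = []
        for imp in impute_missing(t, m=5, seed=13):
            res = standardized_regression("y", ["x"], imp).iloc[0]
            se = (res["ci_high"] - res["ci_low"]) / (2 * 1.959964)
            ests.append((res["beta_std"], se**2))
        pooled = rubin_pool(ests)
        truth_std = 0.6 / np.sqrt(0.6**2 + 1.0)
        assert abs(pooled.q_bar - truth_std) < 2 * pooled.se


class TestRubinPool:
    def test_identical_estimates(self):
        p = rubin_pool([(2.0, 0.5)] * 5)
        assert p.q_bar == 2.0 and p.B == 0.0 and p.T == pytest.approx(0.5)

    def test_hand_computed_example(self):
        p = rubin_pool([(1, 1), (2, 1), (3, 1)])
        assert p.q_bar == 2.0
        assert p.W == 1.0 and p.B == 1.0
        assert p.T == pytest.approx(7 / 3)

    def test_scale_equivariance(self):
        base = rubin_pool([(1, 1), (2, 1), (3, 1)])
        scaled = rubin_pool([(5, 1), (10, 1), (15, 1)])
        assert scaled.q_bar == pytest.approx(5 * base.q_bar)
        assert scaled.B == pytest.approx(25 * base.B)
        assert scaled.T - scaled.W == pytest.approx(25 * (base.T - base.W))

    def test_single_imputation_rejected(self):
        with pytest.raises(ValidationError):
            rubin_pool([(1, 1)])


class TestAgeRanges:
    def test_stratum_assignment(self):
        labels = age_range_labels([3, 19.9, 20, 45, 79.9, 80, 106])
        assert list(labels.astype(str)) == [
            "0-19", "0-19", "20-39", "40-59", "60-79", "80-106", "80-106",
        ]
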