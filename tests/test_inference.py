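import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from foxrange.errors import (
    DomainError,
    InfiniteLikelihoodError,
    RankDeficiencyError,
    UndefinedStatisticError,
)
from foxrange.inference import (
    aicc,
    build_analysis_table,
    collinearity_screen,
    enumerate_candidates,
    fit_null,
    fit_ols,
    paired_t,
    rank_models,
    summarize_cohort,
)


class TestPairedT:
    def test_reported_field_statistic_reproduced(self):
        """A paired design engineered to give t = 3.13 at df = 51 must yield
        the two-sided p = 0.003 reported for the MCP vs LoCoH comparison."""
        n = 52
        e = np.arange(n) - np.arange(n).mean()
        e = e / e.std(ddof=1)  # mean 0, sd 1
        m = 3.13 / math.sqrt(n)  # t = m / (sd/sqrt(n)) with sd = 1
        res = paired_t(m + e, np.zeros(n))
        assert res.t == pytest.approx(3.13)
        assert res.df == 51
        assert round(res.p, 3) == 0.003

    def test_antisymmetric_differences(self):
        res = paired_t(np.array([1.0, -1.0]), np.zeros(2))
        assert res.t == 0.0 and res.p == 1.0

    def test_simple_arithmetic(self):
        res = paired_t(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert res.t == pytest.approx(2.0 / (1.0 / math.sqrt(3)))
        assert res.df == 2

    def test_shift_invariance(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        r1 = paired_t(a, b)
        r2 = paired_t(a + 17.3, b + 17.3)
        assert r1.t == pytest.approx(r2.t) and r1.p == pytest.approx(r2.p)

    def test_scipy_oracle(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.4, 1, 25)
        mine = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            paired_t(np.array([1.0, 1.0]), np.array([0.0, 0.0]))


class TestFitOls:
    def test_hand_computed_example(self):
        df = pd.DataFrame({"log_area": [0.0, 1.0, 1.0], "x": [0.0, 1.0, 2.0]})
        fit = fit_ols(df, ("x",))
        assert fit.beta[0] == pytest.approx(1.0 / 6.0)
        assert fit.beta[1] == pytest.approx(0.5)
        assert fit.r2 == pytest.approx(0.75)
        assert fit.K == 3

    def test_exact_fit_raises_infinite_likelihood(self):
        df = pd.DataFrame({"log_area": [0.0, 2.0, 4.0, 6.0], "x": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(InfiniteLikelihoodError):
            fit_ols(df, ("x",))

    def test_statsmodels_oracle(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "x1": rng.normal(0, 1, n),
                "x2": rng.normal(0, 2, n),
                "x3": rng.integers(0, 2, n).astype(float),
            }
        )
        df["log_area"] = 1.0 + 0.5 * df.x1 - 0.8 * df.x2 + rng.normal(0, 0.7, n)
        fit = fit_ols(df, ("x1", "x2", "x3"))
        ref = sm.OLS(df["log_area"], sm.add_constant(df[["x1", "x2", "x3"]])).fit()
        assert np.allclose(fit.beta, ref.params.to_numpy(), rtol=1e-8)
        assert np.allclose(fit.se, ref.bse.to_numpy(), rtol=1e-8)
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-10)
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-10)

    def test_aliased_term_named(self, rng):
        n = 30
        df = pd.DataFrame({"a": rng.normal(0, 1, n)})
        df["b"] = 2.0 * df["a"]
        df["log_area"] = df["a"] + rng.normal(0, 1, n)
        with pytest.raises(RankDeficiencyError, match="b"):
            fit_ols(df, ("a", "b"))


class TestAicc:
    def test_reference_selection_table_rows(self):
        """The emulated study's reference (logLik, df) pairs at n = 52
        reproduce its reported AICc for the top two models to within
        rounding of the inputs."""
        best = aicc(-52.28, 5, 52)
        second = aicc(-53.67, 4, 52)
        assert best == pytest.approx(115.87, abs=0.01)
        assert second == pytest.approx(116.20, abs=0.01)
        assert round(second - best, 1) == 0.3

    def test_small_numbers(self):
        assert aicc(0.0, 1, 3) == pytest.approx(6.0)

    def test_domain(self):
        with pytest.raises(DomainError):
            aicc(-10.0, 5, 6)

    def test_approaches_aic_from_above(self):
        K, ll = 4, -50.0
        aic = -2 * ll + 2 * K
        vals = [aicc(ll, K, n) for n in (10, 50, 500, 5000)]
        assert all(v > aic for v in vals)
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] == pytest.approx(aic, abs=0.01)


class TestEnumerateCandidates:
    @pytest.mark.parametrize("p,count", [(5, 31), (1, 1), (2, 3)])
    def test_subset_count(self, p, count):
        covs = tuple(f"c{i}" for i in range(p))
        assert len(enumerate_candidates(covs)) == count

    def test_two_covariate_subsets(self):
        assert enumerate_candidates(("A", "B")) == [("A",), ("B",), ("A", "B")]

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            enumerate_candidates(())


class TestRankModels:
    def _fits(self, rng, n=40):
        df = pd.DataFrame({"x": rng.normal(0, 1, n), "z": rng.normal(0, 1, n)})
        df["log_area"] = 0.7 * df.x + rng.normal(0, 1, n)
        return [fit_ols(df, t) for t in enumerate_candidates(("x", "z"))] + [fit_null(df)]

    def test_weights_sum_to_one_and_best_delta_zero(self, rng):
        table = rank_models(self._fits(rng))
        assert table["weight"].sum() == pytest.approx(1.0)
        assert table["delta"].iloc[0] == 0.0
        assert table["delta"].is_monotonic_increasing

    def test_equal_models_share_weight(self, rng):
        fits = self._fits(rng)[:1] * 2
        table = rank_models(fits)
        assert np.allclose(table["weight"], 0.5)
        assert table["equivalent"].all()

    def test_two_unit_delta_weights(self):
        # closed form: weights (1, e^-1) normalised -> (0.731, 0.269)
        rel = np.exp([-0.0, -1.0])
        w = rel / rel.sum()
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        df = pd.DataFrame({"log_area": [0.0, 1.0, 0.5, 2.0, 1.1], "x": [0, 1, 0, 1, 1.0]})
        f = fit_ols(df, ("x",))
        f2 = fit_null(df)
        table = rank_models([f, f2])
        assert table["weight"].sum() == pytest.approx(1.0)


class TestCollinearityScreen:
    def test_duplicated_covariate_resolved(self, rng):
        n = 50
        df = pd.DataFrame({"a": rng.normal(0, 1, n)})
        df["b"] = df["a"] * 1.0
        df["c"] = rng.normal(0, 1, n)
        df["log_area"] = df["a"] + rng.normal(0, 1, n)
        res = collinearity_screen(df, ("a", "b", "c"))
        assert ("a" in res.retained) ^ ("b" in res.retained)
        assert "c" in res.retained

    def test_orthogonal_covariates_all_kept(self, rng):
        n = 200
        df = pd.DataFrame({f"c{i}": rng.normal(0, 1, n) for i in range(4)})
        df["log_area"] = df["c0"] + rng.normal(0, 1, n)
        res = collinearity_screen(df, ("c0", "c1", "c2", "c3"))
        assert res.retained == ["c0", "c1", "c2", "c3"]

    def test_constant_covariate_warned_and_dropped(self, rng):
        n = 40
        df = pd.DataFrame({"a": rng.normal(0, 1, n), "k": np.ones(n)})
        df["log_area"] = df["a"] + rng.normal(0, 1, n)
        with pytest.warns(UserWarning, match="constant"):
            res = collinearity_screen(df, ("a", "k"))
        assert res.retained == ["a"]


class TestSummaries:
    def test_three_fox_arithmetic(self):
        areas = pd.DataFrame(
            {
                "animal_id": ["a", "b", "c"],
                "estimator": ["MCP"] * 3,
                "level": [1.0] * 3,
                "area_km2": [2.0, 4.0, 6.0],
                "sex": ["F", "F", "F"],
            }
        )
        t = summarize_cohort(areas)["by_estimator_level"]
        row = t[t["group"] == "all"].iloc[0]
        assert row["mean"] == pytest.approx(4.0)
        assert row["se"] == pytest.approx(2.0 / math.sqrt(3))

    def test_single_fox_has_blank_se(self):
        areas = pd.DataFrame(
            {
                "animal_id": ["a"],
                "estimator": ["MCP"],
                "level": [1.0],
                "area_km2": [2.0],
                "sex": ["M"],
            }
        )
        t = summarize_cohort(areas)["by_estimator_level"]
        assert np.isnan(t[t["group"] == "all"].iloc[0]["se"])

    def test_nonpositive_area_rejected(self):
        areas = pd.Series([1.0, 0.0], index=["a", "b"])
        comp = pd.DataFrame(
            {
                "animal_id": ["a", "b"],
                "prop_agriculture": [0.1, 0.1],
                "prop_settlement": [0.0, 0.0],
                "mean_elevation_m": [50.0, 60.0],
                "centroid_latitude": [59.0, 59.1],
                "zone": ["BN", "BN"],
            }
        )
        attrs = pd.DataFrame(
            {"animal_id": ["a", "b"], "sex": ["F", "M"], "age_class": ["adult", "adult"]}
        )
        with pytest.raises(DomainError):
            build_analysis_table(areas, comp, attrs)
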