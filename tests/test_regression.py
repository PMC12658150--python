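import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tssmut import regression as rg

POS4 = ["downstream_TSS", "downstream_far", "upstream_TSS", "upstream_far"]


def sim_design(n=4000, seed=0):
    rng = np.random.default_rng(seed)
    feat = pd.DataFrame({"x1": rng.normal(size=n)})
    pos = pd.Series(rng.choice(POS4, size=n))
    return feat, pos, rng


class TestBuildDesign:
    def test_column_count_with_interactions(self):
        """1 numeric feature, 4 sum-coded position categories (3 columns),
        interactions: p = 1 + 1 + 3 + 3 = 8."""
        feat, pos, _ = sim_design()
        spec, X, idx = rg.build_design(feat, pos, interactions=True)
        assert X.shape[1] == 8
        assert spec.columns[0] == "intercept"

    def test_standardized_columns(self):
        feat, pos, _ = sim_design()
        feat["x1"] = feat["x1"] * 7 + 3
        spec, X, idx = rg.build_design(feat, pos)
        assert X["x1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert X["x1"].std(ddof=0) == pytest.approx(1.0)

    def test_no_interaction_integer_bin_design(self):
        """The genome-wide design: no interactions, integer bin distance as
        a plain numeric predictor -> 1 + m + 1 columns."""
        feat, pos, rng = sim_design()
        feat["bin"] = rng.integers(1, 51, size=len(feat)).astype(float)
        spec, X, idx = rg.build_design(feat, position=None, interactions=False)
        assert X.shape[1] == 1 + 2

    def test_missing_rows_dropped_before_standardizing(self):
        feat, pos, _ = sim_design(n=100)
        feat.loc[feat.index[:10], "x1"] = np.nan
        spec, X, idx = rg.build_design(feat, pos)
        assert len(X) == 90
        assert X["x1"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_single_label_categorical_dropped(self):
        feat, pos, _ = sim_design(n=50)
        feat["flag"] = "yes"
        with pytest.warns(UserWarning, match="flag"):
            spec, X, idx = rg.build_design(feat, pos)
        assert "flag" not in spec.feature_cols

    def test_sum_coding_minus_sum_identity(self):
        """The omitted category's interaction vector is minus the sum of
        the included categories' vectors (coding algebra, exact)."""
        feat, pos, _ = sim_design()
        spec, X, idx = rg.build_design(feat, pos, interactions=True)
        omitted = spec.omitted_category
        v = spec.interaction_vector("x1", omitted)
        total = sum(spec.interaction_vector("x1", c)
                    for c in spec.position_categories[:-1])
        assert np.allclose(v.to_numpy(), -total.to_numpy())


class TestFit:
    def test_intercept_only_closed_form(self, rng):
        n = 500
        y = rng.poisson(3.0, n)
        u = rng.uniform(0.5, 2.0, n)
        X = pd.DataFrame({"intercept": np.ones(n)})
        fit = rg.fit_count_model(X, y, np.log(u), family="poisson")
        assert np.exp(fit.params["intercept"]) == pytest.approx(y.sum() / u.sum())

    def test_poisson_recovery_within_3se(self):
        """Simulated Poisson with known coefficients: estimates within 3 SE
        componentwise in >= 95/100-like fashion (checked over 10 seeds)."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 5000
            feat = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
            spec, X, idx = rg.build_design(feat, position=None, interactions=False)
            beta = pd.Series({"intercept": 0.2, "x1": 0.3, "x2": -0.2})
            mu = np.exp(X.to_numpy() @ beta[spec.columns].to_numpy())
            y = rng.poisson(mu)
            fit = rg.fit_count_model(X, y, np.zeros(n), family="poisson")
            se = np.sqrt(np.diag(fit.cov))
            ok = np.abs(fit.params.to_numpy() - beta[spec.columns].to_numpy()) < 3 * se
            hits += ok.all()
        assert hits >= 9

    def test_nb_on_poisson_data_reports_equidispersion(self, rng):
        """NB fit on Poisson data: tiny dispersion, variance ratio ~1."""
        n = 8000
        X = pd.DataFrame({"intercept": np.ones(n)})
        y = rng.poisson(5.0, n)
        fit = rg.fit_count_model(X, y, np.zeros(n), family="nb")
        var_ratio = 1 + fit.alpha * fit.mu.mean()
        assert abs(var_ratio - 1) < 0.05

    def test_nonfinite_offset_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(4)})
        with np.errstate(divide="ignore"):
            offset = np.log([1.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            rg.fit_count_model(X, [1, 2, 1, 2], offset)


class TestDispersion:
    def test_poisson_fit_on_poisson_data(self, rng):
        n = 10_000
        X = pd.DataFrame({"intercept": np.ones(n)})
        y = rng.poisson(4.0, n)
        fit = rg.fit_count_model(X, y, np.zeros(n), family="poisson")
        stat, flag = rg.dispersion_diagnostic(fit)
        assert abs(stat - 1.0) < 0.1 and flag == "ok"

    def test_poisson_fit_on_nb_data_overdispersed(self, rng):
        n = 5000
        X = pd.DataFrame({"intercept": np.ones(n)})
        mu = 4.0
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu), n)  # alpha = 1
        fit = rg.fit_count_model(X, y, np.zeros(n), family="poisson")
        stat, flag = rg.dispersion_diagnostic(fit)
        assert stat > 1.5 and flag == "overdispersed"

    def test_saturated_zero_residuals(self):
        fit = rg.FitResult(pd.Series({"intercept": 0.0}),
                           pd.DataFrame([[1.0]], index=["intercept"], columns=["intercept"]),
                           "poisson", None, np.array([2.0, 3.0]),
                           np.array([2.0, 3.0]), 1, True)
        stat, _ = rg.dispersion_diagnostic(fit)
        assert stat == 0.0


class TestGVIF:
    def test_duplicate_removed_first_iteration(self, rng):
        x = rng.normal(size=300)
        feat = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=300)})
        kept, log = rg.gvif_filter(feat, threshold=5)
        assert set(kept) == {"b", "c"}
        assert log[log["removed"]]["feature"].iloc[0] == "a"

    def test_orthogonal_features_retained(self, rng):
        feat = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        kept, _ = rg.gvif_filter(feat, threshold=5)
        assert set(kept) == set("abcd")

    def test_infinite_threshold_identity(self, rng):
        x = rng.normal(size=200)
        feat = pd.DataFrame({"a": x, "b": x + rng.normal(size=200) * 0.01})
        kept, _ = rg.gvif_filter(feat, threshold=np.inf)
        assert set(kept) == {"a", "b"}

    def test_refit_after_exact_collinearity_preserves_coefficients(self, rng):
        """Dropping an exactly collinear duplicate leaves the retained
        coefficients unchanged (both solve the same reduced problem)."""
        n = 3000
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = rng.poisson(np.exp(0.1 + 0.3 * x))
        full = pd.DataFrame({"a": x, "b": x.copy(), "c": z})
        kept, _ = rg.gvif_filter(full, threshold=5)
        feat = full[kept]
        spec, X, idx = rg.build_design(feat, position=None)
        fit = rg.fit_count_model(X, y, np.zeros(n), family="poisson")
        spec2, X2, _ = rg.build_design(pd.DataFrame({"b": x, "c": z}), position=None)
        fit2 = rg.fit_count_model(X2, y, np.zeros(n), family="poisson")
        assert np.allclose(fit.params["b"], fit2.params["b"], atol=1e-6)


class TestContrasts:
    def fit_null(self, seed=0, n=2000):
        rng = np.random.default_rng(seed)
        feat = pd.DataFrame({"x1": rng.normal(size=n)})
        pos = pd.Series(rng.choice(POS4, size=n))
        spec, X, idx = rg.build_design(feat, pos, interactions=True)
        y = rng.poisson(2.0, n)
        fit = rg.fit_count_model(X, y, np.zeros(n), family="poisson")
        return spec, fit

    def test_single_contrast_equals_unadjusted(self):
        spec, fit = self.fit_null()
        C = pd.DataFrame([{"x1": 1.0}]).fillna(0.0)
        C.index = ["c1"]
        res = rg.contrast_tests(fit, C, adjust="single_step_maxz")
        assert res["p_adj"].iloc[0] == pytest.approx(res["p"].iloc[0], abs=1e-12)

    def test_identical_contrasts_no_penalty(self):
        spec, fit = self.fit_null()
        C = pd.DataFrame([{"x1": 1.0}, {"x1": 1.0}], index=["a", "b"]).fillna(0.0)
        res = rg.contrast_tests(fit, C, adjust="single_step_maxz", draws=200_000)
        assert res["p_adj"].iloc[0] == pytest.approx(res["p"].iloc[0], rel=0.02)

    def test_independent_contrasts_sidak(self):
        """m independent contrasts: adjusted p ~ 1-(1-p)^m."""
        rng = np.random.default_rng(3)
        n = 4000
        feat = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(3)})
        spec, X, idx = rg.build_design(feat, position=None)
        y = rng.poisson(2.0, n)
        fit = rg.fit_count_model(X, y, np.zeros(n), family="poisson")
        C = pd.DataFrame(np.eye(3), index=["c0", "c1", "c2"],
                         columns=["x0", "x1", "x2"])
        res = rg.contrast_tests(fit, C, adjust="single_step_maxz", draws=400_000)
        for _, row in res.iterrows():
            sidak = 1 - (1 - row["p"]) ** 3
            assert row["p_adj"] == pytest.approx(sidak, abs=0.01)

    def test_bonferroni(self):
        spec, fit = self.fit_null()
        C = pd.DataFrame([{"x1": 1.0}, {"intercept": 1.0}],
                         index=["a", "b"]).fillna(0.0)
        res = rg.contrast_tests(fit, C, adjust="bonferroni")
        assert np.allclose(res["p_adj"], np.minimum(1, res["p"] * 2))

    def test_planted_tss_interaction_recovered(self):
        """A +0.3 log-scale TSS-only interaction is recovered by the
        downstream TSS-far contrast within 3 SE."""
        rng = np.random.default_rng(7)
        n = 20_000
        feat = pd.DataFrame({"x1": rng.normal(size=n)})
        pos = pd.Series(rng.choice(POS4, size=n))
        spec, X, idx = rg.build_design(feat, pos, interactions=True)
        eta = 0.3 + 0.3 * feat["x1"].to_numpy() * (pos == "downstream_TSS").to_numpy()
        y = rng.poisson(np.exp(eta))
        fit = rg.fit_count_model(X, y, np.zeros(n), family="poisson")
        C = rg.tss_effect_contrasts(spec)
        res = rg.contrast_tests(fit, C, adjust="single_step_maxz", draws=100_000)
        row = res.loc["x1|downstream|TSS-far"]
        assert abs(row["estimate"] - 0.3) < 3 * row["se"]
        # and the null upstream contrast is near zero
        row0 = res.loc["x1|upstream|TSS-far"]
        assert abs(row0["estimate"]) < 3 * row0["se"]

    def test_pct_change_column(self):
        spec, fit = self.fit_null()
        C = pd.DataFrame([{"x1": 1.0}], index=["c"]).fillna(0.0)
        res = rg.contrast_tests(fit, C, adjust="none")
        assert res["pct_change"].iloc[0] == pytest.approx(
            100 * (np.exp(res["estimate"].iloc[0]) - 1))
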