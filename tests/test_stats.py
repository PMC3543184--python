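"""Enrichment, correlation, and covariance-model selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import translatome_kit as tk
from translatome_kit.stats import _aic, default_model_spec


class TestHypergeometricEnrichment:
    def test_strictly_greater_convention(self):
        """With universe 10, trait 4, subset 5 and 3 observed, only the
        4-of-4 draw is more extreme: C(4,4) C(6,1) / C(10,5) = 6/252."""
        assert tk.hypergeometric_enrichment(5, 10, 4, 3) == pytest.approx(
            6.0 / 252.0, abs=1e-12
        )

    def test_most_extreme_count_has_zero_pvalue(self):
        assert tk.hypergeometric_enrichment(5, 10, 4, 4) == 0.0
        assert tk.hypergeometric_enrichment(3, 8, 0, 0) == 0.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            tk.hypergeometric_enrichment(5, 10, 11, 3)
        with pytest.raises(ValueError):
            tk.hypergeometric_enrichment(5, 10, 4, 5)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = tk.pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = tk.pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_samples_near_zero(self):
        """At n = 10^4 the null r has SD 0.01; |r| < 0.05 in every one
        of 50 seeds."""
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            r, _ = tk.pearson_correlation(rng.normal(size=10_000),
                                          rng.normal(size=10_000))
            ok += abs(r) < 0.05
        assert ok == 50

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            tk.pearson_correlation(np.ones(5), np.arange(5.0))


class TestCovarianceModel:
    def test_noiseless_single_covariate(self):
        """A response equal to one standardized covariate keeps exactly
        that covariate with coefficient 1 and adjusted R-squared 1."""
        X, y, _ = tk.ancova_dataset(n=200, coefficients={"cai": 1.0},
                                    noise_sd=1e-10, seed=0)
        fit = tk.fit_covariance_model(X.drop(columns="protein_level"), y,
                                      default_model_spec("occ"))
        assert fit.selected == ["cai"]
        assert fit.coefficients["cai"] == pytest.approx(1.0, abs=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_rarely_retains_covariates(self):
        """AIC retains a pure-noise regressor with probability
        P(chi2_1 > 2) ~ 0.157, so per-covariate retention over seeds must
        sit near that rate and well below one half."""
        spec = default_model_spec("occ")
        terms = list(spec.quantitative)
        retained = {t: 0 for t in terms}
        n_seeds = 100
        for seed in range(n_seeds):
            X, _, _ = tk.ancova_dataset(n=400, coefficients={}, seed=seed)
            rng = np.random.default_rng(seed + 10_000)
            y = pd.Series(np.exp(rng.normal(size=400)), index=X.index)
            fit = tk.fit_covariance_model(X.drop(columns="protein_level"),
                                          y, spec)
            for t in terms:
                retained[t] += t in fit.selected
        rates = {t: retained[t] / n_seeds for t in terms}
        assert all(rate <= 0.35 for rate in rates.values()), rates

    def test_adjusted_r2_closed_form(self):
        X, y, _ = tk.ancova_dataset(n=300, seed=3)
        fit = tk.fit_covariance_model(X.drop(columns="protein_level"), y,
                                      default_model_spec("occ"))
        n, p = fit.n_used, len(fit.selected)
        expected = 1 - (1 - fit.r2) * (n - 1) / (n - p - 1)
        assert fit.adj_r2 == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_affine_covariate_rescaling(self):
        """Standardization absorbs scale changes of log covariates and
        affine changes of raw covariates."""
        X, y, _ = tk.ancova_dataset(n=300, seed=4)
        X = X.drop(columns="protein_level")
        spec = default_model_spec("occ")
        base = tk.fit_covariance_model(X, y, spec)
        X2 = X.assign(mrna_half_life=3.0 * X["mrna_half_life"],
                      gravy=-2.0 * X["gravy"] + 5.0)
        other = tk.fit_covariance_model(X2, y, spec)
        assert set(base.selected) == set(other.selected)
        for term in base.selected:
            expected = base.coefficients[term]
            if term == "gravy":
                expected = -expected           # flipped sign flips the slope
            assert other.coefficients[term] == pytest.approx(expected, abs=1e-8)

    def test_collinear_pair_named(self):
        X, y, _ = tk.ancova_dataset(n=100, seed=5)
        X = X.drop(columns="protein_level")
        X["dG_down"] = 2.0 * X["dG_up"] + 1e-9
        with pytest.raises(ValueError, match="dG_up and dG_down"):
            tk.fit_covariance_model(X, y, default_model_spec("occ"))

    def test_aic_matches_statsmodels_up_to_constant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(80, 3))
        y = x[:, 0] + rng.normal(size=80)
        diff_mine = _aic(x, y) - _aic(x[:, :2], y)
        f1 = sm.OLS(y, sm.add_constant(x)).fit().aic
        f2 = sm.OLS(y, sm.add_constant(x[:, :2])).fit().aic
        assert diff_mine == pytest.approx(f1 - f2, abs=1e-8)

    def test_exhaustive_agrees_with_stepwise_here(self):
        X, y, _ = tk.ancova_dataset(
            n=300, coefficients={"cai": 0.5, "mrna_half_life": -0.4},
            noise_sd=0.3, seed=7,
        )
        X = X.drop(columns=["protein_level", "functional_category"])
        spec = tk.ModelSpec(response="occ",
                            quantitative=dict.fromkeys(X.columns, "raw"))
        spec.quantitative.update({"mrna_concentration": "log",
                                  "mrna_half_life": "log",
                                  "cds_length_nt": "log",
                                  "aromaticity": "log", "cai": "log"})
        a = tk.fit_covariance_model(X, y, spec, selection="stepwise")
        b = tk.fit_covariance_model(X, y, spec, selection="exhaustive")
        assert {"cai", "mrna_half_life"} <= set(a.selected)
        assert set(a.selected) == set(b.selected)

    def test_too_few_complete_cases_rejected(self):
        X, y, _ = tk.ancova_dataset(n=30, seed=8)
        X = X.drop(columns="protein_level")
        X.iloc[15:, 0] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            tk.fit_covariance_model(X, y, default_model_spec("occ"))


class TestProteinLevelModel:
    def make_dataset(self, occ_beta, seed=0, n=300):
        X, _, _ = tk.ancova_dataset(n=n, coefficients={}, seed=seed)
        X = X.drop(columns="protein_level")
        rng = np.random.default_rng(seed + 1)
        X["occupancy"] = np.clip(rng.normal(0.66, 0.06, size=n), 0.3, 0.95)
        X["density"] = rng.lognormal(0.0, 0.4, size=n)
        z = lambda v: (v - v.mean()) / v.std(ddof=0)
        eta = (0.54 * z(np.log(X["cai"])) + occ_beta * z(np.log(X["occupancy"])))
        protein = pd.Series(np.exp(eta + rng.normal(0, 0.5, size=n)),
                            index=X.index, name="protein_level")
        return X, protein

    def test_translatome_covariates_improve_fit(self):
        X, protein = self.make_dataset(occ_beta=0.4)
        fit_without, fit_with = tk.protein_level_model(X, protein)
        assert fit_with.adj_r2 > fit_without.adj_r2
        assert "occupancy" in fit_with.selected

    def test_null_occupancy_effect_usually_dropped(self):
        dropped = 0
        for seed in range(20):
            X, protein = self.make_dataset(occ_beta=0.0, seed=seed)
            _, fit_with = tk.protein_level_model(X, protein)
            dropped += "occupancy" not in fit_with.selected
        assert dropped >= 20 * 0.6            # AIC noise-retention ~16%/seed

    def test_deterministic_cai_only(self):
        X, protein = self.make_dataset(occ_beta=0.0, seed=3)
        z = (np.log(X["cai"]) - np.log(X["cai"]).mean())
        z = z / z.std(ddof=0)
        protein = pd.Series(np.exp(z), index=X.index)
        fit_without, _ = tk.protein_level_model(X, protein)
        assert fit_without.selected == ["cai"]
        assert fit_without.coefficients["cai"] == pytest.approx(1.0, abs=1e-6)


def test_enumeration_oracle_small_universe():
    """Spot-check the hypergeometric p-value against literal enumeration
    of subsets for one instance (the exhaustive sweep lives in the
    acceptance suite)."""
    n2, m, n1, n_obs = 9, 4, 4, 2
    universe = [1] * m + [0] * (n2 - m)
    total = more = 0
    for subset in itertools.combinations(range(n2), n1):
        total += 1
        more += sum(universe[i] for i in subset) > n_obs
    assert tk.hypergeometric_enrichment(n1, n2, m, n_obs) == pytest.approx(
        more / total, abs=1e-12
    )
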