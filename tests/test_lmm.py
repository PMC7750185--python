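import numpy as np
import pandas as pd
import pytest

import coloboot as cb
from coloboot.lmm import (
    NotConvergedError,
    RankDeficientDesignError,
    fit_arrays,
    loglik_dense,
    ols_profile,
)
from conftest import random_instance


class TestLikelihoodOracle:
    def test_matches_dense_covariance_logpdf(self):
        """Profiled-likelihood fit reports the same log-likelihood as a dense
        block-compound-symmetric Gaussian density evaluated at the optimum."""
        rng = np.random.default_rng(101)
        for _ in range(15):
            y, X, farm = random_instance(rng)
            fit = fit_arrays(y, X, farm)
            oracle = loglik_dense(
                y, X, fit.params.to_numpy(), fit.theta_U, fit.theta_eps, farm
            )
            assert fit.llf == pytest.approx(oracle, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        """Independent optimizer cross-check on a few instances."""
        import warnings

        import statsmodels.api as sm

        rng = np.random.default_rng(202)
        for _ in range(3):
            y, X, farm = random_instance(rng, n_max=50)
            fit = fit_arrays(y, X, farm)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=farm).fit(reml=False)
            # our profiled optimum should never be worse, and should agree
            assert fit.llf >= res.llf - 1e-6
            assert fit.llf == pytest.approx(res.llf, abs=1e-4)
            np.testing.assert_allclose(
                fit.params.to_numpy(), res.fe_params, atol=1e-3
            )

    def test_ols_limit(self):
        """With the farm variance profiled to zero the fit is exactly OLS."""
        rng = np.random.default_rng(303)
        y, X, farm = random_instance(rng)
        beta, theta_eps, _ = ols_profile(y, X, farm)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, beta_ols, atol=1e-8)
        resid = y - X @ beta_ols
        assert theta_eps == pytest.approx(float(resid @ resid) / len(y), abs=1e-8)


class TestFitBasics:
    def test_intercept_only_balanced_grand_mean(self):
        """On balanced data the intercept-only ML estimate of mu is the grand
        mean (symmetry of the balanced estimator)."""
        rng = np.random.default_rng(5)
        G, m = 12, 5
        farm = np.repeat(np.arange(G), m)
        y = rng.normal(3.0, 1.0, size=G * m) + rng.normal(0, 1, G)[farm]
        fit = fit_arrays(y, np.ones((G * m, 1)), farm)
        assert fit.params.iloc[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_aic_formula_and_k(self, small_dataset):
        fit = cb.fit_lmm(small_dataset, "log_tbc", ["teat_dry_wiped"])
        assert fit.k_params == fit.k_fixed + 2
        assert cb.aic_of(fit) == pytest.approx(
            -2 * fit.llf + 2 * fit.k_params, abs=1e-12
        )

    def test_aic_of_rejects_nonconverged(self, small_dataset):
        fit = cb.fit_lmm(small_dataset, "log_tbc", ["teat_dry_wiped"])
        fit.converged = False
        with pytest.raises(NotConvergedError):
            cb.aic_of(fit)

    def test_nested_loglik_monotone(self, study_dataset):
        """A superset of fixed effects can only raise the ML log-likelihood."""
        terms = ["teat_dry_wiped", "milking_system", "feeding_hot_water"]
        lls = [
            cb.fit_lmm(study_dataset, "log_tbc", terms[: k + 1]).llf
            for k in range(len(terms))
        ]
        assert all(lls[i + 1] >= lls[i] - 1e-8 for i in range(len(lls) - 1))

    def test_strong_signal_beats_intercept_on_aic(self, small_dataset):
        null = cb.fit_lmm(small_dataset, "log_tbc", [])
        full = cb.fit_lmm(small_dataset, "log_tbc", ["teat_dry_wiped"])
        assert full.aic < null.aic

    def test_single_farm_rejected(self, small_dataset):
        one_farm = cb.Dataset(
            frame=small_dataset.frame[
                small_dataset.frame.farm_id == small_dataset.frame.farm_id.iloc[0]
            ].reset_index(drop=True),
            standardization=small_dataset.standardization,
        )
        with pytest.raises(ValueError):
            cb.fit_lmm(one_farm, "log_tbc", ["teat_dry_wiped"])

    def test_rank_deficient_raise_names_columns(self, study_dataset):
        with pytest.raises(RankDeficientDesignError) as err:
            cb.fit_lmm(
                study_dataset, "log_tbc",
                ["collection_source", "milking_system"],
                on_collinear="raise",
            )
        assert "milking_system:Robot" in str(err.value)


class TestInvariances:
    def test_record_order_and_farm_labels(self, small_dataset):
        fit = cb.fit_lmm(small_dataset, "log_tbc", ["teat_dry_wiped"])
        frame = small_dataset.frame.sample(frac=1.0, random_state=9)
        frame = frame.assign(farm_id="farm-" + frame["farm_id"].str[::-1])
        shuffled = cb.Dataset(
            frame=frame.reset_index(drop=True),
            standardization=small_dataset.standardization,
        )
        fit2 = cb.fit_lmm(shuffled, "log_tbc", ["teat_dry_wiped"])
        pd.testing.assert_series_equal(fit.params, fit2.params, atol=1e-8)
        assert fit.llf == pytest.approx(fit2.llf, abs=1e-8)
        assert fit.theta_U == pytest.approx(fit2.theta_U, abs=1e-6)


class TestPredict:
    def test_blup_shrinkage_identity(self, small_dataset):
        """Per-farm mean conditional residual equals the fixed-part mean
        residual shrunk by 1/(1 + lambda n_j)."""
        fit = cb.fit_lmm(small_dataset, "log_tbc", ["teat_dry_wiped"])
        r_fixed = small_dataset.frame["log_tbc"].to_numpy() - fit.predict(
            mode="fixed_only"
        )
        cond = small_dataset.frame["log_tbc"].to_numpy() - fit.predict(
            mode="with_farm_effect"
        )
        lam = fit.lam
        for code, farm in enumerate(fit.design.farm_ids):
            mask = fit.design.farm_codes == code
            nj = mask.sum()
            expected = r_fixed[mask].mean() / (1.0 + lam * nj)
            assert cond[mask].mean() == pytest.approx(expected, abs=1e-8)

    def test_zero_farm_variance_modes_identical(self):
        rng = np.random.default_rng(17)
        n, G = 120, 30
        farm = np.repeat(np.arange(G), n // G)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.5]) + rng.normal(0, 1, n)  # no farm effect
        fit = fit_arrays(y, X, farm)
        if fit.theta_U == 0.0:
            np.testing.assert_allclose(
                fit.predict(mode="fixed_only"),
                fit.predict(mode="with_farm_effect"),
            )
        else:  # tiny estimated farm variance still shrinks BLUPs hard
            assert np.abs(fit.blup_values).max() < 0.2

    def test_unseen_farm_gets_fixed_only(self, small_dataset):
        fit = cb.fit_lmm(small_dataset, "log_tbc", ["teat_dry_wiped"])
        rec = small_dataset.frame.iloc[[0]].assign(farm_id="brand-new")
        np.testing.assert_allclose(
            fit.predict(rec, mode="with_farm_effect"),
            fit.predict(rec, mode="fixed_only"),
        )

    def test_unseen_level_rejected(self, small_dataset):
        fit = cb.fit_lmm(small_dataset, "log_tbc", ["teat_dry_wiped"])
        rec = small_dataset.frame.iloc[[0]].assign(teat_dry_wiped="Sometimes")
        with pytest.raises(ValueError, match="unseen"):
            fit.predict(rec)


class TestResidualNormality:
    def test_gaussian_residuals_near_symmetric(self, study_dataset):
        fit = cb.fit_lmm(study_dataset, "log_tbc", ["teat_dry_wiped"])
        diag = cb.residual_normality(fit)
        assert abs(diag["skewness"]) < 0.4
        assert not diag["unreliable"]
        assert len(diag["qq_sample"]) == fit.n

    def test_skewed_noise_flagged(self):
        rng = np.random.default_rng(23)
        n, G = 240, 40
        farm = np.repeat(np.arange(G), n // G)
        y = 1.0 + rng.exponential(2.0, size=n)  # strongly right-skewed noise
        fit = fit_arrays(y, np.ones((n, 1)), farm)
        assert cb.residual_normality(fit)["skewness"] > 0.5

    def test_small_sample_guard(self):
        rng = np.random.default_rng(29)
        farm = np.array([0, 0, 1, 1, 0, 1])
        y = rng.normal(size=6)
        fit = fit_arrays(y, np.ones((6, 1)), farm)
        assert cb.residual_normality(fit)["unreliable"]
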