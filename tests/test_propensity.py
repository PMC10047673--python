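import math
import warnings

import numpy as np
import pytest

from promatch.data_model import CovariateSpec, encode_design
from promatch.errors import DesignError, InputError, SeparationError
from promatch.propensity import (PropensityFit, assign_deciles, decile_checks,
                                 fit_propensity)
from promatch.synthetic import SimulationConfig, simulate_cohort


class TestFitPropensity:
    def test_intercept_only_reproduces_log_odds(self):
        """694 treated of 1053: the intercept is log(694/359) and every
        score equals the treated fraction."""
        n, k = 1053, 694
        X = np.ones((n, 1))
        y = np.concatenate([np.ones(k), np.zeros(n - k)])
        fit = fit_propensity(X, y)
        assert fit.converged
        assert math.isclose(fit.coefficients[0], math.log(694 / 359), rel_tol=1e-9)
        np.testing.assert_allclose(fit.scores, k / n, atol=1e-10)

    def test_null_model_slopes_near_zero(self):
        rng = np.random.default_rng(4)
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = rng.random(n) < 0.5
        fit = fit_propensity(X, y.astype(float))
        se = 2 / n ** 0.5  # crude asymptotic scale for unit-variance covariates
        assert np.all(np.abs(fit.coefficients[1:]) < 4 * se)

    def test_recovers_simulated_coefficients_within_3_se(self, big_cohort):
        """Slope recovery against the generator's true assignment model, with
        standard errors from the inverse Fisher information."""
        cohort, truth = big_cohort
        from promatch.pipeline import PipelineConfig, analysis_cohort
        analysis = analysis_cohort(cohort, PipelineConfig(input_path="unused"))
        X, labels = encode_design(analysis)
        y = analysis.df["fast_track"].astype(bool).to_numpy()
        fit = fit_propensity(X, y, labels)

        # independent Fisher-information oracle at the MLE
        mu = 1 / (1 + np.exp(-(X @ fit.coefficients)))
        info = (X * (mu * (1 - mu))[:, None]).T @ X
        se = np.sqrt(np.diag(np.linalg.inv(info)))

        centers = truth.centers
        for j, label in enumerate(labels):
            if label == "intercept":
                true_val = truth.beta_treat["intercept"] - sum(
                    truth.beta_treat[t] * centers[t]
                    for t in centers if t in truth.beta_treat
                    and t in labels)
            else:
                true_val = truth.beta_treat.get(label, 0.0)
            assert abs(fit.coefficients[j] - true_val) < 3 * se[j], label

    def test_agrees_with_statsmodels_glm(self, default_cohort):
        import statsmodels.api as sm
        cohort, _ = default_cohort
        from promatch.pipeline import PipelineConfig, analysis_cohort
        analysis = analysis_cohort(cohort, PipelineConfig(input_path="unused"))
        X, labels = encode_design(analysis)
        y = analysis.df["fast_track"].astype(bool).to_numpy().astype(float)
        fit = fit_propensity(X, y, labels)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.log_likelihood, ref.llf, atol=1e-6)

    def test_mean_score_equals_treated_fraction(self, default_pipeline_result):
        fit = default_pipeline_result.fit
        treated_frac = default_pipeline_result.summary()["n_treated"] / \
            default_pipeline_result.cohort_analysis.n
        assert abs(fit.scores.mean() - treated_frac) < 1e-6

    def test_scores_invariant_to_affine_covariate_rescaling(self, default_cohort):
        cohort, _ = default_cohort
        from promatch.pipeline import PipelineConfig, analysis_cohort
        analysis = analysis_cohort(cohort, PipelineConfig(input_path="unused"))
        X, labels = encode_design(analysis)
        y = analysis.df["fast_track"].astype(bool).to_numpy()
        fit1 = fit_propensity(X, y, labels)
        X2 = X.copy()
        j = labels.index("age")
        X2[:, j] = (X2[:, j] - 50.0) / 7.0
        fit2 = fit_propensity(X2, y, labels)
        np.testing.assert_allclose(fit1.scores, fit2.scores, atol=1e-10)

    def test_perfect_separation_detected(self):
        # a tight decision gap forces the divergence past the detection bound
        x = np.repeat([-0.0005, 0.0005], 20)
        X = np.column_stack([np.ones(40), x])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_propensity(X, y)

    def test_rank_deficiency_detected(self):
        n = 30
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = np.tile([0.0, 1.0], n // 2)
        with pytest.raises(DesignError):
            fit_propensity(X, y)

    def test_single_group_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(InputError):
            fit_propensity(X, np.ones(10))


def _toy_fit(scores):
    scores = np.asarray(scores, dtype=float)
    return PropensityFit(np.array([0.0]), ["intercept"], scores, True, 1, 0.0)


class TestDecileChecks:
    def test_identical_distributions_pass_with_p_one(self):
        rng = np.random.default_rng(8)
        scores = np.repeat(rng.random(200), 2)  # treated/control twins
        y = np.tile([True, False], 200)
        fit = _toy_fit(scores)
        X = np.column_stack([np.ones(400), scores])
        diag = decile_checks(fit, X, y, labels=["intercept", "cov"])
        assert diag.passed
        np.testing.assert_allclose(diag.score_test_p, 1.0)
        np.testing.assert_allclose(diag.covariate_test_p["cov"], 1.0)

    def test_bonferroni_convention(self):
        """A raw p of 0.0056 in one of ten strata adjusts to 0.056, which
        still passes at alpha 0.05."""
        from promatch.propensity import _bonferroni
        adj = _bonferroni([0.0056] + [0.9] * 9)
        assert math.isclose(adj[0], 0.056, rel_tol=1e-12)
        assert all(a == 1.0 for a in adj[1:])
        assert (adj >= 0.05).all()

    def test_planted_shift_detected(self):
        """A location shift confined to one stratum fails the family."""
        rng = np.random.default_rng(15)
        n = 1000
        scores = np.sort(rng.random(n))
        y = rng.random(n) < 0.5
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        # plant a covariate shift in stratum 3 only
        in3 = (np.arange(n) * 10) // n == 3
        X[in3 & y, 1] += 3.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diag = decile_checks(_toy_fit(scores), X, y,
                                 labels=["intercept", "cov"])
        assert not diag.passed
        assert diag.covariate_test_p["cov"][3] < 0.05

    def test_empty_group_stratum_flagged(self):
        n = 100
        scores = np.sort(np.linspace(0.01, 0.99, n))
        y = scores > 0.15  # bottom stratum is all-control
        X = np.ones((n, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            diag = decile_checks(_toy_fit(scores), X, y, labels=["intercept"])
        assert ("propensity_score", 0) in diag.untestable
        assert diag.score_test_p[0] == 1.0

    def test_decile_sizes_balanced_for_distinct_scores(self):
        rng = np.random.default_rng(23)
        n = 1037
        strata = assign_deciles(rng.random(n))
        sizes = np.bincount(strata, minlength=10)
        assert sizes.min() >= n // 10
        assert sizes.max() <= -(-n // 10)

    def test_edges_non_decreasing(self, default_pipeline_result):
        d = default_pipeline_result.diagnostics
        assert (np.diff(d.decile_edges) >= 0).all()
        assert ((d.score_test_p >= 0) & (d.score_test_p <= 1)).all()
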