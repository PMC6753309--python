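"""Hierarchical logistic regression, bridge sampling and Bayes factors."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, log_expit

from wmbind.bridge import bridge_sample, log_ml_quadrature
from wmbind.generate import GroundTruth, simulate_dataset
from wmbind.logistic import (
    BFConfig,
    aggregate_accuracy,
    bayes_factor,
    fit_accuracy_model,
    marginal_likelihood,
    sensitivity_analysis,
)
from wmbind.mpt import MPTParams

#: Pure binding truth: Pi ~ 1, so RSS_New has no effect on accuracy.
NULL_RSS_NEW_TRUTH = dict(
    group=MPTParams(0.6, -0.35, 10.0, 0.0),
    sd={"pi_intercept": 0.0, "pi_slope": 0.0},
)

SMALL_BF = dict(chains=2, warmup=600, draws=1200)


@pytest.fixture(scope="module")
def accuracy_data():
    truth = GroundTruth(**NULL_RSS_NEW_TRUTH, n_subjects=10, seed=71)
    return aggregate_accuracy(simulate_dataset(truth, words=False))


@pytest.fixture(scope="module")
def fitted(accuracy_data):
    return fit_accuracy_model(accuracy_data, BFConfig(seed=5, **SMALL_BF))


class TestAggregation:
    def test_standardization_recorded_and_invertible(self, accuracy_data):
        std = accuracy_data.standardization.set_index("predictor")
        for p, z in accuracy_data.z.items():
            raw = z * std.loc[p, "scale"] + std.loc[p, "mean"]
            assert raw.min() >= 0
            np.testing.assert_allclose(np.sort(np.unique(raw.round(9) % 1)), 0)

    def test_counts_complete(self, accuracy_data):
        assert accuracy_data.k_correct.shape == accuracy_data.n_total.shape
        assert (accuracy_data.n_total > 0).all()
        assert (accuracy_data.k_correct <= accuracy_data.n_total).all()


class TestFit:
    def test_set_size_effect_found_rss_new_null(self, fitted):
        lo, hi = fitted.hdi("set_size")
        assert hi < 0  # larger memory sets hurt accuracy
        lo_n, hi_n = fitted.hdi("rss_new")
        assert lo_n < 0 < hi_n  # no new-word effect in the generative truth

    def test_fitted_probabilities_bounded(self, fitted):
        beta, u, _ = fitted.model.unpack(fitted.flat()[:100])
        eta = beta @ fitted.model.z_fixed.T
        p = expit(eta)
        assert np.all((p > 0) & (p < 1))

    def test_intercept_only_data_recovers_null(self):
        """Constant accuracy: every fixed-effect HDI spans zero."""
        rng = np.random.default_rng(0)
        truth = GroundTruth(group=MPTParams(1.2, 0.0, 10.0, 0.0),
                            sd={k: 0.0 for k in ("pb_intercept", "pb_slope",
                                                 "pi_intercept", "pi_slope")},
                            n_subjects=10, seed=81)
        df = simulate_dataset(truth, words=False)
        # constant p_correct requires constant rss_list too; restrict to one
        df = df[df.rss_list == 2]
        fit = fit_accuracy_model(df, BFConfig(seed=6, **SMALL_BF))
        for pred in ("set_size", "rss_new"):
            lo, hi = fit.hdi(pred)
            assert lo < 0 < hi


class TestBridge:
    @staticmethod
    def _toy(k, n, scale):
        def log_joint_scalar(b):
            return (k * log_expit(b) + (n - k) * log_expit(-b)
                    + stats.cauchy.logpdf(b, scale=scale))

        def log_joint(theta):
            b = theta[:, 0]
            return (k * log_expit(b) + (n - k) * log_expit(-b)
                    + stats.cauchy.logpdf(b, scale=scale))

        return log_joint_scalar, log_joint

    @staticmethod
    def _posterior_draws(log_joint_scalar, rng, n_draws=8000):
        b, lp, out = 0.0, log_joint_scalar(0.0), []
        for t in range(n_draws + 2000):
            prop = b + 0.6 * rng.standard_normal()
            lpp = log_joint_scalar(prop)
            if np.log(rng.random()) < lpp - lp:
                b, lp = prop, lpp
            if t >= 2000:
                out.append(b)
        return np.array(out)[:, None]

    def test_matches_quadrature_within_two_percent(self):
        """Intercept-only binomial-logistic toy: bridge vs numerical integration."""
        log_joint_scalar, log_joint = self._toy(37, 60, 0.353)
        oracle = log_ml_quadrature(log_joint_scalar)
        rng = np.random.default_rng(10)
        draws = self._posterior_draws(log_joint_scalar, rng)
        res = bridge_sample(log_joint, draws, rng, reps=3)
        assert res.converged
        assert abs(res.log_ml - oracle) / abs(oracle) < 0.02

    def test_repeated_estimates_agree(self):
        log_joint_scalar, log_joint = self._toy(12, 40, 1.0)
        rng = np.random.default_rng(11)
        draws = self._posterior_draws(log_joint_scalar, rng)
        res = bridge_sample(log_joint, draws, rng, reps=5)
        assert res.spread < 0.02


class TestBayesFactor:
    def test_dropping_absent_predictor_is_error(self, accuracy_data):
        cfg = BFConfig(seed=5, **SMALL_BF)
        with pytest.raises(ValueError):
            bayes_factor(accuracy_data, "session", cfg)
        reduced = fit_accuracy_model(accuracy_data, cfg, fixed=("set_size", "rss_list"))
        with pytest.raises(ValueError, match="not in the fitted model"):
            bayes_factor(accuracy_data, "rss_new", cfg, full_fit=reduced)

    def test_strong_effect_strongly_favored(self, accuracy_data, fitted):
        cfg = BFConfig(seed=5, **SMALL_BF)
        res = bayes_factor(accuracy_data, "set_size", cfg, full_fit=fitted)
        assert res.bf > 100

    def test_null_effect_bayes_factors_mostly_below_one(self):
        """True RSS_New null: evidence should typically favor exclusion."""
        below = 0
        for rep in range(3):
            truth = GroundTruth(**NULL_RSS_NEW_TRUTH, n_subjects=10, seed=900 + rep)
            data = aggregate_accuracy(simulate_dataset(truth, words=False))
            res = bayes_factor(data, "rss_new", BFConfig(seed=20 + rep, **SMALL_BF))
            below += res.bf < 1
        assert below >= 2

    def test_reciprocity(self, accuracy_data, fitted):
        """Independent re-estimates of both marginal likelihoods: the forward
        and reverse Bayes factors multiply to 1 within estimator noise."""
        cfg = BFConfig(seed=5, **SMALL_BF)
        res = bayes_factor(accuracy_data, "rss_new", cfg, full_fit=fitted)
        rng = np.random.default_rng(77)
        ml_full = marginal_likelihood(fitted, rng)
        reduced = fit_accuracy_model(accuracy_data, BFConfig(seed=31, **SMALL_BF),
                                     fixed=("set_size", "rss_list"))
        ml_red = marginal_likelihood(reduced, rng)
        log_bf_rev = ml_red.log_ml - ml_full.log_ml
        assert abs(res.log_bf + log_bf_rev) < 0.3


class TestSensitivity:
    def test_single_scale_collapses_to_point(self, accuracy_data):
        cfg = BFConfig(seed=5, **SMALL_BF)
        out = sensitivity_analysis(accuracy_data, "rss_new", scales=(0.353,), config=cfg)
        assert len(out) == 1
        lo, hi = out.attrs["bf_range"]
        assert lo == hi == out["bf"].iloc[0]

    def test_null_bf_shrinks_with_wider_prior(self, accuracy_data):
        """Occam factor: under a null, a wider effect prior penalizes the
        bigger model, so inclusion BFs decrease over the scale grid."""
        cfg = BFConfig(seed=5, **SMALL_BF)
        out = sensitivity_analysis(accuracy_data, "rss_new",
                                   scales=(0.25, 3.0), config=cfg)
        bf_narrow = out.loc[out.prior_scale == 0.25, "bf"].iloc[0]
        bf_wide = out.loc[out.prior_scale == 3.0, "bf"].iloc[0]
        assert bf_wide < bf_narrow

    def test_invalid_scale_rejected(self, accuracy_data):
        with pytest.raises(ValueError):
            sensitivity_analysis(accuracy_data, "rss_new", scales=(0.5, -1.0),
                                 config=BFConfig(seed=5, **SMALL_BF))
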