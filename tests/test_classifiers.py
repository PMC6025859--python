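import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from metabosig import (SignatureClassifier, aggregate_by_class, auc,
                       fit_logistic, fit_pcr, fit_pls)
from conftest import make_cohort_frame
from metabosig.cohort import CohortTable


def standardized(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


class TestLogistic:
    def test_separable_feature_flags_separation(self):
        y = np.repeat([0, 1], 20)
        X = y[:, None].astype(float)
        clf = fit_logistic(X, y)
        assert clf.separation_flag_
        assert auc(clf.decision_function(X), y) == 1.0

    def test_coefficients_match_statsmodels_mle(self, rng):
        """Unpenalized fit agrees with an independent ML implementation."""
        n = 200
        X = rng.normal(size=(n, 2))
        eta = 0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        clf = SignatureClassifier("logistic", scale=False).fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X - X.mean(axis=0))).fit(disp=0)
        np.testing.assert_allclose(clf.intercept_[0], ref.params[0], atol=1e-4)
        np.testing.assert_allclose(clf.coef_.ravel(), ref.params[1:], atol=1e-4)
        # and the true coefficients are recovered within 3 SE
        assert abs(ref.params[1] - 1.2) < 3 * ref.bse[1]
        assert abs(ref.params[2] + 0.8) < 3 * ref.bse[2]

    def test_feature_permutation_equivariance(self, rng):
        X = rng.normal(size=(80, 4))
        y = rng.integers(0, 2, 80)
        perm = [2, 0, 3, 1]
        s1 = fit_logistic(X, y).decision_function(X)
        s2 = fit_logistic(X[:, perm], y).decision_function(X[:, perm])
        np.testing.assert_allclose(s1, s2, atol=1e-6)

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 1] = 4.2
        y = rng.integers(0, 2, 50)
        with pytest.warns(UserWarning, match="constant"):
            clf = fit_logistic(X, y)
        assert np.isfinite(clf.decision_function(X)).all()


class TestPCR:
    def test_full_rank_equals_plain_logistic_auc(self, rng):
        """Unpenalized logistic is rotation-invariant: projecting on all
        principal axes changes nothing about the ranking."""
        X = rng.normal(size=(50, 4)) * np.array([1, 5, 0.2, 2.0])
        y = rng.integers(0, 2, 50)
        a_log = auc(SignatureClassifier("logistic").fit(standardized(X), y)
                    .decision_function(standardized(X)), y)
        a_pcr = auc(fit_pcr(X, y, k=4).decision_function(X), y)
        assert a_pcr == pytest.approx(a_log, abs=1e-9)

    def test_single_feature_reduces_to_univariate_auc(self, rng):
        x = rng.normal(size=(60, 1))
        y = (x.ravel() + rng.normal(size=60) > 0).astype(int)
        a = auc(fit_pcr(x, y, k=1).decision_function(x), y)
        assert a == pytest.approx(max(auc(x.ravel(), y), 1 - auc(x.ravel(), y)),
                                  abs=1e-12)

    def test_axis_sign_does_not_change_auc(self, rng):
        X = rng.normal(size=(70, 3))
        y = rng.integers(0, 2, 70)
        clf = fit_pcr(X, y, k=2)
        flipped = SignatureClassifier("pcr", 2).fit(-X, y)
        assert auc(clf.decision_function(X), y) == pytest.approx(
            auc(flipped.decision_function(-X), y), abs=1e-9)

    def test_k_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 2] = X[:, 0] + X[:, 1]  # rank 2 after centering
        with pytest.raises(ValueError, match="rank"):
            fit_pcr(X, np.tile([0, 1], 5), k=3)


class TestPLS:
    def test_single_feature_reduces_to_univariate_auc(self, rng):
        x = rng.normal(size=(60, 1))
        y = (x.ravel() + rng.normal(size=60) > 0).astype(int)
        a = auc(fit_pls(x, y, k=1).decision_function(x), y)
        assert a == pytest.approx(max(auc(x.ravel(), y), 1 - auc(x.ravel(), y)),
                                  abs=1e-12)

    def test_first_weight_proportional_to_covariance_vector(self, rng):
        """The first NIPALS PLS1 direction is X'y on standardized data."""
        X = rng.normal(size=(80, 5))
        y = rng.integers(0, 2, 80)
        clf = fit_pls(X, y, k=1)
        Z = standardized(X)
        w = Z.T @ (y - y.mean())
        w = w / np.linalg.norm(w)
        got = clf.projection_[:, 0]
        got = got / np.linalg.norm(got)
        np.testing.assert_allclose(np.abs(got), np.abs(w), atol=1e-8)

    def test_supervised_projection_tracks_best_feature(self, rng):
        """k=1 PLS training AUC is within 0.05 of the best single feature
        when effects are spread over correlated features."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            n, p = 120, 8
            latent = r.normal(size=n)
            X = latent[:, None] * 0.7 + r.normal(size=(n, p))
            y = (latent + r.normal(size=n) * 0.8 > 0).astype(int)
            clf = fit_pls(X, y, k=1)
            a_pls = auc(clf.decision_function(X), y)
            best = max(max(auc(X[:, j], y), 1 - auc(X[:, j], y)) for j in range(p))
            assert a_pls >= best - 0.05


class TestScoringContract:
    def test_new_data_scored_with_training_statistics(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, 50)
        clf = fit_pcr(X, y, k=1)
        single = clf.decision_function(X[:1])  # n=1 has no usable statistics
        batch = clf.decision_function(X)[:1]
        np.testing.assert_allclose(single, batch, atol=1e-12)
        # a constant shift of the test data shifts scores deterministically
        shifted = clf.decision_function(X + 1.0)
        expected = clf.decision_function(X) + \
            (1.0 / clf.scale_) @ clf.projection_ @ clf.coef_.ravel()
        np.testing.assert_allclose(shifted, expected, atol=1e-8)

    def test_participant_order_irrelevant(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        perm = rng.permutation(40)
        for fam in ("logistic", "pcr", "pls"):
            s = SignatureClassifier(fam, 1).fit(X, y).decision_function(X)
            sp = SignatureClassifier(fam, 1).fit(X[perm], y[perm]).decision_function(X)
            np.testing.assert_allclose(s, sp, atol=1e-6)


class TestAggregates:
    def test_class_sums_then_log1p(self):
        df = make_cohort_frame(metabolites=("PCaaC32:3", "PCaaC38:0",
                                            "lysoPCaC16:0", "PCaeC38:0"))
        df["PCaaC32:3"] = 1.0
        df["PCaaC38:0"] = 2.0
        agg = aggregate_by_class(CohortTable(df))
        np.testing.assert_allclose(agg["sum_PCaa"], np.log(4.0))
        assert list(agg.columns) == ["sum_lysoPC", "sum_PCaa", "sum_PCae"]

    def test_missing_class_omitted_with_warning(self):
        df = make_cohort_frame(metabolites=("PCaaC32:3", "PCaeC38:0"))
        with pytest.warns(UserWarning, match="lysoPC"):
            agg = aggregate_by_class(CohortTable(df))
        assert "sum_lysoPC" not in agg.columns

    def test_commutes_with_row_reordering(self, tiny_cohort, rng):
        agg = aggregate_by_class(tiny_cohort)
        perm = rng.permutation(tiny_cohort.n)
        shuffled = tiny_cohort.subset(perm)
        agg2 = aggregate_by_class(shuffled)
        np.testing.assert_allclose(agg.to_numpy()[perm], agg2.to_numpy())
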