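"""Multivariate classifiers: logistic, PCR-logistic, PLS-logistic.

The three classification families compared by the pipeline:

* ``logistic`` -- unpenalized multivariate logistic regression on the
  metabolite matrix directly;
* ``pcr`` -- principal component regression: unsupervised principal-
  component scores of the standardized matrix fed to a logistic fit;
* ``pls`` -- partial least squares (univariate-response NIPALS, "PLS1"):
  supervised covariance-maximizing scores fed to a logistic fit.

Features are centered and unit-variance scaled before projection by
default (metabolite variances differ by orders of magnitude).  Scoring
new data always reuses the training standardization.  On complete
separation the logistic deviance has no finite maximizer; the fit is
flagged and the diverged-direction scores are still returned, since AUC
depends only on the ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .cohort import CohortTable
from .nomenclature import classify_metabolite_name

__all__ = ["ModelSpec", "SignatureClassifier", "fit_logistic", "fit_pcr",
           "fit_pls", "aggregate_by_class"]

FAMILIES = ("logistic", "pcr", "pls")


@dataclass(frozen=True)
class ModelSpec:
    """Family + component count + input kind (signature vs aggregates)."""

    family: str = "pcr"
    n_components: int = 1
    inputs: str = "signature"  # {"signature", "aggregate"}

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.inputs not in ("signature", "aggregate"):
            raise ValueError("inputs must be 'signature' or 'aggregate'")

    @property
    def label(self) -> str:
        base = {"logistic": "log", "pcr": "pcr", "pls": "pls"}[self.family]
        return f"sum_{base}" if self.inputs == "aggregate" else base


class SignatureClassifier(ClassifierMixin, BaseEstimator):
    """One estimator covering the three families.

    Parameters
    ----------
    family : {"logistic", "pcr", "pls"}
    n_components : int
        Number of projection components (ignored for ``logistic``).
    scale : bool
        Unit-variance scaling before projection (centering always).

    Attributes
    ----------
    classes_ : array of class labels (positive class = classes_[1])
    center_, scale_ : training standardization
    projection_ : (p, k) loading matrix (pcr/pls; identity for logistic)
    coef_, intercept_ : logistic coefficients on the projected scores
    converged_ : bool
    separation_flag_ : True when the training classes are completely
        separated by the fitted score.
    """

    def __init__(self, family: str = "pcr", n_components: int = 1, scale: bool = True):
        self.family = family
        self.n_components = n_components
        self.scale = scale

    # -- internals -------------------------------------------------------
    def _standardize(self, X):
        return (X - self.center_) / self.scale_

    def fit(self, X, y):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("y must be binary with both classes present")
        yb = (y == self.classes_[1]).astype(float)
        n, p = X.shape
        self.n_features_in_ = p

        self.center_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if self.scale else np.ones(p)
        # relative tolerance: a column constant up to rounding has no signal
        zero_var = sd <= 1e-10 * np.maximum(1.0, np.abs(self.center_))
        if zero_var.any():
            if self.family == "logistic":
                warnings.warn(f"dropping {int(zero_var.sum())} constant feature(s)")
            sd = np.where(zero_var, 1.0, sd)
        self.scale_ = sd
        self.zero_var_mask_ = zero_var
        Z = self._standardize(X)
        Z[:, zero_var] = 0.0

        if self.family == "logistic":
            keep = ~zero_var
            self.projection_ = np.eye(p)[:, keep]
            S = Z[:, keep]
        elif self.family == "pcr":
            k = self._check_k(np.linalg.matrix_rank(Z))
            pca = PCA(n_components=k, svd_solver="full")
            pca.fit(Z)
            V = pca.components_.T  # (p, k)
            # deterministic sign: largest-|loading| entry positive per axis
            for j in range(k):
                i = np.argmax(np.abs(V[:, j]))
                if V[i, j] < 0:
                    V[:, j] = -V[:, j]
            self.projection_ = V
            S = Z @ V
        else:  # pls
            k = self._check_k(np.linalg.matrix_rank(Z))
            if np.allclose(Z.T @ (yb - yb.mean()), 0.0):
                raise ValueError("zero covariance between X and y; no PLS direction")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # y-residual warnings at high k
                pls = PLSRegression(n_components=k, scale=False)
                pls.fit(Z, yb - yb.mean())
            self.pls_ = pls
            self.projection_ = pls.x_rotations_  # maps centered X to scores
            S = pls.transform(Z)

        # C=inf disables the ridge term: plain maximum-likelihood fit
        logit = LogisticRegression(C=np.inf, solver="lbfgs",
                                   max_iter=200, tol=1e-8)
        with warnings.catch_warnings():
            # near-separation stalls lbfgs; the diverged direction still
            # ranks correctly and converged_/separation_flag_ record it
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            logit.fit(S, yb)
        self.logit_ = logit
        self.coef_ = logit.coef_
        self.intercept_ = logit.intercept_
        self.converged_ = bool(np.all(logit.n_iter_ < 200))

        scores = S @ logit.coef_.ravel() + logit.intercept_[0]
        pos, neg = scores[yb == 1], scores[yb == 0]
        self.separation_flag_ = bool(pos.min() > neg.max() or pos.max() < neg.min())
        return self

    def _check_k(self, rank: int) -> int:
        if self.n_components > rank:
            raise ValueError(f"n_components={self.n_components} exceeds rank {rank}")
        return self.n_components

    def _scores(self, X):
        check_is_fitted(self, "logit_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        Z = self._standardize(np.asarray(X, dtype=float))
        Z[:, self.zero_var_mask_] = 0.0
        if self.family == "pls":
            return self.pls_.transform(Z)
        return Z @ self.projection_

    def decision_function(self, X):
        S = self._scores(X)
        return S @ self.coef_.ravel() + self.intercept_[0]

    def predict_proba(self, X):
        return self.logit_.predict_proba(self._scores(X))

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def fit_logistic(X, y) -> SignatureClassifier:
    """Unpenalized multivariate logistic regression."""
    return SignatureClassifier(family="logistic").fit(X, y)


def fit_pcr(X, y, k: int = 1, scale: bool = True) -> SignatureClassifier:
    """Principal component regression with logistic link on k scores."""
    return SignatureClassifier(family="pcr", n_components=k, scale=scale).fit(X, y)


def fit_pls(X, y, k: int = 1, scale: bool = True) -> SignatureClassifier:
    """PLS1 (NIPALS) projection with logistic link on k scores."""
    return SignatureClassifier(family="pls", n_components=k, scale=scale).fit(X, y)


def aggregate_by_class(cohort: CohortTable) -> pd.DataFrame:
    """Lipid-class aggregate inputs: log(1 + sum of raw concentrations).

    Sums run over ALL panel metabolites of each class (not only
    signature members), mirroring the aggregate-model variant.  Columns
    are ``sum_lysoPC``, ``sum_PCaa``, ``sum_PCae``; a class with no
    member in the panel is omitted with a warning.
    """
    by_class: dict[str, list[str]] = {"lysoPC": [], "PCaa": [], "PCae": []}
    for nm in cohort.metabolites:
        by_class[classify_metabolite_name(nm).lipid_class].append(nm)
    cols = {}
    for cls, members in by_class.items():
        if not members:
            warnings.warn(f"no {cls} metabolites in panel; column omitted")
            continue
        cols[f"sum_{cls}"] = np.log1p(cohort.concentrations[members].sum(axis=1))
    return pd.DataFrame(cols, index=cohort.data.index)
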