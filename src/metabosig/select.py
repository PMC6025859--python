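"""Bootstrap out-of-bag AUC metabolite selection.

The pre-selection step of the pipeline: for each metabolite, draw B
bootstrap training sets (N with replacement), fit a univariate logistic
regression on each draw, score the out-of-bag (OOB) participants with
the fitted linear predictor, and record the OOB AUC.  A metabolite
enters the stratum's signature when the 2.5% quantile of its empirical
OOB-AUC distribution exceeds 0.5 — i.e. it ranked cases above controls
better than chance in at least 97.5% of resamples.

For a one-feature logistic regression the linear predictor is a strictly
monotone function of the feature whose direction is the sign of the
fitted slope, and the sign of the ML slope equals the sign of the
training covariance sum(x * (y - ybar)) (the profile log-likelihood is
concave with that derivative at zero).  The OOB AUC therefore equals
``auc(x_oob, y_oob)`` when that covariance is positive and one minus it
otherwise; replicates are scored through this identity rather than an
iterative fit.  Tests assert exact agreement with explicit logistic
fits.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import StratumSpec

__all__ = [
    "auc",
    "bootstrap_oob_auc",
    "select_signature",
    "SelectionRule",
    "BootstrapAUCDist",
    "Signature",
    "BootstrapAUCSelector",
]

QUANTILES = (0.025, 0.5, 0.975)


class UndefinedAUCError(ValueError):
    """Both classes are required to define an AUC."""


class BootstrapInstabilityError(RuntimeError):
    """Too many degenerate bootstrap replicates."""


def auc(scores, labels) -> float:
    """Area under the ROC curve of *scores* for binary *labels*.

    Computed as the Mann-Whitney probability with midrank tie handling:
    (concordant case-control pairs + half the tied pairs) divided by
    n_case * n_control; identical to the trapezoidal ROC area.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos = y == 1
    n1 = int(pos.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("labels contain a single class")
    r = rankdata(s)
    u = r[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class BootstrapAUCDist:
    """Empirical OOB-AUC distribution of one metabolite over B replicates."""

    metabolite: str
    replicate_aucs: np.ndarray
    B: int
    n_discarded: int = 0
    oob_fractions: np.ndarray | None = None

    @property
    def n_valid(self) -> int:
        return len(self.replicate_aucs)

    def quantile(self, q: float) -> float:
        # linear interpolation of order statistics (type 7), fixed package-wide
        return float(np.quantile(self.replicate_aucs, q, method="linear"))

    @property
    def quantiles(self) -> dict[float, float]:
        return {q: self.quantile(q) for q in QUANTILES}


@dataclass(frozen=True)
class SelectionRule:
    """Signature membership rule: q-quantile of OOB AUC above threshold."""

    quantile: float = 0.025
    threshold: float = 0.5
    strict: bool = True

    def admits(self, dist: BootstrapAUCDist) -> bool:
        v = dist.quantile(self.quantile)
        return v > self.threshold if self.strict else v >= self.threshold


@dataclass
class Signature:
    """Metabolites of one stratum passing the bootstrap AUC criterion.

    ``entries`` rows: metabolite, q025, q50, q975 — the reported AUC of
    a signature member is the median (q50) of its OOB distribution.
    """

    stratum: StratumSpec | str
    entries: pd.DataFrame
    rule: SelectionRule = field(default_factory=SelectionRule)

    @property
    def metabolites(self) -> list[str]:
        return list(self.entries["metabolite"])

    def __len__(self) -> int:
        return len(self.entries)

    def without(self, names) -> "Signature":
        keep = ~self.entries["metabolite"].isin(set(names))
        return Signature(self.stratum, self.entries.loc[keep].reset_index(drop=True),
                         self.rule)


def _oob_auc_one_replicate(x, y, idx, oob):
    """OOB AUC of a univariate logistic fit on the draw ``idx``."""
    y_tr = y[idx]
    if y_tr.min() == y_tr.max():
        return None
    y_te = y[oob]
    if len(y_te) == 0 or y_te.min() == y_te.max():
        return None
    x_tr = x[idx]
    # sign of the univariate logistic ML slope = sign of train covariance
    slope_sign = np.sign(np.sum(x_tr * (y_tr - y_tr.mean())))
    a = auc(x[oob], y_te)
    if slope_sign < 0:
        a = 1.0 - a
    elif slope_sign == 0:
        a = 0.5
    return a


def bootstrap_oob_auc(x, y, B: int = 1000, seed: int | None = None) -> BootstrapAUCDist:
    """Bootstrap OOB-AUC distribution for a single metabolite.

    Per replicate: draw N participants with replacement; the OOB set is
    everyone absent from the draw; fit the univariate logistic on the
    draw and record the AUC of its linear predictor on the OOB set.
    Replicates whose draw or OOB set lacks a class are discarded and
    counted, not redrawn.  Deterministic given *seed*.

    Raises
    ------
    BootstrapInstabilityError
        If fewer than half of the replicates are valid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 participants")
    if y.min() == y.max():
        raise UndefinedAUCError("labels contain a single class")
    rng = np.random.default_rng(seed)
    aucs, fracs = [], []
    n_discarded = 0
    all_idx = np.arange(n)
    for _ in range(B):
        idx = rng.integers(n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[idx] = True
        oob = all_idx[~in_bag]
        a = _oob_auc_one_replicate(x, y, idx, oob)
        if a is None:
            n_discarded += 1
            continue
        aucs.append(a)
        fracs.append(len(oob) / n)
    if len(aucs) < 0.5 * B:
        raise BootstrapInstabilityError(
            f"only {len(aucs)} of {B} replicates valid ({n_discarded} discarded)")
    return BootstrapAUCDist("", np.asarray(aucs), B, n_discarded,
                            np.asarray(fracs))


def select_signature(dists: list[BootstrapAUCDist],
                     stratum: StratumSpec | str = "all",
                     rule: SelectionRule | None = None) -> Signature:
    """Signature = metabolites whose OOB-AUC quantile passes the rule.

    The default rule is the 2.5% quantile strictly above 0.5.  An empty
    selection is a valid (empty) signature — some strata select nothing.
    Entries are sorted by metabolite name.
    """
    rule = rule or SelectionRule()
    rows = []
    for d in dists:
        if rule.admits(d):
            qs = d.quantiles
            rows.append({"metabolite": d.metabolite, "q025": qs[0.025],
                         "q50": qs[0.5], "q975": qs[0.975],
                         "n_valid": d.n_valid})
    entries = pd.DataFrame(rows, columns=["metabolite", "q025", "q50", "q975", "n_valid"])
    entries = entries.sort_values("metabolite").reset_index(drop=True)
    return Signature(stratum, entries, rule)


def metabolite_seed(master_seed: int, stratum: str, metabolite: str) -> np.random.SeedSequence:
    """Stable per-(stratum, metabolite) seed, independent of panel order."""
    return np.random.SeedSequence(
        [master_seed, zlib.crc32(stratum.encode()), zlib.crc32(metabolite.encode())])


class BootstrapAUCSelector(SelectorMixin, BaseEstimator):
    """Feature selector driven by bootstrap OOB-AUC distributions.

    Scikit-learn estimator: ``fit(X, y)`` computes the OOB-AUC
    distribution of every column and keeps those passing the selection
    rule; ``transform`` drops the rest.  Column seeds are derived from
    ``random_state`` and the column name, so results do not depend on
    panel order.

    Parameters
    ----------
    B : int
        Bootstrap replicates per feature.
    quantile, threshold, strict : selection rule
        Keep a feature when its ``quantile``-quantile OOB AUC is above
        (``strict``) or at-or-above ``threshold``.
    stratum : str
        Label recorded on the resulting :class:`Signature`.
    random_state : int
        Master seed.

    Attributes
    ----------
    dists_ : list of BootstrapAUCDist
    support_ : boolean mask of selected features
    signature_ : Signature
    """

    def __init__(self, B: int = 1000, quantile: float = 0.025,
                 threshold: float = 0.5, strict: bool = True,
                 stratum: str = "all", random_state: int = 0):
        self.B = B
        self.quantile = quantile
        self.threshold = threshold
        self.strict = strict
        self.stratum = stratum
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xv = X.to_numpy(dtype=float)
            self.feature_names_in_ = np.asarray(names, dtype=object)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(y)
        self.n_features_in_ = Xv.shape[1]
        rule = SelectionRule(self.quantile, self.threshold, self.strict)
        dists = []
        for j, nm in enumerate(names):
            ss = metabolite_seed(self.random_state, self.stratum, nm)
            d = bootstrap_oob_auc(Xv[:, j], y, B=self.B,
                                  seed=ss.generate_state(1)[0])
            d.metabolite = nm
            dists.append(d)
        self.dists_ = dists
        self.support_ = np.array([rule.admits(d) for d in dists])
        self.signature_ = select_signature(dists, self.stratum, rule)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
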