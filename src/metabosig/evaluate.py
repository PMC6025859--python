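"""Bootstrap model evaluation, consistency tables, and signature algebra.

For each (stratum, model family, input set) the model is refit on B
bootstrap draws; the training AUC is measured on the draw and the test
AUC on the out-of-bag participants of the same draw.  The 2.5/50/97.5%
quantiles of the paired train/test AUC distributions summarize each
model, and the train - test differences — averaged as mean absolute
differences per quantile and over all quantiles and strata — rank the
families by classification consistency (overfit).  Metabolite selection
is NOT re-run inside the model bootstrap: selection has its own
bootstrap beforehand, and the model bootstrap conditions on the chosen
feature set (the optimism this induces is inherent to the sequential
design).

Single-score fits (one-component PCR/PLS, one-feature logistic) use an
exact shortcut: a logistic fit of a single score is strictly monotone
in that score, so train and test AUCs depend only on the score and the
sign of the fitted slope, which equals the sign of the training
covariance.  Multi-score fits run the full estimator per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .classifiers import ModelSpec, SignatureClassifier
from .select import QUANTILES, auc, BootstrapInstabilityError

__all__ = [
    "ModelBootstrapSummary",
    "bootstrap_model_auc",
    "select_components",
    "consistency_table",
    "consistency_arithmetic",
    "SignatureComparison",
    "signature_set_ops",
    "roc_band_export",
]


@dataclass
class ModelBootstrapSummary:
    """Paired train/test AUC distributions of one (stratum, model) run."""

    stratum: str
    spec: ModelSpec
    train_aucs: np.ndarray
    test_aucs: np.ndarray
    B: int
    seed: int | None = None
    n_discarded: int = 0
    roc_grid: np.ndarray | None = None
    roc_tprs: np.ndarray | None = None  # (n_valid, len(grid)) test-set TPRs

    @property
    def n_valid(self) -> int:
        return len(self.train_aucs)

    def train_quantile(self, q: float) -> float:
        return float(np.quantile(self.train_aucs, q, method="linear"))

    def test_quantile(self, q: float) -> float:
        return float(np.quantile(self.test_aucs, q, method="linear"))

    @property
    def train_quantiles(self) -> dict[float, float]:
        return {q: self.train_quantile(q) for q in QUANTILES}

    @property
    def test_quantiles(self) -> dict[float, float]:
        return {q: self.test_quantile(q) for q in QUANTILES}


def _first_pls_direction(Z: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """First NIPALS PLS1 weight vector: proportional to Z'(y - ybar)."""
    w = Z.T @ (yb - yb.mean())
    nrm = np.linalg.norm(w)
    return w if nrm == 0 else w / nrm


def _single_score(Z: np.ndarray, yb: np.ndarray, family: str) -> np.ndarray | None:
    """Projection direction of the single-component fast path."""
    if family == "pcr":
        # top right-singular vector of the centered/scaled matrix
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        return vt[0]
    if family == "pls":
        w = _first_pls_direction(Z, yb)
        if not np.any(w):
            return None
        return w
    return None


def bootstrap_model_auc(X, y, spec: ModelSpec, B: int = 1000,
                        seed: int | None = None, stratum: str = "all",
                        scale: bool = True, store_roc: bool = False,
                        roc_grid=None) -> ModelBootstrapSummary:
    """Bootstrap train/test AUC distribution of one model on fixed features.

    Per replicate: draw N with replacement, fit the model on the draw,
    record its training AUC on the draw and test AUC on the out-of-bag
    set.  Degenerate replicates (either set single-class) are discarded
    and counted.  Quantiles use the same linear-interpolation estimator
    as the univariate selection stage.  With ``store_roc`` the test-set
    ROC of each replicate is interpolated on ``roc_grid`` for band
    construction.
    """
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if y.dtype.kind in "OUS":  # group labels; OA is the positive class
        yb = (y == "OA").astype(float)
    else:
        yb = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    if store_roc:
        roc_grid = np.linspace(0, 1, 101) if roc_grid is None else np.asarray(roc_grid, float)
        if roc_grid.min() < 0 or roc_grid.max() > 1:
            raise ValueError("roc_grid must lie in [0, 1]")
    fast = (spec.family in ("pcr", "pls") and spec.n_components == 1) or \
           (spec.family == "logistic" and p == 1)

    train_aucs, test_aucs, tprs = [], [], []
    n_discarded = 0
    all_idx = np.arange(n)
    for _ in range(B):
        idx = rng.integers(n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[idx] = True
        oob = all_idx[~in_bag]
        y_tr, y_te = yb[idx], yb[oob]
        if len(oob) == 0 or y_tr.min() == y_tr.max() or y_te.min() == y_te.max():
            n_discarded += 1
            continue
        X_tr, X_te = X[idx], X[oob]
        if fast:
            center = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=1) if scale else np.ones(p)
            sd[sd == 0] = 1.0
            Z_tr = (X_tr - center) / sd
            Z_te = (X_te - center) / sd
            if spec.family == "logistic":
                s_tr, s_te = Z_tr[:, 0], Z_te[:, 0]
            else:
                v = _single_score(Z_tr, y_tr, spec.family)
                if v is None:
                    n_discarded += 1
                    continue
                s_tr, s_te = Z_tr @ v, Z_te @ v
            # logistic of a single score is monotone; slope sign = cov sign
            if np.sum(s_tr * (y_tr - y_tr.mean())) < 0:
                s_tr, s_te = -s_tr, -s_te
            a_tr, a_te = auc(s_tr, y_tr), auc(s_te, y_te)
        else:
            try:
                clf = SignatureClassifier(spec.family, spec.n_components,
                                          scale=scale).fit(X_tr, y_tr)
            except (ValueError, np.linalg.LinAlgError):
                n_discarded += 1
                continue
            s_tr = clf.decision_function(X_tr)
            s_te = clf.decision_function(X_te)
            a_tr, a_te = auc(s_tr, y_tr), auc(s_te, y_te)
        train_aucs.append(a_tr)
        test_aucs.append(a_te)
        if store_roc:
            fpr, tpr, _ = roc_curve(y_te, s_te)
            tprs.append(np.interp(roc_grid, fpr, tpr))
    if len(train_aucs) < 0.5 * B:
        raise BootstrapInstabilityError(
            f"only {len(train_aucs)} of {B} replicates valid")
    return ModelBootstrapSummary(
        stratum, spec, np.asarray(train_aucs), np.asarray(test_aucs), B, seed,
        n_discarded, roc_grid if store_roc else None,
        np.asarray(tprs) if store_roc else None)


def select_components(X, y, family: str, k_range, B: int = 1000,
                      seed: int | None = None, scale: bool = True) -> int:
    """Component count minimizing the mean train - test AUC gap.

    Runs the model bootstrap for each k in ``k_range`` (same seed, hence
    the same resample draws) and returns the k with the smallest
    ``|mean(train AUC) - mean(test AUC)|``; ties break toward smaller k.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    gaps = {}
    for k in sorted(k_range):
        s = bootstrap_model_auc(X, y, ModelSpec(family, k), B=B, seed=seed,
                                scale=scale)
        gaps[k] = abs(float(s.train_aucs.mean()) - float(s.test_aucs.mean()))
    return min(gaps, key=lambda k: (gaps[k], k))


# ---------------------------------------------------------------------------
# consistency (overfit) tables

def consistency_table(summaries: list[ModelBootstrapSummary]) -> pd.DataFrame:
    """Assemble the train/test/difference grid from bootstrap summaries.

    Rows: (model label, quantile); columns: per-stratum ``<s>_train``,
    ``<s>_test``, ``<s>_diff`` plus ``mad_quantile`` (mean |diff| across
    strata at that quantile) and ``mad_all`` (mean |diff| over all
    quantile x stratum cells of the model, repeated on each row).
    """
    strata: list[str] = []
    models: list[str] = []
    for s in summaries:
        if s.stratum not in strata:
            strata.append(s.stratum)
        if s.spec.label not in models:
            models.append(s.spec.label)
    by_key = {(s.spec.label, s.stratum): s for s in summaries}
    for m in models:
        missing = [st for st in strata if (m, st) not in by_key]
        if missing:
            raise ValueError(f"model {m!r} missing strata {missing}")
    rows = []
    for m in models:
        diffs = np.empty((len(QUANTILES), len(strata)))
        for qi, q in enumerate(QUANTILES):
            row: dict = {"model": m, "quantile": q}
            for si, st in enumerate(strata):
                s = by_key[(m, st)]
                tr, te = s.train_quantile(q), s.test_quantile(q)
                row[f"{st}_train"] = tr
                row[f"{st}_test"] = te
                row[f"{st}_diff"] = tr - te
                diffs[qi, si] = tr - te
            row["mad_quantile"] = float(np.abs(diffs[qi]).mean())
            rows.append(row)
        mad_all = float(np.abs(diffs).mean())
        for r in rows[-len(QUANTILES):]:
            r["mad_all"] = mad_all
    return pd.DataFrame(rows)


def consistency_arithmetic(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute difference and mean-absolute-difference columns.

    Takes a consistency grid (e.g. the packaged printed one) and
    recomputes every ``*_diff`` cell as train - test, ``mad_quantile``
    as the mean |diff| across strata per row, and ``mad_all`` as the
    mean |diff| over all rows of each model.  Used to verify internal
    arithmetic of a printed table against its own train/test columns.
    """
    out = table.copy()
    strata = sorted({c[:-6] for c in table.columns if c.endswith("_train")})
    for s in strata:
        out[f"{s}_diff"] = out[f"{s}_train"] - out[f"{s}_test"]
    diff_cols = [f"{s}_diff" for s in strata]
    out["mad_quantile"] = out[diff_cols].abs().mean(axis=1)
    out["mad_all"] = np.nan
    for _, g in out.groupby("model"):
        out.loc[g.index, "mad_all"] = float(g[diff_cols].abs().to_numpy().mean())
    return out


# ---------------------------------------------------------------------------
# signature set algebra

@dataclass
class SignatureComparison:
    """Named metabolite sets with unions/intersections/Venn counts."""

    sets: dict[str, frozenset] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    @property
    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for s in self.sets.values():
            out |= s
        return out

    @property
    def intersection(self) -> frozenset:
        vals = list(self.sets.values())
        out = vals[0]
        for s in vals[1:]:
            out &= s
        return out

    def difference(self, a: str, b: str) -> frozenset:
        return self.sets[a] - self.sets[b]

    def pairwise_counts(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.names, 2):
            rows.append({"a": a, "b": b,
                         "n_a": len(self.sets[a]), "n_b": len(self.sets[b]),
                         "n_intersection": len(self.sets[a] & self.sets[b]),
                         "n_union": len(self.sets[a] | self.sets[b])})
        return pd.DataFrame(rows)

    def venn_counts(self) -> dict[tuple[bool, ...], int]:
        """Exclusive Venn region sizes for 2 or 3 sets.

        Keys are membership tuples aligned with ``names``; e.g. for
        three sets ``(True, False, True)`` counts elements in the first
        and third sets only.
        """
        if not 2 <= len(self.sets) <= 3:
            raise ValueError("Venn regions defined for 2 or 3 sets")
        names = self.names
        regions: dict[tuple[bool, ...], int] = {}
        from itertools import product
        for mask in product([True, False], repeat=len(names)):
            if not any(mask):
                continue
            region = self.union
            for nm, inside in zip(names, mask):
                region = region & self.sets[nm] if inside else region - self.sets[nm]
            regions[mask] = len(region)
        return regions


def signature_set_ops(signatures: dict) -> SignatureComparison:
    """Set algebra over named signatures (Signature objects or iterables)."""
    sets = {}
    for name, sig in signatures.items():
        members = sig.metabolites if hasattr(sig, "metabolites") else sig
        sets[name] = frozenset(members)
    return SignatureComparison(sets)


# ---------------------------------------------------------------------------
# ROC bands

def roc_band_export(summary: ModelBootstrapSummary, grid=None) -> pd.DataFrame:
    """Vertically averaged test-set ROC with 95% bands.

    Requires the summary to have been produced with ``store_roc=True``.
    Returns columns ``fpr``, ``tpr_mean``, ``tpr_lo``, ``tpr_hi``
    (2.5/97.5% envelopes across replicates).
    """
    if summary.roc_tprs is None:
        raise ValueError("summary was computed without store_roc=True")
    tprs = summary.roc_tprs
    fpr = summary.roc_grid
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < 0 or grid.max() > 1:
            raise ValueError("grid must lie in [0, 1]")
        tprs = np.vstack([np.interp(grid, fpr, t) for t in tprs])
        fpr = grid
    return pd.DataFrame({
        "fpr": fpr,
        "tpr_mean": tprs.mean(axis=0),
        "tpr_lo": np.quantile(tprs, 0.025, axis=0),
        "tpr_hi": np.quantile(tprs, 0.975, axis=0),
    })
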