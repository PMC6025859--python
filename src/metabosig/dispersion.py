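"""Homogeneity of multivariate dispersions (PERMDISP2-style).

Each participant's dispersion is its Euclidean distance in metabolite
space to its own group centroid (arithmetic mean vector; a spatial-
median variant is available).  Group dispersions are compared with
Tukey's honestly-significant-difference test on the per-participant
distances — a one-way ANOVA layout with studentized-range adjustment
(Tukey-Kramer for unequal group sizes).  A label-permutation test of
the overall ANOVA F on distances is available but off by default, since
the pipeline's significance calls come from Tukey's HSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DispersionResult", "group_dispersion", "tukey_dispersion_test",
           "permdisp_f_test"]


class DegenerateGroupError(ValueError):
    pass


@dataclass
class DispersionResult:
    """Per-participant distances to own-group centroid, plus group means."""

    distances: np.ndarray
    labels: np.ndarray
    group_means: dict = field(default_factory=dict)

    @property
    def groups(self) -> list:
        return sorted(self.group_means)


def _spatial_median(X: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> np.ndarray:
    """Geometric median by Weiszfeld iteration."""
    m = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - m, axis=1)
        d = np.where(d < tol, tol, d)
        w = 1.0 / d
        m_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def group_dispersion(values, labels, center: str = "centroid") -> DispersionResult:
    """Distance of each participant to its group center.

    Parameters
    ----------
    values : (n, p) array or DataFrame
        Log-transformed metabolite matrix.
    labels : length-n sequence
        Group assignment (>= 2 groups, each with >= 2 members).
    center : {"centroid", "spatial-median"}
        Group center definition; the arithmetic-mean centroid is the
        default.
    """
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise DegenerateGroupError("need >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise DegenerateGroupError(f"groups of size 1: {small}")
    dist = np.empty(len(labels))
    means = {}
    for g in uniq:
        m = labels == g
        c = X[m].mean(axis=0) if center == "centroid" else _spatial_median(X[m])
        dist[m] = np.linalg.norm(X[m] - c, axis=1)
        means[g] = float(dist[m].mean())
    return DispersionResult(dist, labels, means)


def tukey_dispersion_test(result: DispersionResult) -> pd.DataFrame:
    """Tukey HSD on the per-participant distances.

    One-way ANOVA layout: within-group mean square from the distance
    values, studentized-range p-values per group pair (Tukey-Kramer
    standard error for unequal n).  With k=2 groups this reduces to the
    pooled-variance two-sample t-test.

    Returns a DataFrame with one row per group pair: ``group1``,
    ``group2``, ``mean_diff`` and ``p_adj``.
    """
    d, labels = result.distances, result.labels
    groups = result.groups
    k = len(groups)
    ns = {g: int((labels == g).sum()) for g in groups}
    n_tot = len(d)
    df_w = n_tot - k
    sse = sum(((d[labels == g] - result.group_means[g]) ** 2).sum() for g in groups)
    if sse <= 0:
        raise ZeroDivisionError("zero within-group variance of distances")
    mse = sse / df_w
    rows = []
    for g1, g2 in combinations(groups, 2):
        diff = result.group_means[g2] - result.group_means[g1]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append({"group1": g1, "group2": g2,
                     "mean_diff": float(diff), "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


def permdisp_f_test(values, labels, n_permutations: int = 999,
                    seed: int | None = None) -> float:
    """Permutation p-value for the overall dispersion ANOVA F (optional)."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)

    def f_stat(lab):
        res = group_dispersion(values, lab)
        d = res.distances
        grand = d.mean()
        groups = res.groups
        ssb = sum((lab == g).sum() * (res.group_means[g] - grand) ** 2 for g in groups)
        ssw = sum(((d[lab == g] - res.group_means[g]) ** 2).sum() for g in groups)
        k = len(groups)
        return (ssb / (k - 1)) / (ssw / (len(d) - k))

    f_obs = f_stat(labels)
    hits = sum(f_stat(rng.permutation(labels)) >= f_obs for _ in range(n_permutations))
    return (1 + hits) / (1 + n_permutations)
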