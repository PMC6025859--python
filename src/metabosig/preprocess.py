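"""Batch adjustment, log(x+1) transform, and stratification.

Order of operations in the pipeline: batch adjust on the natural
concentration scale, then log(x+1), then demographic stratification.
The default batch adjustment rescales each batch multiplicatively so
its within-batch median matches the all-cohort median per metabolite
(scale-based, robust, positivity-preserving); a log-scale mean-centering
alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, StratumSpec

__all__ = ["TransformedMatrix", "adjust_batch", "log1p_transform", "stratify"]


class BatchAdjustmentError(ValueError):
    pass


@dataclass
class TransformedMatrix:
    """Participants x metabolites matrix on the log(x+1) scale."""

    values: pd.DataFrame
    batch_adjusted: bool = False
    log_transformed: bool = True


def adjust_batch(cohort: CohortTable, method: str = "median-ratio") -> CohortTable:
    """Remove additive (log-scale) batch shifts from the concentrations.

    ``median-ratio`` (default): each batch's values for a metabolite are
    multiplied by (global median / batch median), so all per-batch
    medians coincide afterwards.  ``log-center``: log(x+1) values are
    mean-centered per batch (global mean restored), then mapped back
    with expm1 and clipped at zero.

    Single-batch cohorts are returned unchanged.  A batch whose values
    are all zero for some metabolite has no defined scale and raises
    :class:`BatchAdjustmentError`.
    """
    batches = cohort.data["batch"]
    if batches.nunique() <= 1:
        return cohort
    if (batches.value_counts() < 2).any():
        raise BatchAdjustmentError("every batch needs >= 2 participants")
    conc = cohort.concentrations.astype(float)

    if method == "median-ratio":
        global_med = conc.median(axis=0)
        adj = conc.copy()
        for b, idx in conc.groupby(batches).groups.items():
            bmed = conc.loc[idx].median(axis=0)
            if (bmed == 0).any():
                bad = bmed.index[bmed == 0].tolist()
                raise BatchAdjustmentError(
                    f"batch {b!r} has all-zero concentrations for {bad}")
            adj.loc[idx] = conc.loc[idx] * (global_med / bmed)
    elif method == "log-center":
        logv = np.log1p(conc)
        global_mean = logv.mean(axis=0)
        adj_log = logv.copy()
        for _, idx in logv.groupby(batches).groups.items():
            adj_log.loc[idx] = logv.loc[idx] - logv.loc[idx].mean(axis=0) + global_mean
        adj = np.expm1(adj_log).clip(lower=0.0)
    else:
        raise ValueError(f"unknown batch adjustment method {method!r}")
    return cohort.with_concentrations(adj)


def log1p_transform(cohort: CohortTable) -> TransformedMatrix:
    """Natural log(x+1) of every concentration.

    Monotone and order-preserving per column, so univariate AUCs are
    invariant under this transform.
    """
    conc = cohort.concentrations.to_numpy(dtype=float)
    if (conc < 0).any():
        raise ValueError("negative concentrations")
    values = pd.DataFrame(np.log1p(conc), columns=cohort.metabolites,
                          index=cohort.data.index)
    return TransformedMatrix(values, log_transformed=True)


def stratify(cohort: CohortTable, spec: StratumSpec) -> CohortTable:
    """Participants satisfying all of the stratum's rules (conjunctive).

    Boundaries exactly as in the study design: age > 50 strict,
    BMI >= 30 inclusive.  An empty result warns but is returned.
    """
    return spec.apply(cohort)
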