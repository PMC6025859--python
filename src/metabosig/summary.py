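"""Demographic comparison statistics and diabetes-sensitivity utilities.

Sex-ratio comparisons between cases and controls use the 2x2 chi-square
test with Yates continuity correction (|O - E| shrunk by up to 0.5);
continuous demographics (age, BMI) use Welch's unequal-variance t-test,
either from raw values or from printed summary moments.  The diabetes
sensitivity check flags signature metabolites whose transformed levels
differ between diabetic and non-diabetic participants within either
group, and returns the signature with those metabolites removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, StratumSpec, TABLE1_STRATA
from .preprocess import log1p_transform
from .select import Signature

__all__ = ["sex_ratio_chisq", "welch_t_from_summary", "demographics_table",
           "dm_sensitivity"]


def sex_ratio_chisq(n_oa_male: int, n_oa_female: int,
                    n_hv_male: int, n_hv_female: int,
                    correction: bool = True) -> float:
    """P-value of the 2x2 chi-square test of sex ratio, OA vs HV.

    Yates continuity correction is applied by default (it reproduces the
    printed cohort p-values from the printed counts); pass
    ``correction=False`` for the uncorrected statistic.
    """
    table = np.array([[n_oa_male, n_oa_female], [n_hv_male, n_hv_female]])
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ZeroDivisionError("zero marginal total; test undefined")
    return float(stats.chi2_contingency(table, correction=correction)[1])


def welch_t_from_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int) -> float:
    """Two-sided Welch t-test p-value from summary moments.

    Satterthwaite degrees of freedom; suitable for recomputing group
    comparisons from printed means/SDs (bound-level only, since printed
    moments are rounded).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=False)
    return float(res.pvalue)


def demographics_table(cohort: CohortTable,
                       strata: dict[str, StratumSpec] | None = None) -> pd.DataFrame:
    """Stratum-by-stratum demographic summary with OA-vs-HV p-values.

    One row per stratum: counts (total, OA, HV, females and female
    split), the Yates chi-square p for the sex ratio, age and BMI
    mean +/- SD per group with Welch p-values.  Sex-specific strata
    leave the female columns and sex p blank, mirroring the printed
    layout.
    """
    strata = strata or TABLE1_STRATA
    rows = []
    for key, spec in strata.items():
        sub = spec.apply(cohort).data
        oa = sub[sub["group"] == "OA"]
        hv = sub[sub["group"] == "HV"]
        row: dict = {"stratum": key, "total": len(sub),
                     "oa": len(oa), "hv": len(hv)}
        if spec.sex_rule == "all":
            fem = sub[sub["sex"] == "female"]
            row["females"] = len(fem)
            row["females_oa"] = int((fem["group"] == "OA").sum())
            row["females_hv"] = int((fem["group"] == "HV").sum())
            row["p_sex"] = sex_ratio_chisq(
                len(oa) - row["females_oa"], row["females_oa"],
                len(hv) - row["females_hv"], row["females_hv"])
        else:
            row["females"] = row["females_oa"] = row["females_hv"] = np.nan
            row["p_sex"] = np.nan
        for var in ("age", "bmi"):
            row[f"{var}_mean"] = sub[var].mean()
            row[f"{var}_sd"] = sub[var].std(ddof=1)
            row[f"{var}_oa_mean"] = oa[var].mean()
            row[f"{var}_oa_sd"] = oa[var].std(ddof=1)
            row[f"{var}_hv_mean"] = hv[var].mean()
            row[f"{var}_hv_sd"] = hv[var].std(ddof=1)
            row[f"p_{var}"] = float(
                stats.ttest_ind(oa[var], hv[var], equal_var=False).pvalue)
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


@dataclass
class DMSensitivityResult:
    """Flagged metabolites, reduced signature, and the per-test p-values.

    Iterable as ``(flagged, reduced)`` for convenience.
    """

    flagged: list[str]
    reduced: Signature
    pvalues: pd.DataFrame  # columns: metabolite, group, p

    def __iter__(self):
        return iter((self.flagged, self.reduced))


def dm_sensitivity(cohort: CohortTable, signature: Signature,
                   alpha: float = 0.05) -> DMSensitivityResult:
    """Diabetes-mellitus sensitivity: flag and drop DM-associated members.

    Within OA and HV separately, each metabolite's log(x+1) values are
    compared between DM and non-DM participants by a two-sided Welch
    t-test; metabolites with p < alpha in either group that belong to
    the signature are flagged, and the reduced signature drops them —
    the caller re-runs the model bootstrap on the reduced set.
    Metabolites whose DM or non-DM group has < 2 members in both groups
    are skipped with a warning.
    """
    if "dm_status" not in cohort.data.columns:
        raise ValueError("cohort has no dm_status column")
    values = log1p_transform(cohort).values
    dm = cohort.data["dm_status"]
    flagged = []
    prows = []
    for metab in signature.metabolites:
        significant = False
        skipped = True
        for g in ("OA", "HV"):
            gm = (cohort.data["group"] == g).to_numpy()
            a = values.loc[gm & (dm == "yes").to_numpy(), metab]
            b = values.loc[gm & (dm == "no").to_numpy(), metab]
            if len(a) < 2 or len(b) < 2:
                continue
            skipped = False
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            prows.append({"metabolite": metab, "group": g, "p": p})
            if p < alpha:
                significant = True
        if skipped:
            warnings.warn(f"{metab}: DM group too small in both groups; skipped")
            continue
        if significant:
            flagged.append(metab)
    return DMSensitivityResult(flagged, signature.without(flagged),
                               pd.DataFrame(prows, columns=["metabolite", "group", "p"]))
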