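"""Cohort container, demographic strata, and CSV round-trip.

A cohort is one row per participant: demographics (case/control group,
age, sex, BMI, measurement batch, optional diabetes-mellitus status)
plus per-metabolite plasma concentrations in the panel's µM scale.
``OA`` (osteoarthritis, the case class) and ``HV`` (healthy volunteer,
the control class) are the only group labels; OA is always the positive
class for AUC computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nomenclature import classify_metabolite_name, MetaboliteNameError

__all__ = [
    "CohortTable",
    "StratumSpec",
    "TABLE1_STRATA",
    "read_cohort_csv",
    "write_cohort_csv",
]

DEMOGRAPHIC_COLUMNS = ["subject_id", "group", "age", "sex", "bmi", "batch"]
OPTIONAL_COLUMNS = ["dm_status"]
GROUPS = ("OA", "HV")
SEXES = ("male", "female")
DM_LEVELS = ("yes", "no", "unknown")


class CohortSchemaError(ValueError):
    """A mandatory demographic column is missing."""


class CohortValidationError(ValueError):
    """Row values violate the cohort invariants."""


@dataclass
class CohortTable:
    """Participants x (demographics + metabolite concentrations).

    ``data`` holds one row per participant with the demographic columns
    first and one column per metabolite (canonical compact names);
    ``metabolites`` is the ordered list of metabolite column names.
    Concentrations are non-negative reals on the natural (pre-transform)
    scale.
    """

    data: pd.DataFrame
    metabolites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
        if missing:
            raise CohortSchemaError(f"missing mandatory columns: {missing}")
        if not self.metabolites:
            candidates = [
                c
                for c in df.columns
                if c not in DEMOGRAPHIC_COLUMNS and c not in OPTIONAL_COLUMNS
            ]
            self.metabolites = [classify_metabolite_name(c).canonical for c in candidates]
            df = df.rename(columns=dict(zip(candidates, self.metabolites)))
        self._validate(df)
        # normalize vocabularies
        df = df.copy()
        df["group"] = df["group"].str.upper()
        df["sex"] = df["sex"].str.lower()
        if "dm_status" in df.columns:
            df["dm_status"] = df["dm_status"].fillna("unknown").str.lower()
        self.data = df.reset_index(drop=True)

    def _validate(self, df: pd.DataFrame) -> None:
        if not df["group"].str.upper().isin(GROUPS).all():
            bad = sorted(set(df["group"]) - set(GROUPS))
            raise CohortValidationError(f"group labels outside {GROUPS}: {bad}")
        if not df["sex"].str.lower().isin(SEXES).all():
            raise CohortValidationError(f"sex values outside {SEXES}")
        conc = df[self.metabolites]
        if conc.isna().any().any():
            raise CohortValidationError("missing concentration values are not supported")
        if (conc.to_numpy(dtype=float) < 0).any():
            raise CohortValidationError("negative concentrations")
        if (df["age"] <= 0).any() or (df["bmi"] <= 0).any():
            raise CohortValidationError("age and bmi must be positive")

    # -- convenience accessors -------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    @property
    def y(self) -> np.ndarray:
        """Binary labels, OA (case) = 1, HV (control) = 0."""
        return (self.data["group"] == "OA").to_numpy(dtype=int)

    @property
    def concentrations(self) -> pd.DataFrame:
        return self.data[self.metabolites]

    def with_concentrations(self, conc: pd.DataFrame) -> "CohortTable":
        """Return a copy with the metabolite columns replaced."""
        df = self.data.copy()
        df[self.metabolites] = conc[self.metabolites].to_numpy()
        return CohortTable(df, list(self.metabolites))

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(self.data.loc[np.asarray(mask)].reset_index(drop=True),
                           list(self.metabolites))


@dataclass(frozen=True)
class StratumSpec:
    """A demographic stratum: conjunctive age / BMI / sex rules.

    Boundary semantics follow the study design exactly: the age split is
    strictly greater than 50 (a 50-year-old belongs to the <=50 stratum)
    and the obesity split is BMI >= 30 inclusive.
    """

    name: str
    age_rule: str = "all"     # {"all", ">50", "<=50"}
    bmi_rule: str = "all"     # {"all", ">=30", "<30"}
    sex_rule: str = "all"     # {"all", "male", "female"}

    def __post_init__(self) -> None:
        if self.age_rule not in ("all", ">50", "<=50"):
            raise ValueError(f"bad age_rule {self.age_rule!r}")
        if self.bmi_rule not in ("all", ">=30", "<30"):
            raise ValueError(f"bad bmi_rule {self.bmi_rule!r}")
        if self.sex_rule not in ("all", "male", "female"):
            raise ValueError(f"bad sex_rule {self.sex_rule!r}")

    def mask(self, data: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(data), dtype=bool)
        if self.age_rule == ">50":
            m &= data["age"].to_numpy() > 50
        elif self.age_rule == "<=50":
            m &= data["age"].to_numpy() <= 50
        if self.bmi_rule == ">=30":
            m &= data["bmi"].to_numpy() >= 30
        elif self.bmi_rule == "<30":
            m &= data["bmi"].to_numpy() < 30
        if self.sex_rule != "all":
            m &= (data["sex"] == self.sex_rule).to_numpy()
        return m

    def apply(self, cohort: CohortTable) -> CohortTable:
        m = self.mask(cohort.data)
        if not m.any():
            warnings.warn(f"stratum {self.name!r} selected no participants")
        return cohort.subset(m)


#: The ten demographic strata of the study design, keyed by machine name.
TABLE1_STRATA: dict[str, StratumSpec] = {
    "all": StratumSpec("all"),
    "males": StratumSpec("males", sex_rule="male"),
    "females": StratumSpec("females", sex_rule="female"),
    "bmi_ge_30": StratumSpec("bmi_ge_30", bmi_rule=">=30"),
    "bmi_lt_30": StratumSpec("bmi_lt_30", bmi_rule="<30"),
    "age_gt_50": StratumSpec("age_gt_50", age_rule=">50"),
    "males_age_gt_50": StratumSpec("males_age_gt_50", age_rule=">50", sex_rule="male"),
    "females_age_gt_50": StratumSpec("females_age_gt_50", age_rule=">50", sex_rule="female"),
    "age_gt_50_bmi_ge_30": StratumSpec("age_gt_50_bmi_ge_30", age_rule=">50", bmi_rule=">=30"),
    "age_gt_50_bmi_lt_30": StratumSpec("age_gt_50_bmi_lt_30", age_rule=">50", bmi_rule="<30"),
}

#: The six strata that carried a signature into multivariate modeling.
MODELED_STRATA = [
    "all",
    "age_gt_50",
    "males",
    "males_age_gt_50",
    "age_gt_50_bmi_ge_30",
    "age_gt_50_bmi_lt_30",
]


def read_cohort_csv(path, schema: dict[str, str] | None = None) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row: the demographic columns (``subject_id``,
        ``group``, ``age``, ``sex``, ``bmi``, ``batch``, optionally
        ``dm_status``) followed by one column per metabolite.
    schema : dict, optional
        Maps canonical column names to the names used in the file, e.g.
        ``{"group": "diagnosis"}``.

    Every non-demographic column must parse as a panel metabolite name
    (either dialect); names are normalized to the compact form.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "batch": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory columns: {missing}")
    metab_cols = [c for c in df.columns
                  if c not in DEMOGRAPHIC_COLUMNS and c not in OPTIONAL_COLUMNS]
    if not metab_cols:
        raise CohortSchemaError("no metabolite columns found")
    try:
        canonical = [classify_metabolite_name(c).canonical for c in metab_cols]
    except MetaboliteNameError as exc:
        raise MetaboliteNameError(f"non-metabolite data column: {exc}") from exc
    df = df.rename(columns=dict(zip(metab_cols, canonical)))
    return CohortTable(df, canonical)


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV (demographics first, then metabolites)."""
    cols = [c for c in DEMOGRAPHIC_COLUMNS if c in cohort.data.columns]
    cols += [c for c in OPTIONAL_COLUMNS if c in cohort.data.columns]
    cols += cohort.metabolites
    cohort.data[cols].to_csv(path, index=False)
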