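"""Synthetic case-control cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: exact demographic cell counts, truncated-normal age and BMI
within demographic bands, log-normal metabolite concentrations with
block-exchangeable within-lipid-class correlation, per-metabolite case
shifts calibrated to a target univariate AUC, and optional additive
(log-scale) batch effects.

Effect calibration uses the binormal equal-variance identity

    AUC = Phi(d / sqrt(2)),    d = sqrt(2) * Phi^{-1}(AUC),

where ``d`` is the standardized case-control mean difference on the log
scale.  Because the downstream log(x+1) transform is monotone, the
univariate AUC of the simulated natural-scale concentration equals the
AUC of its log, so the calibration is exact regardless of the
within-class correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortTable
from .fixtures_io import load_fixture
from .nomenclature import MetaboliteInfo, classify_metabolite_name

__all__ = [
    "SubjectBlock",
    "SimulationConfig",
    "auc_to_effect",
    "effect_to_auc",
    "simulate_cohort",
    "default_study_config",
    "two_group_config",
]


def auc_to_effect(auc: float) -> float:
    """Standardized mean difference d such that Phi(d/sqrt(2)) = AUC.

    Domain is 0.5 <= auc < 1; d >= 0 and strictly increasing in auc.
    """
    if not 0.5 <= auc < 1.0:
        raise ValueError(f"target AUC must be in [0.5, 1), got {auc}")
    return math.sqrt(2.0) * stats.norm.ppf(auc)


def effect_to_auc(d: float) -> float:
    """Inverse of :func:`auc_to_effect`."""
    if d < 0:
        raise ValueError("effect size must be >= 0")
    return float(stats.norm.cdf(d / math.sqrt(2.0)))


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose (lo, hi)-truncated normal mean is target_mean."""
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} outside truncation ({lo}, {hi})")

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    span = 12 * sd
    return optimize.brentq(lambda m: trunc_mean(m) - target_mean,
                           target_mean - span, target_mean + span, xtol=1e-8)


@dataclass(frozen=True)
class SubjectBlock:
    """A homogeneous demographic cell: n subjects of one group and sex.

    ``age_mean``/``bmi_mean`` are the *target* means of the truncated
    normal draws inside (``age_lo``, ``age_hi``) / (``bmi_lo``,
    ``bmi_hi``); the location parameter is solved so the truncated mean
    matches the target.  ``effect_multiplier`` scales every metabolite's
    standardized case shift for subjects in this cell, which is how
    signal is concentrated in a demographic subgroup (e.g. older males).
    """

    n: int
    group: str
    sex: str
    age_mean: float
    age_sd: float
    age_lo: float
    age_hi: float
    bmi_mean: float
    bmi_sd: float
    bmi_lo: float
    bmi_hi: float
    effect_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("block n must be >= 0")
        if self.group not in ("OA", "HV"):
            raise ValueError(f"bad group {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"bad sex {self.sex!r}")


@dataclass
class SimulationConfig:
    """Everything :func:`simulate_cohort` needs; deterministic given seed."""

    seed: int
    blocks: list[SubjectBlock]
    panel: list[MetaboliteInfo]
    effects: dict[str, float] = field(default_factory=dict)  # metabolite -> target AUC
    rho_within_class: float = 0.5
    n_batches: int = 1
    batch_sd: float = 0.0
    base_log_mean: float = 4.0
    base_log_sd: float = 0.4

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one subject block required")
        if not self.panel:
            raise ValueError("panel must be non-empty")
        if not 0.0 <= self.rho_within_class < 1.0:
            raise ValueError("rho_within_class must be in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        names = {m.canonical for m in self.panel}
        for k, v in self.effects.items():
            if k not in names:
                raise ValueError(f"effect for metabolite {k!r} not in panel")
            if not 0.5 <= v < 1.0:
                raise ValueError(f"target AUC for {k!r} must be in [0.5, 1)")

    @property
    def metabolite_names(self) -> list[str]:
        return [m.canonical for m in self.panel]


def _class_blocks_correlation(panel: list[MetaboliteInfo], rho: float) -> np.ndarray:
    """Block-exchangeable correlation: rho within lipid class, 0 across."""
    classes = np.array([m.lipid_class for m in panel])
    same = classes[:, None] == classes[None, :]
    R = np.where(same, rho, 0.0)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw one synthetic cohort. Deterministic given ``config.seed``.

    Demographic counts match the block definitions exactly; ages and
    BMIs are truncated normals honoring each block's band; log
    concentrations are multivariate normal with the configured
    correlation, case blocks shifted by
    ``auc_to_effect(target) * effect_multiplier`` standard deviations,
    plus per-(batch, metabolite) additive shifts; natural-scale
    concentrations are obtained by exponentiation (hence positive).
    """
    rng = np.random.default_rng(config.seed)
    names = config.metabolite_names
    M = len(names)

    rows = []
    mult = []
    for b in config.blocks:
        if b.n == 0:
            continue
        age_loc = _truncnorm_loc(b.age_mean, b.age_sd, b.age_lo, b.age_hi)
        bmi_loc = _truncnorm_loc(b.bmi_mean, b.bmi_sd, b.bmi_lo, b.bmi_hi)
        a_lo, a_hi = (b.age_lo - age_loc) / b.age_sd, (b.age_hi - age_loc) / b.age_sd
        m_lo, m_hi = (b.bmi_lo - bmi_loc) / b.bmi_sd, (b.bmi_hi - bmi_loc) / b.bmi_sd
        ages = stats.truncnorm.rvs(a_lo, a_hi, loc=age_loc, scale=b.age_sd,
                                   size=b.n, random_state=rng)
        bmis = stats.truncnorm.rvs(m_lo, m_hi, loc=bmi_loc, scale=b.bmi_sd,
                                   size=b.n, random_state=rng)
        for j in range(b.n):
            rows.append({"group": b.group, "sex": b.sex,
                         "age": ages[j], "bmi": bmis[j]})
            mult.append(b.effect_multiplier)
    n = len(rows)
    demo = pd.DataFrame(rows)
    demo["subject_id"] = [f"S{i:04d}" for i in range(n)]
    demo["batch"] = [f"B{k}" for k in rng.integers(config.n_batches, size=n)]
    mult = np.asarray(mult)

    R = _class_blocks_correlation(config.panel, config.rho_within_class)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, M)) @ L.T

    d = np.array([auc_to_effect(config.effects.get(nm, 0.5)) for nm in names])
    case = (demo["group"] == "OA").to_numpy(dtype=float)
    shift = case[:, None] * mult[:, None] * d[None, :]  # in SD units

    batch_shift = rng.normal(0.0, config.batch_sd, size=(config.n_batches, M)) \
        if config.batch_sd > 0 else np.zeros((config.n_batches, M))
    batch_idx = demo["batch"].str.lstrip("B").astype(int).to_numpy()

    log_conc = (config.base_log_mean
                + config.base_log_sd * (z + shift)
                + batch_shift[batch_idx])
    conc = pd.DataFrame(np.exp(log_conc), columns=names)

    df = pd.concat([demo[["subject_id", "group", "age", "sex", "bmi", "batch"]],
                    conc], axis=1)
    return CohortTable(df, names)


def default_panel() -> list[MetaboliteInfo]:
    """The 39 lysoPC/PCaa/PCae metabolites of the published signatures."""
    t2 = load_fixture("table2")
    return [classify_metabolite_name(nm) for nm in t2.index]


# Age/BMI moments for cells not printed directly are derived by moment
# subtraction from the printed stratum rows (e.g. the age<=50 HV mean
# follows from the All and Age>50 HV rows); SDs for derived cells are
# round choices of plausible magnitude.
_AGE_PARAMS = {  # (group, age_band) -> (target mean, sd, lo, hi)
    ("OA", "gt50"): (64.4, 6.7, 50.0, 95.0),
    ("HV", "gt50"): (59.9, 6.2, 50.0, 95.0),
    ("OA", "le50"): (41.6, 7.0, 18.0, 50.0),
    ("HV", "le50"): (39.0, 7.0, 18.0, 50.0),
}
_BMI_PARAMS = {  # (group, age_band, bmi_band) -> (target mean, sd, lo, hi)
    ("OA", "gt50", "ge30"): (35.0, 5.0, 30.0, 60.0),
    ("OA", "gt50", "lt30"): (27.4, 2.3, 15.0, 30.0),
    ("OA", "le50", "lt30"): (27.4, 2.4, 15.0, 30.0),
    ("HV", "gt50", "ge30"): (32.2, 2.1, 30.0, 60.0),
    ("HV", "le50", "ge30"): (33.8, 2.7, 30.0, 60.0),
    ("HV", "gt50", "lt30"): (26.4, 2.8, 15.0, 30.0),
    ("HV", "le50", "lt30"): (24.0, 3.3, 15.0, 30.0),
}

# Joint (group, sex, age band, BMI band) cell counts. These are fully
# determined by the printed stratum marginals (totals, sex counts, the
# age>50 rows and the BMI-stratified rows) and sum to 346.
_CELL_COUNTS = {
    # (group, sex, age_band, bmi_band): n
    ("OA", "male", "gt50", "ge30"): 42,
    ("OA", "male", "gt50", "lt30"): 30,
    ("OA", "male", "le50", "lt30"): 3,
    ("OA", "female", "gt50", "ge30"): 47,
    ("OA", "female", "gt50", "lt30"): 29,
    ("OA", "female", "le50", "lt30"): 1,
    ("HV", "male", "gt50", "ge30"): 19,
    ("HV", "male", "gt50", "lt30"): 31,
    ("HV", "male", "le50", "ge30"): 13,
    ("HV", "male", "le50", "lt30"): 21,
    ("HV", "female", "gt50", "ge30"): 23,
    ("HV", "female", "gt50", "lt30"): 29,
    ("HV", "female", "le50", "ge30"): 28,
    ("HV", "female", "le50", "lt30"): 30,
}


def default_study_config(seed: int = 0, *, effects: dict[str, float] | None = None,
                         subgroup_multipliers: dict[tuple[str, str], float] | None = None,
                         rho_within_class: float = 0.5,
                         n_batches: int = 1, batch_sd: float = 0.0) -> SimulationConfig:
    """Study-shaped cohort: 346 participants matching the demographic table.

    Counts per (group, sex, age band, BMI band) cell reproduce the
    published stratum sizes exactly (346 total; 152 OA / 194 HV; 250
    over age 50; 122 males over 50; ...).  ``effects`` maps metabolite
    names to target univariate AUCs (default: 0.5 everywhere, i.e. a
    null cohort).  ``subgroup_multipliers`` maps ``(sex, age_band)``
    with age_band in {"gt50", "le50"} to a multiplier on the
    standardized case shift, used to concentrate signal in a subgroup,
    e.g. ``{("male", "gt50"): 1.0, ("female", "gt50"): 0.3}``.
    """
    blocks = []
    for (group, sex, ab, bb), cnt in _CELL_COUNTS.items():
        am, asd, alo, ahi = _AGE_PARAMS[(group, ab)]
        bm, bsd, blo, bhi = _BMI_PARAMS[(group, ab, bb)]
        m = 1.0 if subgroup_multipliers is None else subgroup_multipliers.get((sex, ab), 1.0)
        blocks.append(SubjectBlock(cnt, group, sex, am, asd, alo, ahi,
                                   bm, bsd, blo, bhi, effect_multiplier=m))
    return SimulationConfig(seed=seed, blocks=blocks, panel=default_panel(),
                            effects=effects or {},
                            rho_within_class=rho_within_class,
                            n_batches=n_batches, batch_sd=batch_sd)


def two_group_config(n_case: int, n_control: int, panel: list[MetaboliteInfo],
                     seed: int = 0, **kwargs) -> SimulationConfig:
    """Minimal config: one case and one control block, flat demographics."""
    mk = lambda n, g: SubjectBlock(n, g, "male", 60.0, 8.0, 30.0, 90.0,
                                   28.0, 4.0, 15.0, 55.0)
    return SimulationConfig(seed=seed, blocks=[mk(n_case, "OA"), mk(n_control, "HV")],
                            panel=panel, **kwargs)
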