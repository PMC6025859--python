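"""End-to-end orchestration of the stepwise workflow.

preprocess (batch adjust + log(x+1)) -> dispersion homogeneity checks ->
per-stratum bootstrap univariate selection -> per-stratum model
bootstrap and consistency table -> signature set algebra -> report
files.  All randomness flows from one master seed through stable
per-stage derivations, so stages re-run independently with identical
results.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, TABLE1_STRATA, MODELED_STRATA, read_cohort_csv
from .classifiers import ModelSpec, aggregate_by_class
from .dispersion import group_dispersion, tukey_dispersion_test
from .evaluate import (bootstrap_model_auc, consistency_table, roc_band_export,
                       signature_set_ops)
from .preprocess import adjust_batch, log1p_transform, stratify
from .select import BootstrapAUCSelector
from .summary import demographics_table

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; ``seed`` is mandatory for every bootstrap."""

    seed: int
    input_csv: str | None = None
    simulate: dict | None = None        # kwargs for default_study_config
    strata: list[str] = field(default_factory=lambda: list(MODELED_STRATA))
    B: int = 1000
    families: list[str] = field(default_factory=lambda: ["pcr", "pls", "logistic"])
    n_components: int = 1
    batch_method: str = "median-ratio"
    selection_quantile: float = 0.025
    selection_threshold: float = 0.5
    out_dir: str = "metabosig_run"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if self.input_csv is None and self.simulate is None:
            raise ValueError("provide input_csv or a simulate block")
        unknown = set(self.strata) - set(TABLE1_STRATA)
        if unknown:
            raise ValueError(f"unknown strata: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _jsonable(obj):
    """Recursively coerce manifest content to JSON-safe types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [master, zlib.crc32(stage.encode())]).generate_state(1)[0])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write report files to ``out_dir``.

    Outputs: demographics.tsv, dispersion.tsv, signature_<stratum>.tsv,
    signatures.tsv (signature-shaped grid of median OOB AUCs),
    consistency.tsv, roc_<stratum>.csv (one-component PCR bands),
    venn.json and manifest.json.  Returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "B": config.B, "stages": {}}

    if config.input_csv:
        cohort = read_cohort_csv(config.input_csv)
    else:
        from .simulate import default_study_config, simulate_cohort
        sim = dict(config.simulate or {})
        sim.setdefault("seed", _stage_seed(config.seed, "simulate"))
        cohort = simulate_cohort(default_study_config(**sim))
        manifest["stages"]["simulate"] = {"seed": sim["seed"], "n": cohort.n}

    cohort = adjust_batch(cohort, method=config.batch_method)
    demographics_table(cohort).to_csv(out / "demographics.tsv", sep="\t")

    matrix = log1p_transform(cohort)
    age_band = np.where(cohort.data["age"] > 50, "age_gt_50", "age_le_50")
    disp_labels = np.char.add(np.asarray(age_band, dtype=str),
                              np.char.add("/", cohort.groups.to_numpy(dtype=str)))
    disp = tukey_dispersion_test(group_dispersion(matrix.values, disp_labels))
    disp.to_csv(out / "dispersion.tsv", sep="\t", index=False)

    signatures = {}
    sig_grid = {}
    discarded: dict[str, int] = {}
    for key in config.strata:
        sub = stratify(cohort, TABLE1_STRATA[key])
        X = log1p_transform(sub).values
        sel = BootstrapAUCSelector(
            B=config.B, quantile=config.selection_quantile,
            threshold=config.selection_threshold, stratum=key,
            random_state=_stage_seed(config.seed, "select")).fit(X, sub.y)
        sig = sel.signature_
        signatures[key] = sig
        sig.entries.to_csv(out / f"signature_{key}.tsv", sep="\t", index=False)
        sig_grid[key] = dict(zip(sig.entries["metabolite"], sig.entries["q50"]))
        discarded[key] = int(sum(d.n_discarded for d in sel.dists_))
    pd.DataFrame(sig_grid).to_csv(out / "signatures.tsv", sep="\t")
    manifest["stages"]["select"] = {"seed": _stage_seed(config.seed, "select"),
                                    "discarded_replicates": discarded}

    summaries = []
    model_discard: dict[str, int] = {}
    for key in config.strata:
        sig = signatures[key]
        if len(sig) == 0:
            continue
        sub = stratify(cohort, TABLE1_STRATA[key])
        y = sub.y
        X_sig = log1p_transform(sub).values[sig.metabolites]
        X_agg = aggregate_by_class(sub)
        for family in config.families:
            for inputs, X in (("signature", X_sig), ("aggregate", X_agg)):
                spec = ModelSpec(family, config.n_components, inputs)
                seed = _stage_seed(config.seed, f"model/{key}/{spec.label}")
                store = family == "pcr" and inputs == "signature"
                s = bootstrap_model_auc(X, y, spec, B=config.B, seed=seed,
                                        stratum=key, store_roc=store)
                summaries.append(s)
                model_discard[f"{key}/{spec.label}"] = s.n_discarded
                if store:
                    roc_band_export(s).to_csv(out / f"roc_{key}.csv", index=False)
    if summaries:
        consistency_table(summaries).to_csv(out / "consistency.tsv",
                                            sep="\t", index=False)
    manifest["stages"]["model"] = {"discarded_replicates": model_discard}

    nonempty = {k: v for k, v in signatures.items() if len(v)}
    if len(nonempty) >= 2:
        comp = signature_set_ops(dict(list(nonempty.items())[:3]))
        venn = {"sets": {k: sorted(v) for k, v in comp.sets.items()},
                "regions": {"".join("1" if b else "0" for b in k): v
                            for k, v in comp.venn_counts().items()}}
        (out / "venn.json").write_text(json.dumps(venn, indent=2))

    manifest["config"] = asdict(config)
    (out / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=2, default=str))
    return manifest
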