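"""End-to-end orchestration: simulate -> score -> diagnose -> tree ->
impute -> rescore -> contrast.

Reproduces the shape of a full missing-data workup for a multi-site
physical-literacy study on synthetic data: generate a complete cohort,
inject the study-profile missingness, score the battery with the
re-weighting allowances, tabulate missing proportions and patterns,
model the steps-missingness indicator with recursive partitioning,
impute the raw protocol variables by chained equations, recompute the
scores on each completed dataset and contrast them with the original
via dummy-coded regression and effect sizes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, imputation, report, scoring, tree
from .battery import DEFAULT_BATTERY
from .cohort import CohortParams, generate_cohort
from .missingness import MissingnessMechanism, apply_missingness, default_mechanism
from .scoretable import DEFAULT_SCORING_TABLE, raw_to_points

TREE_PREDICTORS = ["age", "gender", "height", "weight", "grade", "site"]


@dataclass
class PipelineConfig:
    """Reproducible configuration of one full run."""

    n: int = 10_000
    seed: int = 0
    m: int = 5
    iterations: int = 50
    k: int = 5
    allow_reweight: bool = True
    db_reweight: bool = True
    impute_variables: list[str] | None = None  # None = every variable with missing cells
    tree_params: tree.TreeParams = field(default_factory=tree.TreeParams)
    mechanism: MissingnessMechanism | None = None  # None = shipped default

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        tp = payload.pop("tree_params", None)
        cfg = cls(**payload)
        if tp:
            cfg.tree_params = tree.TreeParams(**tp)
        return cfg


def _score_subset(masked: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    points = raw_to_points(masked, DEFAULT_SCORING_TABLE, DEFAULT_BATTERY)
    return scoring.score_cohort(
        points, demographics=masked[["age", "gender"]], battery=DEFAULT_BATTERY,
        allow_reweight=cfg.allow_reweight, db_reweight=cfg.db_reweight,
    )


def run_pipeline(cfg: PipelineConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run the full workflow; returns a bundle of all intermediate results.

    The bundle has six sections: ``simulate``, ``score``, ``diagnose``,
    ``tree``, ``impute`` and ``contrast``.  When ``out_dir`` is given
    the standard CSV/JSON artifacts are written there as well.
    """
    cfg = cfg or PipelineConfig()
    bundle: dict = {}

    # 1. simulate a complete cohort and inject missingness
    cohort = generate_cohort(CohortParams(n=cfg.n), seed=cfg.seed)
    mech = cfg.mechanism or default_mechanism()
    masked, truth = apply_missingness(cohort, mech, seed=cfg.seed + 1)
    bundle["simulate"] = {"cohort": masked, "truth": truth, "complete": cohort}

    # 2. score the battery on the observed data
    subset = _score_subset(masked, cfg)
    bundle["score"] = {"analysis_subset": subset}

    # 3. missingness diagnostics on the analysis subset
    score_vars = [c for c in subset.columns if c != "gender"]
    props = diagnostics.proportions_report(subset, score_vars)
    patterns = diagnostics.enumerate_patterns(subset, ["pc", "db", "ku", "mc", "overall"])
    bundle["diagnose"] = {
        "proportions": props,
        "patterns": patterns,
        "n_complete_domains": diagnostics.complete_case_count(
            subset, ["pc", "db", "ku", "mc", "overall"]),
    }

    # 4. recursive partitioning of the steps-missingness indicator
    steps_missing = subset["steps"].isna()
    fitted = tree.grow_tree(masked[TREE_PREDICTORS], steps_missing, cfg.tree_params)
    bundle["tree"] = {
        "tree": fitted,
        "first_split": tree.first_split_variable(fitted),
        "importance": tree.importance(fitted),
    }

    # 5. chained-equation imputation of the raw variables
    spec = imputation.default_imputation_spec(
        masked, variables=cfg.impute_variables, m=cfg.m,
        iterations=cfg.iterations, k=cfg.k, seed=cfg.seed + 2,
    )
    imputed = imputation.mice(masked, spec)
    bundle["impute"] = {"imputed": imputed, "spec": spec}

    # 6. rescore each completed dataset and contrast with the original
    imputed_subsets = [_score_subset(t, cfg) for t in imputed.tables]
    contrast = report.imputation_contrast(subset, imputed_subsets)
    summary = report.group_summary(
        subset.drop(columns=["gender"]), steps_missing,
        group_labels=(False, True),
    )
    bundle["contrast"] = {
        "contrast": contrast,
        "group_summary": summary,
        "imputed_subsets": imputed_subsets,
    }

    if out_dir is not None:
        _write_bundle(bundle, cfg, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["simulate"]["cohort"].to_csv(out / "cohort.csv")
    bundle["score"]["analysis_subset"].to_csv(out / "analysis_subset.csv")
    bundle["diagnose"]["proportions"].to_csv(out / "missing_proportions.csv", index=False)
    bundle["diagnose"]["patterns"].to_frame().to_csv(out / "patterns.csv", index=False)
    with open(out / "tree.json", "w") as fh:
        json.dump(bundle["tree"]["tree"].to_dict(), fh, indent=2)
    imp = pd.Series(bundle["tree"]["importance"], name="importance")
    imp.rename_axis("variable").to_csv(out / "importance.csv")
    for i, t in enumerate(bundle["impute"]["imputed"].tables, start=1):
        t.to_csv(out / f"imputed_{i}.csv")
    bundle["contrast"]["group_summary"].to_csv(out / "group_summary.csv", index=False)
    bundle["contrast"]["contrast"].table.to_csv(out / "contrast.csv", index=False)
    meta = {
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()
                   if k not in ("mechanism", "tree_params")},
        "tree_first_split": bundle["tree"]["first_split"],
        "n_complete_domains": int(bundle["diagnose"]["n_complete_domains"]),
        "n_unique_patterns": bundle["diagnose"]["patterns"].n_unique,
        "imputation_seeds": bundle["impute"]["imputed"].seeds,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
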