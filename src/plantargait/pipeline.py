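"""End-to-end orchestration: simulate -> segment -> featurize -> select ->
train -> report.

A :class:`RunConfig` fixes every stochastic stage with an explicit seed
namespace derived from one base seed (cohort = seed, split = seed+1,
selection = seed+2, models = seed+3), so a rerun with the same config is
byte-identical.  Artifacts: feature table CSV, selection trace JSON, model
report JSON, and per-stage log counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError
from .features import extract_cohort_features
from .models import (
    MODEL_NAMES,
    TREE_MEMBERS,
    ModelMetrics,
    baseline_cv_metrics,
    baseline_predict,
    compute_ri,
    evaluate,
    fit_average_ensemble,
    fit_individual,
    fit_stacked,
    holdout_split,
)
from .selection import stepwise_select, _default_base_model
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_VALID_TASKS = ("fpwt40", "tugt")
_VALID_DIRECTIONS = ("forward", "backward")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON-loadable)."""

    n_participants: int = 40
    seed: int = 7
    task: str = "fpwt40"
    test_fraction: float = 0.33
    threshold_fraction: float = 0.05
    spearman_threshold: float = 0.2
    mrmr_k: Optional[int] = None
    wrapper: bool = True
    direction: str = "backward"
    wrapper_base_estimators: int = 50
    wrapper_max_features: Optional[int] = 15
    tuning_budget: int = 10
    models: List[str] = field(default_factory=lambda: list(MODEL_NAMES))
    ensembles: List[str] = field(
        default_factory=lambda: ["stack-linear", "stack-svm", "SAE", "WAE"])
    output_dir: Optional[str] = None

    def validate(self) -> None:
        if self.task not in _VALID_TASKS:
            raise ConfigurationError(f"task must be one of {_VALID_TASKS}")
        if not 0 < self.test_fraction < 1:
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        if self.n_participants < 6:
            raise ConfigurationError("n_participants must be >= 6")
        if self.direction not in _VALID_DIRECTIONS:
            raise ConfigurationError(f"direction must be one of {_VALID_DIRECTIONS}")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown models: {sorted(unknown)}")
        bad = set(self.ensembles) - {"stack-linear", "stack-svm", "SAE", "WAE"}
        if bad:
            raise ConfigurationError(f"unknown ensembles: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _metrics_entry(metrics: ModelMetrics, baseline: ModelMetrics) -> Dict:
    return {**metrics.as_dict(), "ri": compute_ri(baseline, metrics).ri}


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full pipeline on a synthetic cohort; return the report dict."""
    config.validate()
    task = config.task
    label_col = f"{task}_s"

    logger.info("stage 1/5: simulating cohort (n=%d)", config.n_participants)
    spec = CohortSpec(n_participants=config.n_participants, seed=config.seed)
    recordings, physical, labels, truth = generate_cohort(spec)

    logger.info("stage 2/5: segmenting and extracting features")
    table = extract_cohort_features(recordings, physical,
                                    threshold_fraction=config.threshold_fraction)
    logger.info("feature table: %d participants x %d columns",
                *table.shape)

    y = labels[label_col]
    train_idx, test_idx = holdout_split(len(table),
                                        test_fraction=config.test_fraction,
                                        seed=config.seed + 1)
    train_ids = table.index[train_idx]
    test_ids = table.index[test_idx]
    logger.info("stage 3/5: holdout split train=%d test=%d",
                len(train_ids), len(test_ids))

    logger.info("stage 4/5: stepwise feature selection (%s)", config.direction)
    trace = stepwise_select(
        table, y, train_ids,
        spearman_threshold=config.spearman_threshold,
        mrmr_k=config.mrmr_k,
        direction=config.direction,
        base_model=_default_base_model(config.seed + 2,
                                       config.wrapper_base_estimators),
        seed=config.seed + 2,
        wrapper_max_features=config.wrapper_max_features,
        run_wrapper=config.wrapper,
    )
    subset = trace.final_subset
    for s in trace.stages:
        logger.info("  %s: %d features retained", s["stage"], len(s["retained"]))
    if not subset:
        raise ConfigurationError("selection produced an empty feature subset")

    # Training-mean imputation of flagged-missing features, then slice.
    train_means = table.loc[train_ids].mean()
    filled = table.fillna(train_means)
    X_tr = filled.loc[train_ids, subset].to_numpy(dtype=float)
    X_te = filled.loc[test_ids, subset].to_numpy(dtype=float)
    y_tr = y.loc[train_ids].to_numpy(dtype=float)
    y_te = y.loc[test_ids].to_numpy(dtype=float)

    logger.info("stage 5/5: model training and evaluation")
    seed_m = config.seed + 3
    base_cv = baseline_cv_metrics(y_tr, seed=seed_m)
    base_hold = evaluate(y_te, baseline_predict(y_tr, len(y_te)))
    train_cv: Dict[str, Dict] = {"Baseline": _metrics_entry(base_cv, base_cv)}
    holdout: Dict[str, Dict] = {"Baseline": _metrics_entry(base_hold, base_hold)}

    fitted: Dict[str, object] = {}
    for name in config.models:
        model, cv_metrics = fit_individual(name, X_tr, y_tr,
                                           tuning_budget=config.tuning_budget,
                                           seed=seed_m)
        fitted[name] = model
        train_cv[name] = _metrics_entry(cv_metrics, base_cv)
        holdout[name] = _metrics_entry(evaluate(y_te, model.predict(X_te)),
                                       base_hold)
        logger.info("  %s: CV MAE %.3f s", name, cv_metrics.mae)

    tree_fitted = {n: fitted[n] for n in TREE_MEMBERS if n in fitted}
    for mode in config.ensembles:
        if mode.startswith("stack"):
            kind = mode.split("-", 1)[1]
            stack, cv_metrics = fit_stacked(X_tr, y_tr, second_level=kind,
                                            seed=seed_m)
            label = f"Stack ({'linear' if kind == 'linear' else 'SVM'})"
            train_cv[label] = _metrics_entry(cv_metrics, base_cv)
            holdout[label] = _metrics_entry(
                evaluate(y_te, stack.predict(X_te)), base_hold)
        elif len(tree_fitted) >= 2:
            ris = {n: train_cv[n]["ri"] for n in tree_fitted}
            try:
                ens = fit_average_ensemble(tree_fitted, mode=mode,
                                           member_ris=ris)
            except ConfigurationError as exc:
                logger.warning("skipping %s: %s", mode, exc)
                continue
            holdout[mode] = _metrics_entry(
                evaluate(y_te, ens.predict(X_te)), base_hold)
            w = ens.weights
            train_cv[mode] = {"weights": w}

    report = {
        "task": task,
        "n_participants": config.n_participants,
        "n_train": int(len(train_ids)),
        "n_test": int(len(test_ids)),
        "selected_features": list(subset),
        "stage_counts": {s["stage"]: len(s["retained"]) for s in trace.stages},
        "train_cv": train_cv,
        "holdout": holdout,
        "seed": config.seed,
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "features.csv")
        labels.to_csv(out / "labels.csv", float_format="%.6g")
        trace.to_json(out / "selection_trace.json")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float))
        (out / "config.json").write_text(
            json.dumps(asdict(config), indent=2, sort_keys=True))
    return report
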