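"""Stepwise feature selection: Spearman filter -> mRMR -> floating wrapper.

The cascade reduces the 384-column feature table to a compact subset on the
training split only:

1. **Spearman filter** — drop features whose rank correlation with the task
   label has magnitude below 0.2 (and constant features, whose correlation
   is undefined).
2. **mRMR** (minimum redundancy, maximum relevance; MID/difference variant
   for a continuous target) — greedy forward selection scoring each
   candidate as ``|pearson(x, y)| - mean_j |pearson(x, x_j)|`` over already
   selected features ``x_j``; at most ``k`` features (the training-set size
   by default) are kept.
3. **Floating wrapper** (SFFS or SBFS) — conditional add/remove steps scored
   by the mean cross-validated MAE of a base regressor; the subset with the
   best CV score over all visited sizes wins.

A PCA benchmark (same base model on leading principal components) gauges
whether stepwise selection beats plain dimensionality reduction.

All statistics are computed from the training rows alone; the public entry
point :func:`stepwise_select` takes the full table plus training indices so
leakage can be asserted by perturbing held-out rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score, cross_validate
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .core import ConfigurationError, ValidationError

__all__ = [
    "SelectionTrace",
    "spearman_filter",
    "mrmr_select",
    "sequential_floating_select",
    "pca_benchmark",
    "stepwise_select",
]


@dataclass
class SelectionTrace:
    """Record of the cascade: per-stage survivors/scores and final subset."""

    stages: List[Dict] = field(default_factory=list)
    final_subset: List[str] = field(default_factory=list)

    def add_stage(self, name: str, retained: Sequence[str],
                  scores: Optional[Dict[str, float]] = None,
                  extra: Optional[Dict] = None) -> None:
        self.stages.append({
            "stage": name,
            "retained": list(retained),
            "scores": dict(scores or {}),
            **(extra or {}),
        })

    def stage(self, name: str) -> Dict:
        for s in self.stages:
            if s["stage"] == name:
                return s
        raise KeyError(name)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"stages": self.stages, "final_subset": self.final_subset},
            indent=2, sort_keys=True, default=float,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _default_base_model(seed: int = 0, n_estimators: int = 100):
    return RandomForestRegressor(n_estimators=n_estimators, random_state=seed,
                                 n_jobs=1)


# ---------------------------------------------------------------------------
# Filter stages
# ---------------------------------------------------------------------------

def spearman_filter(X: pd.DataFrame, y: pd.Series, threshold: float = 0.2
                    ) -> Tuple[List[str], Dict[str, float]]:
    """Retain features with |Spearman rho| >= ``threshold`` against the
    label; drop constant features (undefined correlation).

    Ties at the threshold are retained (>=).  Returns (names, rho per name).
    """
    if len(X) < 2:
        raise ValidationError("need at least 2 training samples")
    y_rank = stats.rankdata(np.asarray(y, dtype=float))
    retained, scores = [], {}
    for col in X.columns:
        x = np.asarray(X[col], dtype=float)
        finite = np.isfinite(x)
        if finite.sum() < 2 or np.nanstd(x) == 0:
            continue
        x_use, y_use = x[finite], y_rank[finite]
        rho = np.corrcoef(stats.rankdata(x_use), stats.rankdata(y_use))[0, 1]
        if not np.isfinite(rho):
            continue
        scores[col] = float(rho)
        if abs(rho) >= threshold:
            retained.append(col)
    return retained, scores


def mrmr_select(X: pd.DataFrame, y: pd.Series, k: int,
                redundancy_weight: float = 1.0) -> List[str]:
    """Greedy forward mRMR for a continuous target (MID form).

    Score of a candidate = |pearson(x, y)| - ``redundancy_weight`` * mean
    |pearson| with already-selected features.  With ``redundancy_weight=0``
    this reduces to top-k relevance ranking.  Returns the first ``k``
    feature names in selection order.
    """
    if k <= 0:
        raise ConfigurationError("k must be positive")
    if k > len(X):
        raise ConfigurationError(
            f"k ({k}) must not exceed the number of training samples ({len(X)})"
        )
    cols = list(X.columns)
    k = min(k, len(cols))
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(Xv, yv, rowvar=False)
    rel = np.abs(np.nan_to_num(mat[-1, :-1]))
    feat_corr = np.abs(np.nan_to_num(mat[:-1, :-1]))

    selected: List[int] = []
    remaining = set(range(len(cols)))
    red_sum = np.zeros(len(cols))
    while len(selected) < k and remaining:
        idx = np.fromiter(remaining, dtype=int)
        if not selected:
            score = rel[idx]
        else:
            score = rel[idx] - redundancy_weight * red_sum[idx] / len(selected)
        # ties broken toward the earlier column for determinism
        best = idx[np.lexsort((idx, -score))[0]]
        selected.append(int(best))
        remaining.discard(int(best))
        red_sum += feat_corr[:, best]
    return [cols[i] for i in selected]


# ---------------------------------------------------------------------------
# Floating wrapper
# ---------------------------------------------------------------------------

def _cv_score(model, X: pd.DataFrame, y: pd.Series, subset: Tuple[str, ...],
              cv_folds: int, seed: int, cache: Dict) -> float:
    """Mean CV negative MAE of ``model`` on the given feature subset."""
    key = frozenset(subset)
    if key in cache:
        return cache[key]
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clone(model), X[list(subset)], y, cv=cv,
                             scoring="neg_mean_absolute_error",
                             error_score="raise")
    if not np.all(np.isfinite(scores)):
        bad = int(np.flatnonzero(~np.isfinite(scores))[0])
        raise ValidationError(f"CV score undefined in fold {bad}")
    val = float(scores.mean())
    cache[key] = val
    return val


def sequential_floating_select(
    X: pd.DataFrame,
    y: pd.Series,
    direction: str = "forward",
    base_model=None,
    cv: int = 5,
    seed: int = 0,
    min_features: int = 1,
    max_features: Optional[int] = None,
) -> Tuple[List[str], Dict[int, float]]:
    """SFFS / SBFS with conditional inclusion/exclusion steps.

    Forward starts from the empty set, adds the best-scoring feature, then
    floats: removes features while removal improves on the best subset seen
    at that size.  Backward mirrors this from the full set.  Scoring is the
    mean 5-fold CV negative MAE of ``base_model``.  Returns the best subset
    over all visited sizes and the best score per size.
    """
    if direction not in ("forward", "backward"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    if cv < 2:
        raise ConfigurationError("cv must be >= 2")
    model = base_model if base_model is not None else _default_base_model(seed)
    features = list(X.columns)
    max_features = min(max_features or len(features), len(features))
    cache: Dict = {}
    best_by_size: Dict[int, Tuple[float, Tuple[str, ...]]] = {}

    def score(subset) -> float:
        return _cv_score(model, X, y, tuple(subset), cv, seed, cache)

    def note(subset) -> None:
        s = score(subset)
        size = len(subset)
        if size not in best_by_size or s > best_by_size[size][0]:
            best_by_size[size] = (s, tuple(subset))

    if direction == "forward":
        current: List[str] = []
        while len(current) < max_features:
            candidates = [f for f in features if f not in current]
            gains = [(score(current + [f]), f) for f in candidates]
            best_gain, best_f = max(gains, key=lambda t: (t[0], -candidates.index(t[1])))
            current.append(best_f)
            note(current)
            # conditional exclusion
            while len(current) > min_features + 1:
                drops = [(score([f for f in current if f != f0]), f0)
                         for f0 in current]
                drop_score, drop_f = max(drops, key=lambda t: t[0])
                size = len(current) - 1
                if size in best_by_size and drop_score > best_by_size[size][0]:
                    current.remove(drop_f)
                    note(current)
                else:
                    break
    else:
        current = list(features)
        note(current)
        while len(current) > min_features:
            drops = [(score([f for f in current if f != f0]), f0)
                     for f0 in current]
            drop_score, drop_f = max(drops, key=lambda t: t[0])
            current.remove(drop_f)
            note(current)
            # conditional inclusion
            while len(current) < len(features) - 1:
                adds = [(score(current + [f]), f)
                        for f in features if f not in current]
                add_score, add_f = max(adds, key=lambda t: t[0])
                size = len(current) + 1
                if size in best_by_size and add_score > best_by_size[size][0]:
                    current.append(add_f)
                    note(current)
                else:
                    break

    best_size = max(best_by_size, key=lambda s: (best_by_size[s][0], -s))
    best_subset = list(best_by_size[best_size][1])
    per_size = {s: v[0] for s, v in best_by_size.items()}
    return best_subset, per_size


# ---------------------------------------------------------------------------
# PCA benchmark
# ---------------------------------------------------------------------------

def pca_benchmark(X: pd.DataFrame, y: pd.Series, base_model=None, cv: int = 5,
                  variance: float = 0.95, seed: int = 0) -> Dict[str, float]:
    """CV metrics of the base model on leading principal components.

    Components are chosen to explain ``variance`` of the (standardized)
    training variance.  Returns mean CV MAE (s), MAPE (%), RMSE (s) plus the
    component count, comparable with the wrapper's CV performance.
    """
    model = base_model if base_model is not None else _default_base_model(seed)
    n_comp = min(len(X) - 1, X.shape[1])
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("pca", PCA(n_components=min(variance, 0.9999), svd_solver="full")
         if variance < 1 else PCA(n_components=n_comp)),
        ("model", clone(model)),
    ])
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    res = cross_validate(
        pipe, X, y, cv=folds,
        scoring={
            "mae": "neg_mean_absolute_error",
            "mape": "neg_mean_absolute_percentage_error",
            "rmse": "neg_root_mean_squared_error",
        },
    )
    pipe.fit(X, y)
    return {
        "mae": float(-res["test_mae"].mean()),
        "mape": float(-res["test_mape"].mean() * 100.0),
        "rmse": float(-res["test_rmse"].mean()),
        "n_components": int(pipe.named_steps["pca"].n_components_),
    }


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def stepwise_select(
    X: pd.DataFrame,
    y: pd.Series,
    train_idx: Sequence,
    spearman_threshold: float = 0.2,
    mrmr_k: Optional[int] = None,
    direction: str = "backward",
    base_model=None,
    cv: int = 5,
    seed: int = 0,
    wrapper_max_features: Optional[int] = None,
    run_wrapper: bool = True,
) -> SelectionTrace:
    """Run the full cascade on the training rows of a feature table.

    ``train_idx`` selects the training rows of ``X``/``y``; held-out rows
    are never touched.  ``mrmr_k`` defaults to the training-set size.
    Feature columns are z-scored with training statistics before mRMR.
    Missing values are imputed with training-column means first.
    """
    X_tr = X.loc[train_idx].copy()
    y_tr = y.loc[train_idx]
    X_tr = X_tr.fillna(X_tr.mean())
    X_tr = X_tr.dropna(axis=1)  # columns with no finite training value

    trace = SelectionTrace()
    retained, rho = spearman_filter(X_tr, y_tr, threshold=spearman_threshold)
    trace.add_stage("spearman", retained,
                    {k: rho[k] for k in retained},
                    extra={"threshold": spearman_threshold})
    if not retained:
        trace.final_subset = []
        return trace

    k = mrmr_k if mrmr_k is not None else len(X_tr)
    k = min(k, len(retained))
    scaler = StandardScaler().fit(X_tr[retained])
    X_std = pd.DataFrame(scaler.transform(X_tr[retained]),
                         index=X_tr.index, columns=retained)
    mrmr_subset = mrmr_select(X_std, y_tr, k=k)
    trace.add_stage("mrmr", mrmr_subset, extra={"k": k})

    if run_wrapper and len(mrmr_subset) > 1:
        subset, per_size = sequential_floating_select(
            X_tr[mrmr_subset], y_tr, direction=direction,
            base_model=base_model, cv=cv, seed=seed,
            max_features=wrapper_max_features,
        )
        trace.add_stage(
            "wrapper", subset,
            extra={"direction": direction,
                   "cv_neg_mae_by_size": {str(s): v for s, v in per_size.items()}},
        )
        trace.final_subset = subset
    else:
        trace.final_subset = mrmr_subset
    return trace
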