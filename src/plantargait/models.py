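"""Regression models for functional-test completion times.

Six individual regressors (LR, SVM, RF, AdaBoost, XGBoost, LGBM), a
two-level stacked model whose second level learns from out-of-fold
predictions of the four tree-based members (nested 5-fold CV), and simple /
weighted average ensembles (SAE / WAE).  Performance is reported as MAE (s),
MAPE (%) and RMSE (s); each model's overall quality is summarized by the
relative index

    RI = sum over m in {MAE, MAPE, RMSE} of (baseline_m - model_m) / baseline_m

against the training-mean baseline predictor (RI = 0 for the baseline
itself, larger is better).  WAE weights members proportionally to their RI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from lightgbm import LGBMRegressor
from scipy.stats import loguniform, randint, uniform
from sklearn.base import clone
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, RandomizedSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .core import ConfigurationError, ValidationError

__all__ = [
    "ModelMetrics",
    "RIScore",
    "EnsembleModel",
    "MODEL_NAMES",
    "TREE_MEMBERS",
    "evaluate",
    "baseline_predict",
    "compute_ri",
    "holdout_split",
    "fit_individual",
    "fit_stacked",
    "fit_average_ensemble",
    "baseline_cv_metrics",
]

MODEL_NAMES = ("LR", "SVM", "RF", "AdaBoost", "XGBoost", "LGBM")
TREE_MEMBERS = ("RF", "AdaBoost", "XGBoost", "LGBM")


@dataclass(frozen=True)
class ModelMetrics:
    """MAE (s), MAPE (%), RMSE (s); RMSE >= MAE always holds."""

    mae: float
    mape: float
    rmse: float

    def as_dict(self) -> Dict[str, float]:
        return {"mae": self.mae, "mape": self.mape, "rmse": self.rmse}

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.mae, self.mape, self.rmse)


@dataclass(frozen=True)
class RIScore:
    """Relative index and its per-metric components."""

    ri: float
    components: Dict[str, float]


def evaluate(y_true, y_pred) -> ModelMetrics:
    """Compute MAE, MAPE (x100, percent) and RMSE of a prediction vector."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValidationError("y_true and y_pred must be equal-length, nonempty")
    if np.any(y_true == 0):
        raise ValidationError("MAPE undefined: y_true contains zeros")
    err = y_pred - y_true
    return ModelMetrics(
        mae=float(np.mean(np.abs(err))),
        mape=float(np.mean(np.abs(err) / np.abs(y_true)) * 100.0),
        rmse=float(math.sqrt(np.mean(err**2))),
    )


def baseline_predict(train_labels, n_test: int) -> np.ndarray:
    """Constant prediction equal to the training-label mean."""
    train_labels = np.asarray(train_labels, dtype=float)
    if train_labels.size == 0:
        raise ValidationError("train_labels must be nonempty")
    return np.full(n_test, train_labels.mean())


def compute_ri(baseline: ModelMetrics, model: ModelMetrics) -> RIScore:
    """Relative index: summed per-metric relative improvement over baseline."""
    components = {}
    for name in ("mae", "mape", "rmse"):
        b = getattr(baseline, name)
        if b <= 0:
            raise ValidationError(f"baseline {name} must be positive")
        components[name] = (b - getattr(model, name)) / b
    return RIScore(ri=float(sum(components.values())), components=components)


def holdout_split(n: int, test_fraction: float = 0.33, seed: int = 0
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Random train/test index split; for n=92 at 33% this gives 61/31."""
    if n < 3:
        raise ValidationError("need at least 3 samples to split")
    train, test = train_test_split(np.arange(n), test_size=test_fraction,
                                   random_state=seed, shuffle=True)
    return np.sort(train), np.sort(test)


# ---------------------------------------------------------------------------
# Individual models
# ---------------------------------------------------------------------------

def _build_model(name: str, seed: int):
    """Estimator + randomized-search space for each supported regressor."""
    if name == "LR":
        return LinearRegression(), {}
    if name == "SVM":
        est = Pipeline([("scale", StandardScaler()),
                        ("svr", SVR(kernel="rbf"))])
        space = {"svr__C": loguniform(0.1, 100.0),
                 "svr__gamma": loguniform(1e-3, 1.0),
                 "svr__epsilon": loguniform(0.01, 1.0)}
        return est, space
    if name == "RF":
        est = RandomForestRegressor(random_state=seed, n_jobs=1)
        space = {"n_estimators": randint(50, 301),
                 "max_depth": randint(2, 13),
                 "min_samples_leaf": randint(1, 6)}
        return est, space
    if name == "AdaBoost":
        est = AdaBoostRegressor(random_state=seed)
        space = {"n_estimators": randint(30, 201),
                 "learning_rate": loguniform(0.01, 2.0)}
        return est, space
    if name == "XGBoost":
        est = XGBRegressor(random_state=seed, n_jobs=1, verbosity=0,
                           tree_method="hist")
        space = {"n_estimators": randint(50, 301),
                 "max_depth": randint(2, 8),
                 "learning_rate": loguniform(0.01, 0.5),
                 "subsample": uniform(0.6, 0.4)}
        return est, space
    if name == "LGBM":
        est = LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1,
                            min_child_samples=5)
        space = {"n_estimators": randint(50, 301),
                 "num_leaves": randint(4, 32),
                 "learning_rate": loguniform(0.01, 0.5),
                 "subsample": uniform(0.6, 0.4)}
        return est, space
    raise ConfigurationError(f"unknown model name {name!r}")


def _cv_metrics(model, X, y, cv: KFold) -> ModelMetrics:
    """Mean per-fold MAE/MAPE/RMSE of a (cloned) estimator."""
    maes, mapes, rmses = [], [], []
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    for tr, va in cv.split(X):
        est = clone(model)
        est.fit(X[tr], y[tr])
        m = evaluate(y[va], est.predict(X[va]))
        maes.append(m.mae)
        mapes.append(m.mape)
        rmses.append(m.rmse)
    return ModelMetrics(float(np.mean(maes)), float(np.mean(mapes)),
                        float(np.mean(rmses)))


def baseline_cv_metrics(y, cv_folds: int = 5, seed: int = 0) -> ModelMetrics:
    """CV metrics of the training-mean baseline predictor."""
    y = np.asarray(y, dtype=float)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    maes, mapes, rmses = [], [], []
    for tr, va in cv.split(y):
        m = evaluate(y[va], baseline_predict(y[tr], va.size))
        maes.append(m.mae)
        mapes.append(m.mape)
        rmses.append(m.rmse)
    return ModelMetrics(float(np.mean(maes)), float(np.mean(mapes)),
                        float(np.mean(rmses)))


def fit_individual(model_name: str, X, y, tuning_budget: int = 20,
                   seed: int = 0, cv_folds: int = 5):
    """Tune (randomized search, ``tuning_budget`` draws), evaluate by 5-fold
    CV, and refit on all data.  Returns ``(fitted model, ModelMetrics)``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 10:
        raise ValidationError("need at least 10 training rows")
    est, space = _build_model(model_name, seed)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    if space and tuning_budget > 0:
        search = RandomizedSearchCV(
            est, space, n_iter=tuning_budget, cv=cv,
            scoring="neg_mean_absolute_error", random_state=seed, n_jobs=1,
            refit=False,
        )
        search.fit(X, y)
        est = clone(est).set_params(**search.best_params_)
    metrics = _cv_metrics(est, X, y, cv)
    fitted = clone(est).fit(X, y)
    return fitted, metrics


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Fitted ensemble: stacked (linear/SVM second level) or SAE/WAE."""

    members: Dict[str, object]
    mode: str                       # stack-linear | stack-svm | SAE | WAE
    second_level: Optional[object] = None
    weights: Optional[Dict[str, float]] = None
    seed: int = 0
    fold_assignments: Optional[np.ndarray] = None

    def member_matrix(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([m.predict(X) for m in self.members.values()])

    def predict(self, X) -> np.ndarray:
        P = self.member_matrix(X)
        if self.mode.startswith("stack"):
            return np.asarray(self.second_level.predict(P), dtype=float)
        w = np.array([self.weights[name] for name in self.members])
        return P @ w


def _oof_predictions(member_specs: Dict[str, object], X: np.ndarray,
                     y: np.ndarray, cv: KFold
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Out-of-fold member predictions: row i is predicted only by models
    trained on folds not containing i."""
    P = np.zeros((X.shape[0], len(member_specs)))
    assign = np.zeros(X.shape[0], dtype=int)
    for fold, (tr, va) in enumerate(cv.split(X)):
        assign[va] = fold
        for j, est in enumerate(member_specs.values()):
            m = clone(est).fit(X[tr], y[tr])
            P[va, j] = m.predict(X[va])
    return P, assign


def _second_level(kind: str, seed: int):
    if kind == "linear":
        return LinearRegression()
    if kind == "svm":
        return Pipeline([("scale", StandardScaler()),
                         ("svr", SVR(kernel="rbf", C=10.0, gamma="scale"))])
    raise ConfigurationError(f"unknown second-level model {kind!r}")


def fit_stacked(X, y, second_level: str = "svm", seed: int = 0,
                cv_folds: int = 5, member_params: Optional[Dict] = None
                ) -> Tuple[EnsembleModel, ModelMetrics]:
    """Two-level stack with nested 5-fold CV.

    Outer folds score the stack; within each outer training set, inner folds
    produce out-of-fold predictions of the four tree members that train the
    second-level regressor.  No member ever predicts a sample it was trained
    on.  Returns the final model (fitted on all data) and outer-CV metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    members = {name: _build_model(name, seed)[0] for name in TREE_MEMBERS}
    if member_params:
        for name, params in member_params.items():
            members[name] = clone(members[name]).set_params(**params)

    outer = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    inner = KFold(n_splits=cv_folds, shuffle=True, random_state=seed + 1)
    maes, mapes, rmses = [], [], []
    for tr, va in outer.split(X):
        if va.size < 2 or tr.size < cv_folds:
            raise ValidationError("fold with too few samples")
        P_tr, _ = _oof_predictions(members, X[tr], y[tr], inner)
        meta = _second_level(second_level, seed).fit(P_tr, y[tr])
        fitted = {n: clone(m).fit(X[tr], y[tr]) for n, m in members.items()}
        P_va = np.column_stack([fitted[n].predict(X[va]) for n in members])
        m = evaluate(y[va], meta.predict(P_va))
        maes.append(m.mae)
        mapes.append(m.mape)
        rmses.append(m.rmse)
    metrics = ModelMetrics(float(np.mean(maes)), float(np.mean(mapes)),
                           float(np.mean(rmses)))

    P_full, assign = _oof_predictions(members, X, y, inner)
    meta = _second_level(second_level, seed).fit(P_full, y)
    fitted_members = {n: clone(m).fit(X, y) for n, m in members.items()}
    model = EnsembleModel(members=fitted_members, mode=f"stack-{second_level}",
                          second_level=meta, seed=seed,
                          fold_assignments=assign)
    return model, metrics


def fit_average_ensemble(members: Dict[str, object], mode: str = "SAE",
                         member_ris: Optional[Dict[str, float]] = None
                         ) -> EnsembleModel:
    """Simple or weighted average of fitted members.

    SAE uses equal weights.  WAE weights each member by the proportion of
    its RI among positive-RI members; members with RI <= 0 are excluded
    (their proportional weight is undefined), and an error is raised only
    when no member has positive RI.
    """
    if mode == "SAE":
        w = {name: 1.0 / len(members) for name in members}
        return EnsembleModel(members=dict(members), mode="SAE", weights=w)
    if mode != "WAE":
        raise ConfigurationError(f"unknown ensemble mode {mode!r}")
    if not member_ris:
        raise ConfigurationError("WAE requires member RI values")
    positive = {n: r for n, r in member_ris.items() if n in members and r > 0}
    if not positive:
        raise ConfigurationError("WAE undefined: no member has positive RI")
    total = sum(positive.values())
    kept = {n: members[n] for n in members if n in positive}
    w = {n: positive[n] / total for n in kept}
    return EnsembleModel(members=kept, mode="WAE", weights=w)
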