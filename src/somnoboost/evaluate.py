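"""Gradient-boosted sleep-stage classification and cross-validated evaluation.

Tree construction is delegated to xgboost (5-class softmax objective,
multiclass logloss as the tracked training metric); everything reported —
multiclass logloss, Cohen's κ, accuracy, weighted precision/recall/F1,
confusion matrices, one-vs-rest ROC AUC, CV means — is computed here.

Two experiment modes mirror the method's two experiments: ``default`` trains
with the stock hyperparameters; ``pso`` first runs a particle-swarm search
whose fitness is inner stratified-CV accuracy, then evaluates the tuned
configuration with the same outer stratified 10-fold protocol. Class
imbalance is handled by oversampling *training folds only*; test folds are
never touched by balancing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .dataset import balance_training, feature_columns, stratified_folds
from .pso import PSOConfig, SearchSpace, compact_xgb_space, decode, optimise
from .stages import STAGES

__all__ = [
    "DEFAULT_XGB_PARAMS",
    "train",
    "multiclass_logloss",
    "cohen_kappa",
    "fold_metrics",
    "cv_mean",
    "run_experiment",
    "FoldResult",
    "CVReport",
    "ExperimentConfig",
]

N_CLASSES = 5

#: Stock hyperparameters for the first (untuned) experiment.
DEFAULT_XGB_PARAMS: dict = {
    "base_score": 0.5,
    "booster": "gbtree",  # "dart" also accepted; dart extras below
    "colsample_bylevel": 1.0,
    "colsample_bynode": 1.0,
    "colsample_bytree": 1.0,
    "gamma": 0.0,
    "learning_rate": 0.1,
    "max_delta_step": 0,
    "max_depth": 3,
    "min_child_weight": 1,
    "n_estimators": 100,
    "reg_alpha": 0.0,
    "reg_lambda": 1.0,
    "scale_pos_weight": 1.0,
    "subsample": 1.0,
    # dart-only extras (ignored by gbtree)
    "sample_type": "uniform",
    "normalize_type": "tree",
    "rate_drop": 0.0,
    "one_drop": 0,
    "skip_drop": 0.0,
}

_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "learning_rate": (1e-6, 1.0),
    "max_depth": (1, 64),
    "n_estimators": (1, 5000),
    "min_child_weight": (0, 1e6),
    "gamma": (0.0, np.inf),
    "subsample": (1e-6, 1.0),
    "colsample_bytree": (1e-6, 1.0),
    "colsample_bylevel": (1e-6, 1.0),
    "colsample_bynode": (1e-6, 1.0),
    "reg_alpha": (0.0, np.inf),
    "reg_lambda": (0.0, np.inf),
    "rate_drop": (0.0, 1.0),
    "skip_drop": (0.0, 1.0),
}


def _validate_params(params: dict) -> dict:
    merged = {**DEFAULT_XGB_PARAMS, **params}
    if merged["booster"] not in ("gbtree", "dart"):
        raise ValueError(f"booster must be gbtree or dart, got {merged['booster']!r}")
    for key, (lo, hi) in _PARAM_BOUNDS.items():
        v = merged[key]
        if not lo <= v <= hi:
            raise ValueError(f"hyperparameter {key}={v} outside [{lo}, {hi}]")
    return merged


def train(
    features: np.ndarray,
    labels: np.ndarray,
    params: dict | None = None,
    seed: int = 0,
    eval_sets: list[tuple[np.ndarray, np.ndarray]] | None = None,
):
    """Fit the boosted-tree multiclass model; returns the fitted classifier.

    ``eval_sets`` (e.g. [(train), (test)]) enables per-round logloss/error
    curves, retrievable via ``model.evals_result()``.
    """
    from xgboost import XGBClassifier

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(features).all():
        raise ValueError("NaN/inf in feature matrix")
    if labels.min() < 0 or labels.max() >= N_CLASSES:
        raise ValueError(f"labels must lie in 0..{N_CLASSES - 1}")
    p = _validate_params(params or {})
    if p["booster"] != "dart":
        p = {k: v for k, v in p.items()
             if k not in ("sample_type", "normalize_type", "rate_drop",
                          "one_drop", "skip_drop")}
    model = XGBClassifier(
        **p,
        objective="multi:softprob",
        num_class=N_CLASSES,
        eval_metric=["mlogloss", "merror"],
        random_state=seed,
        tree_method="hist",
        n_jobs=1,
        verbosity=0,
    )
    kwargs = {}
    if eval_sets is not None:
        kwargs["eval_set"] = eval_sets
        kwargs["verbose"] = False
    model.fit(features, labels, **kwargs)
    return model


def multiclass_logloss(y_true: np.ndarray, proba: np.ndarray) -> float:
    """−(1/M) Σ_j Σ_k y_{jk} ln p_{jk}, probabilities clipped to [1e-15, 1−1e-15]."""
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or proba.shape[0] != y_true.size:
        raise ValueError("probability matrix shape does not match labels")
    if np.abs(proba.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1")
    p = np.clip(proba, 1e-15, 1 - 1e-15)
    rows = np.arange(y_true.size)
    return float(-np.mean(np.log(p[rows, y_true])))


def cohen_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Chance-corrected agreement κ = (Po − Pe)/(1 − Pe)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size or y_true.size == 0:
        raise ValueError("label vectors must be equal-length and nonempty")
    m = y_true.size
    po = float(np.mean(y_true == y_pred))
    classes = np.union1d(y_true, y_pred)
    pe = sum(
        np.count_nonzero(y_true == c) * np.count_nonzero(y_pred == c)
        for c in classes
    ) / m**2
    if pe == 1.0:
        warnings.warn("both raters constant and equal: κ defined as 1")
        return 1.0
    return float((po - pe) / (1 - pe))


@dataclass
class FoldResult:
    fold: int
    accuracy: float
    f1: float
    precision: float
    recall: float
    kappa: float
    confusion: list  # 5×5, rows = true stage in W,N1,N2,SWS,REM order
    auc: dict  # one-vs-rest AUC per stage label
    logloss: float
    train_logloss_curve: list = field(default_factory=list)
    test_logloss_curve: list = field(default_factory=list)
    train_error_curve: list = field(default_factory=list)
    test_error_curve: list = field(default_factory=list)


def fold_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    proba: np.ndarray,
    fold: int = 0,
) -> FoldResult:
    """Accuracy, weighted P/R/F1, κ, confusion matrix, per-class ROC AUC."""
    from sklearn.metrics import (
        confusion_matrix,
        precision_recall_fscore_support,
        roc_auc_score,
    )

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = list(range(N_CLASSES))
    accuracy = float(np.mean(y_true == y_pred))
    present = np.union1d(y_true, y_pred)
    if present.size < N_CLASSES:
        missing = [STAGES[c] for c in labels if c not in present]
        warnings.warn(f"stages absent from fold: {missing}; excluded from averages")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="weighted", zero_division=0
        )
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    auc: dict[str, float] = {}
    for c in labels:
        mask = y_true == c
        if mask.any() and not mask.all():
            auc[STAGES[c]] = float(roc_auc_score(mask.astype(int), proba[:, c]))
        else:
            auc[STAGES[c]] = float("nan")
    return FoldResult(
        fold=fold,
        accuracy=accuracy,
        f1=float(f1),
        precision=float(precision),
        recall=float(recall),
        kappa=cohen_kappa(y_true, y_pred),
        confusion=conf.tolist(),
        auc=auc,
        logloss=multiclass_logloss(y_true, proba),
    )


def cv_mean(values: list[float] | np.ndarray) -> tuple[float, float]:
    """(full-precision arithmetic mean, same rounded to 3 decimals)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no fold values")
    mean = float(values.mean())
    return mean, round(mean, 3)


@dataclass
class ExperimentConfig:
    k: int = 10
    balance: bool = True
    params: dict = field(default_factory=dict)  # overrides on the defaults
    search_space: SearchSpace | None = None  # None → compact space
    pso: PSOConfig | None = None
    inner_cv: int = 3
    capture_curves: bool = False


@dataclass
class CVReport:
    mode: str
    seed: int
    params: dict
    folds: list[FoldResult]
    mean: dict
    pso_history: dict | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def metrics_table(self) -> pd.DataFrame:
        """Per-fold metric table plus a mean row (per-metric CV mean)."""
        rows = [
            {
                "Fold": fr.fold + 1,
                "Accuracy": fr.accuracy,
                "F1-Score": fr.f1,
                "Precision": fr.precision,
                "Recall": fr.recall,
                "Kappa": fr.kappa,
            }
            for fr in self.folds
        ]
        mean_row = {"Fold": "Mean"}
        for key in ("Accuracy", "F1-Score", "Precision", "Recall", "Kappa"):
            mean_row[key] = cv_mean([r[key] for r in rows])[0]
        return pd.DataFrame([*rows, mean_row])


def _seed_streams(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _inner_cv_fitness(
    X: np.ndarray,
    y: np.ndarray,
    space: SearchSpace,
    base_params: dict,
    k: int,
    seed: int,
) -> Callable[[np.ndarray], float]:
    """Fitness = mean stratified k-fold accuracy of the decoded assignment."""

    plan = stratified_folds(y, k=k, seed=seed)

    def fitness(position: np.ndarray) -> float:
        assignment = decode(position, space)
        params = {**base_params, **assignment}
        accs = []
        for fold in range(k):
            tr, te = plan != fold, plan == fold
            model = train(X[tr], y[tr], params, seed=seed)
            accs.append(float(np.mean(model.predict(X[te]) == y[te])))
        return float(np.mean(accs))

    return fitness


def run_experiment(
    data: pd.DataFrame,
    mode: str = "default",
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold evaluation of the (optionally PSO-tuned) classifier.

    ``data`` is an assembled (and normally shifted) feature matrix with a
    ``stage`` label column. In ``pso`` mode the swarm search runs first, with
    fitness measured by inner stratified CV (training folds only within each
    inner split); the tuned parameters are then evaluated by the outer
    stratified k-fold loop. Training folds are oversampled to balance; test
    folds are left untouched.
    """
    if mode not in ("default", "pso"):
        raise ValueError(f"mode must be 'default' or 'pso', got {mode!r}")
    config = config or ExperimentConfig()
    cols = feature_columns(data)
    X = data[cols].to_numpy(dtype=float)
    y = data["stage"].to_numpy(dtype=int)

    fold_seed, balance_seed, train_seed, pso_seed = _seed_streams(seed, 4)

    params = {**DEFAULT_XGB_PARAMS, **config.params}
    history_payload = None
    if mode == "pso":
        space = config.search_space or compact_xgb_space()
        pso_cfg = config.pso or PSOConfig(seed=pso_seed)
        fitness = _inner_cv_fitness(
            X, y, space, params, k=config.inner_cv, seed=pso_seed
        )
        best, history = optimise(space, pso_cfg, fitness)
        params = {**params, **best}
        history_payload = {
            "iterations": history.iterations,
            "best_fitness": history.best_fitness,
            "best_position": [p.tolist() for p in history.best_position],
        }

    plan = stratified_folds(y, k=config.k, seed=fold_seed)
    folds: list[FoldResult] = []
    for fold in range(config.k):
        tr, te = plan != fold, plan == fold
        X_tr, y_tr = X[tr], y[tr]
        if config.balance:
            X_tr, y_tr = balance_training(X_tr, y_tr, seed=balance_seed + fold)
        eval_sets = [(X_tr, y_tr), (X[te], y[te])] if config.capture_curves else None
        try:
            model = train(X_tr, y_tr, params, seed=train_seed, eval_sets=eval_sets)
            proba = model.predict_proba(X[te])
            pred = proba.argmax(axis=1)
            fr = fold_metrics(y[te], pred, proba, fold=fold)
        except Exception as exc:
            raise RuntimeError(f"fold {fold + 1}/{config.k} failed") from exc
        if config.capture_curves:
            curves = model.evals_result()
            fr.train_logloss_curve = list(curves["validation_0"]["mlogloss"])
            fr.test_logloss_curve = list(curves["validation_1"]["mlogloss"])
            fr.train_error_curve = list(curves["validation_0"]["merror"])
            fr.test_error_curve = list(curves["validation_1"]["merror"])
        folds.append(fr)

    mean = {
        metric: cv_mean([getattr(f, metric) for f in folds])[0]
        for metric in ("accuracy", "f1", "precision", "recall", "kappa", "logloss")
    }
    clean_params = {
        k_: v for k_, v in params.items() if isinstance(v, (int, float, str, bool))
    }
    return CVReport(
        mode=mode,
        seed=seed,
        params=clean_params,
        folds=folds,
        mean=mean,
        pso_history=history_payload,
    )
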