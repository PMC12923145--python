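"""Classifier benchmarking: grid search inside 5-fold CV, OOF-AUC model
selection, held-out evaluation and the six-configuration feature ablation.

The classifier set is GBDT, AdaBoost, XGBoost, LightGBM, CatBoost and RF.
The XGBoost/LightGBM/CatBoost entries use the native libraries when they
are importable; otherwise each falls back to a scikit-learn gradient
boosting stand-in with that library's flavour of defaults (documented in
``CLASSIFIER_BACKENDS``).  The benchmarking contract (grid search, OOF
bookkeeping, metrics) is identical either way.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from ithkit.errors import DegenerateInputError
from ithkit.phantom_generator import DENSITY_LEVELS, LOCATION_LEVELS, SEX_LEVELS, SIGN_COLUMNS

LABEL_COLUMN = "label"
CR_COLUMNS = ("sex", "age", "size_mm", "density", "location", *SIGN_COLUMNS)
ITH2D_COLUMN = "ith2d"
ITH3D_COLUMN = "ith3d"

#: the six ablation configurations and the columns each may read
FEATURE_CONFIGURATIONS = {
    "2DITH-3DITH-CR": (ITH2D_COLUMN, ITH3D_COLUMN, *CR_COLUMNS),
    "2DITH-CR": (ITH2D_COLUMN, *CR_COLUMNS),
    "3DITH-CR": (ITH3D_COLUMN, *CR_COLUMNS),
    "CR": CR_COLUMNS,
    "2DITH": (ITH2D_COLUMN,),
    "3DITH": (ITH3D_COLUMN,),
}

DEFAULT_CLASSIFIERS = ("GBDT", "AdaBoost", "XGBoost", "LightGBM", "CatBoost", "RF")

#: small default grids; the framework, not the grid, is the contract
DEFAULT_GRIDS = {
    "GBDT": {"n_estimators": [100, 200], "max_depth": [2, 3],
             "learning_rate": [0.05, 0.1]},
    "AdaBoost": {"n_estimators": [50, 100], "learning_rate": [0.5, 1.0]},
    "XGBoost": {"n_estimators": [100, 200], "max_depth": [3, 4],
                "learning_rate": [0.1]},
    "LightGBM": {"n_estimators": [100, 200], "max_depth": [3],
                 "learning_rate": [0.05, 0.1]},
    "CatBoost": {"n_estimators": [150, 300], "max_depth": [3],
                 "learning_rate": [0.05, 0.1]},
    "RF": {"n_estimators": [100, 300], "max_depth": [None, 6]},
}


def _make_xgboost(seed, **params):
    try:
        from xgboost import XGBClassifier
    except ImportError:
        return GradientBoostingClassifier(random_state=seed, subsample=0.9, **params)
    return XGBClassifier(random_state=seed, eval_metric="logloss", **params)


def _make_lightgbm(seed, **params):
    try:
        from lightgbm import LGBMClassifier
    except ImportError:
        params = dict(params)
        params.setdefault("max_features", "sqrt")
        return GradientBoostingClassifier(random_state=seed, **params)
    return LGBMClassifier(random_state=seed, verbosity=-1, **params)


def _make_catboost(seed, **params):
    try:
        from catboost import CatBoostClassifier
    except ImportError:
        params = dict(params)
        params.setdefault("min_samples_leaf", 3)
        return GradientBoostingClassifier(random_state=seed, **params)
    return CatBoostClassifier(random_seed=seed, verbose=0,
                              depth=params.pop("max_depth", 3),
                              iterations=params.pop("n_estimators", 300), **params)


def _make_adaboost(seed, **params):
    return AdaBoostClassifier(random_state=seed, **params)


_FACTORIES = {
    "GBDT": lambda seed, **p: GradientBoostingClassifier(random_state=seed, **p),
    "AdaBoost": _make_adaboost,
    "XGBoost": _make_xgboost,
    "LightGBM": _make_lightgbm,
    "CatBoost": _make_catboost,
    "RF": lambda seed, **p: RandomForestClassifier(random_state=seed, **p),
}


def classifier_backends() -> dict:
    """Which backend implements each classifier in this environment."""
    out = {}
    for name in DEFAULT_CLASSIFIERS:
        model = _FACTORIES[name](0)
        out[name] = type(model).__module__.split(".")[0]
    return out


CLASSIFIER_BACKENDS = classifier_backends()


@dataclass(frozen=True)
class BenchConfig:
    """Bench settings: classifier set, grids, CV layout and feature set."""

    classifiers: tuple = DEFAULT_CLASSIFIERS
    grids: dict = field(default_factory=lambda: dict(DEFAULT_GRIDS))
    cv_folds: int = 5
    train_ratio: float = 0.7
    seed: int = 0
    feature_configuration: str = "2DITH-3DITH-CR"
    average: str = "weighted"  # precision/recall/F1 averaging mode

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.feature_configuration not in FEATURE_CONFIGURATIONS:
            raise ValueError(
                f"unknown feature configuration {self.feature_configuration!r}; "
                f"choose from {sorted(FEATURE_CONFIGURATIONS)}"
            )
        unknown = set(self.classifiers) - set(_FACTORIES)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------

_SEX_CODE = {s: i for i, s in enumerate(SEX_LEVELS)}
_DENSITY_CODE = {d: i for i, d in enumerate(DENSITY_LEVELS)}  # ordinal by density
_LOCATION_CODE = {l: i for i, l in enumerate(LOCATION_LEVELS)}


def encode_features(cohort: pd.DataFrame, configuration: str) -> pd.DataFrame:
    """Numeric design matrix restricted to the configuration's columns.

    The returned frame contains only the allowed columns, so a model fit on
    it can structurally never read data outside its configuration.
    """
    columns = FEATURE_CONFIGURATIONS[configuration]
    out = {}
    for col in columns:
        values = cohort[col]
        if col == "sex":
            out[col] = values.map(_SEX_CODE).astype(float)
        elif col == "density":
            out[col] = values.map(_DENSITY_CODE).astype(float)
        elif col == "location":
            out[col] = values.map(_LOCATION_CODE).astype(float)
        else:
            out[col] = values.astype(float)
    return pd.DataFrame(out, index=cohort.index)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def stratified_split(cohort: pd.DataFrame, ratio: float = 0.7, seed: int = 0):
    """Disjoint, exhaustive stratified train/test split by the label column."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must be in (0, 1), got {ratio}")
    y = cohort[LABEL_COLUMN]
    counts = y.value_counts()
    if len(counts) < 2:
        raise DegenerateInputError("both classes must be present for a split")
    if counts.min() < 2:
        raise DegenerateInputError("each class needs at least 2 members")
    train, test = train_test_split(cohort, train_size=ratio, stratify=y,
                                   random_state=seed)
    return train, test


def _grid_points(grid: dict):
    if not grid:
        yield {}
        return
    keys = sorted(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _oof_predictions(name, params, X, y, folds, seed):
    """Out-of-fold probability vector and per-fold AUCs; one prediction per row."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    for tr_idx, va_idx in skf.split(X, y):
        if len(np.unique(y[va_idx])) < 2:  # pragma: no cover - stratified guard
            raise DegenerateInputError("degenerate single-class CV fold")
        model = _FACTORIES[name](seed, **params)
        model.fit(X[tr_idx], y[tr_idx])
        proba = model.predict_proba(X[va_idx])[:, 1]
        oof[va_idx] = proba
        fold_aucs.append(roc_auc_score(y[va_idx], proba))
    assert not np.isnan(oof).any(), "OOF predictions must cover every row exactly once"
    return oof, fold_aucs


def tune_and_fit(train: pd.DataFrame, config: BenchConfig) -> dict:
    """Grid search each classifier inside stratified 5-fold CV.

    Returns ``{classifier: {"model", "best_params", "mean_oof_auc",
    "oof_predictions"}}``; the best grid point maximizes the mean of the
    per-fold hold-out AUCs and the winning model is refit on the full
    training part.
    """
    y = train[LABEL_COLUMN].to_numpy()
    if min(np.bincount(y)) < config.cv_folds:
        raise DegenerateInputError(
            f"need >= {config.cv_folds} members per class for {config.cv_folds}-fold CV"
        )
    X = encode_features(train, config.feature_configuration).to_numpy()

    report = {}
    for name in config.classifiers:
        best = None
        for params in _grid_points(config.grids.get(name, {})):
            oof, fold_aucs = _oof_predictions(name, params, X, y,
                                              config.cv_folds, config.seed)
            mean_auc = float(np.mean(fold_aucs))
            if best is None or mean_auc > best["mean_oof_auc"]:
                best = {"best_params": params, "mean_oof_auc": mean_auc,
                        "oof_predictions": oof}
        model = _FACTORIES[name](config.seed, **best["best_params"])
        model.fit(X, y)
        best["model"] = model
        report[name] = best
    return report


def evaluate(model, part: pd.DataFrame, configuration: str = "2DITH-3DITH-CR",
             average: str = "weighted") -> dict:
    """AUC from probabilities plus thresholded accuracy/precision/recall/F1."""
    if len(part) == 0:
        raise DegenerateInputError("evaluation part is empty")
    y = part[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("AUC undefined on a single-class part")
    X = encode_features(part, configuration).to_numpy()
    proba = model.predict_proba(X)[:, 1]
    pred = (proba >= 0.5).astype(int)
    return {
        "auc": float(roc_auc_score(y, proba)),
        "accuracy": float(accuracy_score(y, pred)),
        "precision": float(precision_score(y, pred, average=average,
                                           zero_division=0)),
        "recall": float(recall_score(y, pred, average=average, zero_division=0)),
        "f1": float(f1_score(y, pred, average=average, zero_division=0)),
    }


def run_bench(cohort: pd.DataFrame, config: BenchConfig) -> dict:
    """Split, tune every classifier, evaluate on the held-out part and pick
    the best model by test AUC (ties: mean of the remaining metrics)."""
    train, test = stratified_split(cohort, config.train_ratio, config.seed)
    fits = tune_and_fit(train, config)
    results = {}
    for name, fit in fits.items():
        metrics = evaluate(fit["model"], test, config.feature_configuration,
                           config.average)
        results[name] = {
            "best_params": fit["best_params"],
            "mean_oof_auc": fit["mean_oof_auc"],
            "test": metrics,
        }
    best = max(
        results,
        key=lambda n: (results[n]["test"]["auc"],
                       np.mean([v for k, v in results[n]["test"].items() if k != "auc"])),
    )
    return {"per_classifier": results, "best_classifier": best,
            "configuration": config.feature_configuration,
            "n_train": len(train), "n_test": len(test)}


def ablation_study(cohort: pd.DataFrame, config: BenchConfig,
                   classifier: str | None = None) -> dict:
    """Tune/evaluate one classifier across all six feature configurations
    with a shared split and seed."""
    if classifier is None:
        classifier = "CatBoost"
    train, test = stratified_split(cohort, config.train_ratio, config.seed)
    rows = {}
    for configuration in FEATURE_CONFIGURATIONS:
        cfg = replace(config, feature_configuration=configuration,
                      classifiers=(classifier,))
        fit = tune_and_fit(train, cfg)[classifier]
        rows[configuration] = {
            "best_params": fit["best_params"],
            "mean_oof_auc": fit["mean_oof_auc"],
            "test": evaluate(fit["model"], test, configuration, config.average),
        }
    return {"classifier": classifier, "per_configuration": rows,
            "n_train": len(train), "n_test": len(test)}


def compare_groups(scores, labels):
    """Two-sided rank-sum comparison of scores between the two classes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups = [scores[labels == v] for v in np.unique(labels)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise DegenerateInputError("need exactly two non-empty groups")
    if any(len(g) < 3 for g in groups):
        raise DegenerateInputError("need >= 3 observations per group")
    stat, p = mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                           method="asymptotic")
    return float(stat), float(p)
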