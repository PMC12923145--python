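"""SHAP-guided forward feature selection.

Phase 1 ranks features per classifier by global importance (mean absolute
SHAP value over the cohort) and records the 5-fold CV AUC of every ranked
feature prefix.  Phase 2 selects the classifier with the consistently
highest AUC trajectory (operationalized as the highest mean AUC over
prefixes, ties broken by the full-feature AUC).  Phase 3 scans the selected
trajectory for the first prefix length whose marginal AUC gain drops to
``epsilon`` or below (the knee point); if no gain ever drops that low the
full feature set is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ithkit import _treeshap
from ithkit.errors import DegenerateInputError, UnsupportedModelError
from ithkit.model_bench import (
    LABEL_COLUMN,
    BenchConfig,
    _FACTORIES,
    _oof_predictions,
    encode_features,
)


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ranked by global importance I_i = mean_j |phi_i(j)|."""

    features: tuple  # all input feature names, original order
    importances: tuple  # I_i per feature, original order
    order: tuple  # feature names in descending importance

    def __post_init__(self):
        if set(self.order) != set(self.features):
            raise ValueError("ranking must be a permutation of the features")
        if any(i < 0 for i in self.importances):
            raise ValueError("importances must be non-negative")


@dataclass(frozen=True)
class SelectionTrajectory:
    """Prefix AUCs for one classifier over a SHAP ranking."""

    classifier: str
    ranking: ImportanceRanking
    aucs: tuple  # mean OOF AUC for prefixes of length 1..N

    def prefix(self, i: int) -> tuple:
        return self.ranking.order[:i]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def global_importance(model, data, feature_names=None) -> ImportanceRanking:
    """Rank features of a fitted tree-ensemble model by mean |SHAP|.

    Ties are broken by original column order (stable sort on descending
    importance).
    """
    if isinstance(data, pd.DataFrame):
        if feature_names is None:
            feature_names = tuple(data.columns)
        data = data.to_numpy()
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise DegenerateInputError("data is empty")
    if not _treeshap.supports_model(model):
        raise UnsupportedModelError(
            f"{type(model).__name__} is not a supported tree-ensemble model"
        )
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(data.shape[1]))
    phi, _ = _treeshap.shap_values(model, data)
    importances = np.abs(phi).mean(axis=0)
    order_idx = np.argsort(-importances, kind="stable")
    return ImportanceRanking(
        features=tuple(feature_names),
        importances=tuple(float(v) for v in importances),
        order=tuple(feature_names[i] for i in order_idx),
    )


def trajectory(classifier: str, ranking: ImportanceRanking, train: pd.DataFrame,
               seed: int = 0, params: dict | None = None, cv_folds: int = 5,
               configuration: str = "2DITH-3DITH-CR") -> SelectionTrajectory:
    """Mean OOF AUC of ``classifier`` refit on every ranked feature prefix."""
    y = train[LABEL_COLUMN].to_numpy()
    X_all = encode_features(train, configuration)
    missing = set(ranking.features) - set(X_all.columns)
    if missing:
        raise ValueError(f"ranking names features absent from the cohort: {missing}")
    params = params or {}
    aucs = []
    for i in range(1, len(ranking.order) + 1):
        X = X_all[list(ranking.order[:i])].to_numpy()
        _, fold_aucs = _oof_predictions(classifier, params, X, y, cv_folds, seed)
        aucs.append(float(np.mean(fold_aucs)))
    return SelectionTrajectory(classifier=classifier, ranking=ranking,
                               aucs=tuple(aucs))


def select_best(trajectories) -> SelectionTrajectory:
    """The trajectory with the highest mean AUC over prefixes.

    Ties break on the AUC at the full feature set, then on classifier name
    for determinism.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise DegenerateInputError("no trajectories given")
    lengths = {len(t.aucs) for t in trajectories}
    if len(lengths) != 1:
        raise ValueError("trajectories cover different prefix sets")
    return max(trajectories,
               key=lambda t: (t.mean_auc, t.aucs[-1], t.classifier))


def find_knee(traj, epsilon: float = 0.0) -> int:
    """First prefix length ``l`` whose gain ``AUC[l+1]-AUC[l] <= epsilon``.

    Returns ``N`` (the full length) when every marginal gain exceeds
    ``epsilon``, i.e. the scan exits without a knee.
    """
    aucs = traj.aucs if isinstance(traj, SelectionTrajectory) else tuple(traj)
    if len(aucs) < 2:
        raise DegenerateInputError("trajectory must have length >= 2")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    for l in range(1, len(aucs)):
        if aucs[l] - aucs[l - 1] <= epsilon:
            return l
    return len(aucs)


def run_selection(cohort: pd.DataFrame, config: BenchConfig,
                  epsilon: float = 0.0, shap_samples: int | None = None) -> dict:
    """End-to-end Phase 1-3 over the configured classifier set.

    Each classifier is fit on all features of the configuration, ranked by
    its own SHAP importances, and traced over ranked prefixes.  Classifiers
    whose fitted model the SHAP engine cannot decompose (e.g. a non-sklearn
    backend) are skipped with a note.  ``shap_samples`` optionally caps the
    number of (seeded, subsampled) rows used for the importance pass.
    """
    from ithkit.model_bench import stratified_split

    train, test = stratified_split(cohort, config.train_ratio, config.seed)
    y = train[LABEL_COLUMN].to_numpy()
    X = encode_features(train, config.feature_configuration)
    shap_X = X.to_numpy()
    if shap_samples is not None and shap_samples < len(shap_X):
        idx = np.random.default_rng(config.seed).choice(len(shap_X), shap_samples,
                                                        replace=False)
        shap_X = shap_X[idx]

    trajectories, skipped = [], {}
    for name in config.classifiers:
        grid = config.grids.get(name, {})
        params = {k: v[0] for k, v in grid.items()}  # first grid point
        model = _FACTORIES[name](config.seed, **params)
        model.fit(X.to_numpy(), y)
        try:
            ranking = global_importance(model, shap_X, tuple(X.columns))
        except UnsupportedModelError as exc:
            skipped[name] = str(exc)
            continue
        trajectories.append(
            trajectory(name, ranking, train, seed=config.seed, params=params,
                       cv_folds=config.cv_folds,
                       configuration=config.feature_configuration)
        )
    if not trajectories:
        raise DegenerateInputError("no classifier produced a SHAP trajectory")
    best = select_best(trajectories)
    knee = find_knee(best, epsilon)
    return {
        "trajectories": {t.classifier: t for t in trajectories},
        "skipped": skipped,
        "best_classifier": best.classifier,
        "knee": knee,
        "optimal_subset": best.prefix(knee),
        "epsilon": epsilon,
    }
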