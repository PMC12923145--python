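"""Path-dependent TreeSHAP for scikit-learn tree ensembles.

Computes exact Shapley values of the game ``v(S) = E[f(x) | x_S]`` where the
conditional expectation follows tree paths weighted by training cover (node
sample weights).  The implementation follows the polynomial-time
extend/unwind recursion for tree ensembles, vectorized across samples: the
recursion structure (which nodes are visited, which path element carries
which feature) is identical for every sample, so the per-path zero/one
fractions and weights are carried as arrays over the sample axis.

Supported models: GradientBoostingClassifier (binary; attributions on the
log-odds margin), RandomForestClassifier (positive-class probability),
AdaBoostClassifier (SAMME decision function), and single decision trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from ithkit.errors import UnsupportedModelError


@dataclass
class _Tree:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray  # scalar model output per node (leaf values used)
    cover: np.ndarray  # weighted sample count per node

    @property
    def expected_value(self) -> float:
        """Cover-weighted mean output = E[f] over the tree's distribution."""
        leaves = self.children_left < 0
        return float(np.sum(self.value[leaves] * self.cover[leaves]) / self.cover[0])


def _safe_div(num, den):
    return num / np.where(den == 0, 1.0, den)


class _PathState:
    """Vectorized extend/unwind path bookkeeping.

    ``d`` is structural (same for all samples); ``z``, ``o``, ``w`` hold one
    value per sample per path element.
    """

    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d, z, o, w):
        self.d, self.z, self.o, self.w = d, z, o, w

    @classmethod
    def empty(cls, n):
        return cls([], [], [], [])

    def copy(self):
        return _PathState(list(self.d), [v.copy() for v in self.z],
                          [v.copy() for v in self.o], [v.copy() for v in self.w])

    def extend(self, pz, po, pi):
        l = len(self.d)
        self.d.append(pi)
        self.z.append(np.asarray(pz, dtype=float).copy())
        self.o.append(np.asarray(po, dtype=float).copy())
        self.w.append(np.ones_like(self.z[-1]) if l == 0 else np.zeros_like(self.z[-1]))
        for i in range(l - 1, -1, -1):
            self.w[i + 1] += po * self.w[i] * (i + 1) / (l + 1)
            self.w[i] = pz * self.w[i] * (l - i) / (l + 1)

    def unwind(self, i):
        l = len(self.d) - 1
        o_i, z_i = self.o[i], self.z[i]
        has_o = o_i != 0
        n = self.w[l].copy()
        for j in range(l - 1, -1, -1):
            t = self.w[j].copy()
            with_o = n * (l + 1) / ((j + 1) * np.where(has_o, o_i, 1.0))
            without_o = t * (l + 1) * _safe_div(np.ones_like(t), z_i * (l - j))
            self.w[j] = np.where(has_o, with_o, without_o)
            n = np.where(has_o, t - self.w[j] * z_i * (l - j) / (l + 1), n)
        # recomputed weights occupy indices 0..l-1: drop the last weight,
        # while the structural attributes shift down from position i
        del self.d[i], self.z[i], self.o[i], self.w[-1]

    def unwound_sum(self, i):
        l = len(self.d) - 1
        o_i, z_i = self.o[i], self.z[i]
        has_o = o_i != 0
        n = self.w[l].copy()
        total = np.zeros_like(n)
        for j in range(l - 1, -1, -1):
            with_o = n * (l + 1) / ((j + 1) * np.where(has_o, o_i, 1.0))
            without_o = self.w[j] * (l + 1) * _safe_div(np.ones_like(n), z_i * (l - j))
            total += np.where(has_o, with_o, without_o)
            n = np.where(has_o, self.w[j] - with_o * z_i * (l - j) / (l + 1), n)
        return total


def _tree_shap(tree: _Tree, X: np.ndarray, phi: np.ndarray) -> None:
    """Accumulate per-sample attributions of one tree into ``phi``."""
    n = X.shape[0]
    ones = np.ones(n)

    def recurse(node, state: _PathState, pz, po, pi):
        state = state.copy()
        state.extend(pz, po, pi)
        left = tree.children_left[node]
        if left < 0:  # leaf
            for i in range(1, len(state.d)):  # element 0 is the root dummy
                w = state.unwound_sum(i)
                phi[:, state.d[i]] += w * (state.o[i] - state.z[i]) * tree.value[node]
            return
        right = tree.children_right[node]
        feat = int(tree.feature[node])
        goes_left = X[:, feat] <= tree.threshold[node]
        iz, io = ones, ones
        try:
            k = state.d.index(feat)
        except ValueError:
            k = -1
        if k >= 0:
            iz, io = state.z[k], state.o[k]
            state.unwind(k)
        r_node = tree.cover[node]
        recurse(left, state, iz * tree.cover[left] / r_node,
                np.where(goes_left, io, 0.0), feat)
        recurse(right, state, iz * tree.cover[right] / r_node,
                np.where(goes_left, 0.0, io), feat)

    recurse(0, _PathState.empty(n), ones, ones, -1)


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------

def _from_sklearn_tree(t, value):
    return _Tree(
        children_left=t.children_left,
        children_right=t.children_right,
        feature=t.feature,
        threshold=t.threshold,
        value=np.asarray(value, dtype=float),
        cover=t.weighted_n_node_samples,
    )


def _extract_trees(model):
    """Return (trees, constant_offset, output description)."""
    if isinstance(model, GradientBoostingClassifier):
        if model.n_classes_ != 2:
            raise UnsupportedModelError("only binary classifiers are supported")
        lr = model.learning_rate
        trees = [_from_sklearn_tree(e.tree_, e.tree_.value[:, 0, 0] * lr)
                 for e in model.estimators_[:, 0]]
        # the raw prediction is init + lr * sum(tree outputs); recover the
        # constant init term from the additive decomposition at one point
        probe = np.zeros((1, model.n_features_in_))
        raw = model.decision_function(probe)[0]
        offset = raw - sum(_leaf_output(t, probe[0]) for t in trees)
        return trees, float(offset), "log-odds margin"
    if isinstance(model, RandomForestClassifier):
        if model.n_classes_ != 2:
            raise UnsupportedModelError("only binary classifiers are supported")
        trees = []
        for e in model.estimators_:
            counts = e.tree_.value[:, 0, :]
            p1 = counts[:, 1] / np.maximum(counts.sum(axis=1), 1e-300)
            trees.append(_from_sklearn_tree(e.tree_, p1 / model.n_estimators))
        return trees, 0.0, "positive-class probability"
    if isinstance(model, AdaBoostClassifier):
        if len(model.classes_) != 2:
            raise UnsupportedModelError("only binary classifiers are supported")
        weights = model.estimator_weights_
        norm = weights.sum()
        trees = []
        for e, w in zip(model.estimators_, weights):
            counts = e.tree_.value[:, 0, :]
            sign = 2.0 * np.argmax(counts, axis=1) - 1.0  # SAMME vote +-1
            # sklearn's binary decision_function counts each vote twice
            # (matched class +w, other class -w, then the sign flip + sum)
            trees.append(_from_sklearn_tree(e.tree_, 2.0 * sign * w / norm))
        return trees, 0.0, "SAMME decision function"
    if isinstance(model, DecisionTreeRegressor):
        return [_from_sklearn_tree(model.tree_, model.tree_.value[:, 0, 0])], 0.0, "prediction"
    if isinstance(model, DecisionTreeClassifier):
        if model.n_classes_ != 2:
            raise UnsupportedModelError("only binary classifiers are supported")
        counts = model.tree_.value[:, 0, :]
        p1 = counts[:, 1] / np.maximum(counts.sum(axis=1), 1e-300)
        return [_from_sklearn_tree(model.tree_, p1)], 0.0, "positive-class probability"
    raise UnsupportedModelError(
        f"no tree-SHAP adapter for model type {type(model).__name__}"
    )


def _leaf_output(tree: _Tree, x):
    node = 0
    while tree.children_left[node] >= 0:
        if x[int(tree.feature[node])] <= tree.threshold[node]:
            node = tree.children_left[node]
        else:
            node = tree.children_right[node]
    return tree.value[node]


def supports_model(model) -> bool:
    try:
        _extract_trees(model)
        return True
    except UnsupportedModelError:
        return False


def shap_values(model, X):
    """Per-sample feature attributions and the base (expected) value.

    Returns ``(phi, base)`` with ``phi`` of shape ``(n_samples, n_features)``
    satisfying local accuracy: ``phi.sum(1) + base`` equals the model output
    on its attribution scale (margin or probability, see ``_extract_trees``).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2D array")
    trees, offset, _ = _extract_trees(model)
    phi = np.zeros_like(X, dtype=float)
    for tree in trees:
        _tree_shap(tree, X, phi)
    base = offset + sum(t.expected_value for t in trees)
    return phi, float(base)


def model_output(model, X):
    """The model output on the scale that ``shap_values`` decomposes."""
    if isinstance(model, (GradientBoostingClassifier, AdaBoostClassifier)):
        return model.decision_function(X)
    if isinstance(model, (RandomForestClassifier, DecisionTreeClassifier)):
        return model.predict_proba(X)[:, 1]
    if isinstance(model, DecisionTreeRegressor):
        return model.predict(X)
    raise UnsupportedModelError(type(model).__name__)
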