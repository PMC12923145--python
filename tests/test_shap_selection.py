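import itertools
import math

import numpy as np
import pytest
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeRegressor

from ithkit import _treeshap
from ithkit.errors import DegenerateInputError, UnsupportedModelError
from ithkit.model_bench import BenchConfig, stratified_split
from ithkit.phantom_generator import generate_cohort
from ithkit.shap_selection import (
    ImportanceRanking,
    SelectionTrajectory,
    find_knee,
    global_importance,
    run_selection,
    select_best,
    trajectory,
)


# ---------------------------------------------------------------------------
# TreeSHAP engine
# ---------------------------------------------------------------------------

def _binary_data(rng, n=150, m=5):
    X = rng.normal(size=(n, m))
    y = (X[:, 0] + 0.6 * X[:, 1] + rng.normal(0, 0.4, n) > 0).astype(int)
    return X, y


def _cond_exp(tree, x, S, node=0):
    """Path-dependent conditional expectation, by direct recursion."""
    if tree.children_left[node] < 0:
        return tree.value[node]
    f = int(tree.feature[node])
    left, right = tree.children_left[node], tree.children_right[node]
    if f in S:
        nxt = left if x[f] <= tree.threshold[node] else right
        return _cond_exp(tree, x, S, nxt)
    return (tree.cover[left] * _cond_exp(tree, x, S, left)
            + tree.cover[right] * _cond_exp(tree, x, S, right)) / tree.cover[node]


def _brute_shapley(tree, x, n_features):
    """Exact Shapley values by subset enumeration (the independent oracle)."""
    phi = np.zeros(n_features)
    for i in range(n_features):
        rest = [f for f in range(n_features) if f != i]
        for k in range(len(rest) + 1):
            for S in itertools.combinations(rest, k):
                weight = (math.factorial(k) * math.factorial(n_features - k - 1)
                          / math.factorial(n_features))
                phi[i] += weight * (_cond_exp(tree, x, set(S) | {i})
                                    - _cond_exp(tree, x, set(S)))
    return phi


class TestTreeShap:
    def test_matches_brute_force_shapley(self, rng):
        for trial in range(15):
            X = rng.normal(size=(50, 4))
            y = rng.normal(size=50)
            model = DecisionTreeRegressor(max_depth=4, random_state=trial).fit(X, y)
            tree = _treeshap._extract_trees(model)[0][0]
            xs = rng.normal(size=(3, 4))
            phi, _ = _treeshap.shap_values(model, xs)
            for j in range(3):
                np.testing.assert_allclose(phi[j], _brute_shapley(tree, xs[j], 4),
                                           atol=1e-10)

    @pytest.mark.parametrize("factory", [
        lambda: GradientBoostingClassifier(n_estimators=25, max_depth=3,
                                           random_state=0),
        lambda: RandomForestClassifier(n_estimators=15, max_depth=4,
                                       random_state=0),
        lambda: AdaBoostClassifier(n_estimators=15, random_state=0),
    ])
    def test_local_accuracy(self, rng, factory):
        X, y = _binary_data(rng)
        model = factory().fit(X, y)
        phi, base = _treeshap.shap_values(model, X[:40])
        out = _treeshap.model_output(model, X[:40])
        np.testing.assert_allclose(phi.sum(axis=1) + base, out, atol=1e-6)

    def test_unsupported_model(self, rng):
        X, y = _binary_data(rng)
        model = LogisticRegression().fit(X, y)
        with pytest.raises(UnsupportedModelError):
            _treeshap.shap_values(model, X[:5])


# ---------------------------------------------------------------------------
# global importance and ranking
# ---------------------------------------------------------------------------

class TestGlobalImportance:
    def test_mean_absolute_definition(self, rng):
        X, y = _binary_data(rng)
        model = GradientBoostingClassifier(n_estimators=20, random_state=0).fit(X, y)
        phi, _ = _treeshap.shap_values(model, X[:60])
        ranking = global_importance(model, X[:60])
        np.testing.assert_allclose(ranking.importances,
                                   np.abs(phi).mean(axis=0))
        assert list(ranking.order) == [
            ranking.features[i]
            for i in np.argsort(-np.asarray(ranking.importances), kind="stable")
        ]

    def test_simple_average_example(self):
        # mean(|0.2|, |-0.4|) = 0.3, per the definition
        assert np.mean(np.abs([0.2, -0.4])) == pytest.approx(0.3)

    def test_non_tree_model_rejected(self, rng):
        X, y = _binary_data(rng)
        model = LogisticRegression().fit(X, y)
        with pytest.raises(UnsupportedModelError):
            global_importance(model, X)

    def test_duplicating_samples_keeps_ranking(self, rng):
        X, y = _binary_data(rng)
        model = GradientBoostingClassifier(n_estimators=20, random_state=0).fit(X, y)
        r1 = global_importance(model, X)
        r2 = global_importance(model, np.vstack([X, X]))
        assert r1.order == r2.order
        np.testing.assert_allclose(r1.importances, r2.importances)

    def test_injected_informative_feature_ranks_first(self, rng):
        hits = 0
        reps = 60
        for s in range(reps):
            rs = np.random.default_rng(s)
            X = rs.normal(size=(250, 6))
            y = rs.integers(0, 2, 250)
            X[:, 2] = y + rs.normal(0, 0.3, 250)  # the only informative column
            model = GradientBoostingClassifier(n_estimators=30, max_depth=2,
                                               random_state=s).fit(X, y)
            ranking = global_importance(model, X)
            hits += ranking.order[0] == "f2"
        assert hits >= 0.95 * reps

    def test_ranking_invariants(self):
        with pytest.raises(ValueError):
            ImportanceRanking(features=("a", "b"), importances=(1.0, 0.5),
                              order=("a", "c"))
        with pytest.raises(ValueError):
            ImportanceRanking(features=("a",), importances=(-0.1,), order=("a",))


# ---------------------------------------------------------------------------
# trajectories, selection, knee
# ---------------------------------------------------------------------------

def _traj(name, aucs):
    n = len(aucs)
    ranking = ImportanceRanking(features=tuple(f"f{i}" for i in range(n)),
                                importances=tuple(float(n - i) for i in range(n)),
                                order=tuple(f"f{i}" for i in range(n)))
    return SelectionTrajectory(classifier=name, ranking=ranking, aucs=tuple(aucs))


@pytest.fixture(scope="module")
def trajectory_setup():
    df = generate_cohort(300, effect=1.2, seed=1)
    train, _ = stratified_split(df, 0.7, seed=0)
    from ithkit.model_bench import encode_features

    X = encode_features(train, "2DITH-3DITH-CR")
    model = GradientBoostingClassifier(n_estimators=40, max_depth=2,
                                       random_state=0)
    model.fit(X.to_numpy(), train["label"].to_numpy())
    ranking = global_importance(model, X)
    traj = trajectory("GBDT", ranking, train, seed=0,
                      params={"n_estimators": 40, "max_depth": 2})
    return ranking, traj


class TestTrajectory:
    def test_length_and_nesting(self, trajectory_setup):
        ranking, traj = trajectory_setup
        assert len(traj.aucs) == len(ranking.features)
        for i in range(1, len(traj.aucs)):
            assert set(traj.prefix(i)) < set(traj.prefix(i + 1))

    def test_dominant_feature_explains_most_auc(self):
        df = generate_cohort(400, effect=0.0, seed=3)
        rs = np.random.default_rng(3)
        df["ith3d"] = np.clip(df["label"] * 0.5 + rs.normal(0.25, 0.1, len(df)),
                              0, 0.999)
        train, _ = stratified_split(df, 0.7, seed=0)
        from ithkit.model_bench import encode_features

        X = encode_features(train, "2DITH-3DITH-CR")
        model = GradientBoostingClassifier(n_estimators=40, max_depth=2,
                                           random_state=0)
        model.fit(X.to_numpy(), train["label"].to_numpy())
        ranking = global_importance(model, X)
        assert ranking.order[0] == "ith3d"
        traj = trajectory("GBDT", ranking, train, seed=0,
                          params={"n_estimators": 40, "max_depth": 2})
        assert traj.aucs[0] >= traj.aucs[-1] - 0.05


class TestSelectBest:
    def test_dominating_trajectory_selected(self):
        best = select_best([_traj("a", [0.6, 0.7, 0.8]),
                            _traj("b", [0.7, 0.8, 0.9])])
        assert best.classifier == "b"

    def test_tie_breaks_deterministically(self):
        best = select_best([_traj("b", [0.6, 0.7]), _traj("a", [0.6, 0.7])])
        assert best.classifier == "b"  # name order as the final tiebreak

    def test_mostly_dominant_higher_mean_wins(self):
        a = _traj("a", [0.70, 0.72, 0.74, 0.76, 0.90])
        b = _traj("b", [0.73, 0.75, 0.77, 0.79, 0.81])
        assert select_best([a, b]).classifier == "b"

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            select_best([])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            select_best([_traj("a", [0.5, 0.6]), _traj("b", [0.5, 0.6, 0.7])])


class TestFindKnee:
    def test_canonical_plateau(self):
        assert find_knee(_traj("c", [0.5, 0.8, 0.85, 0.85, 0.85]), 0.0) == 3

    def test_immediate_decrease(self):
        assert find_knee(_traj("c", [0.7, 0.6, 0.65]), 0.0) == 1

    def test_strictly_increasing_returns_n(self):
        assert find_knee(_traj("c", [0.5, 0.6, 0.7, 0.8]), 0.0) == 4

    def test_epsilon_threshold(self):
        aucs = [0.5, 0.6, 0.64, 0.70]
        assert find_knee(_traj("c", aucs), 0.045) == 2
        assert find_knee(_traj("c", aucs), 0.0) == 4

    def test_monotone_in_epsilon(self, rng):
        for _ in range(50):
            aucs = rng.random(8).tolist()
            knees = [find_knee(_traj("c", aucs), e)
                     for e in sorted(rng.random(5), reverse=True)]
            assert all(a >= b for a, b in zip(knees[1:], knees))

    def test_short_trajectory_rejected(self):
        with pytest.raises(DegenerateInputError):
            find_knee(_traj("c", [0.5]), 0.0)


class TestRunSelection:
    def test_end_to_end_ith3d_dominates(self):
        df = generate_cohort(500, effect=1.5, seed=5)
        config = BenchConfig(
            classifiers=("CatBoost", "RF"),
            grids={"CatBoost": {"n_estimators": [60], "max_depth": [2]},
                   "RF": {"n_estimators": [60], "max_depth": [4]}},
            seed=5,
        )
        result = run_selection(df, config, shap_samples=150)
        assert result["best_classifier"] in ("CatBoost", "RF")
        best = result["trajectories"][result["best_classifier"]]
        assert best.ranking.order[0] == "ith3d"
        assert 1 <= result["knee"] <= len(best.ranking.features)
        assert result["optimal_subset"] == best.prefix(result["knee"])
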