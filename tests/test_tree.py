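"""The weighted-Gini CART: split search, growth, prediction, CV loss."""

import numpy as np
import pytest

from rnflasym.metrics import feature_labels_binary, feature_matrix
from rnflasym.screening import confusion
from rnflasym.tree import (
    DecisionTree,
    TrainConfig,
    best_split,
    cv_classification_loss,
    grow_tree,
    observation_weights,
    stratified_folds,
    training_loss,
    weighted_gini,
)

from .oracles import best_stump_gain, optimal_tree_loss, random_instance


# ---------------------------------------------------------------- gini
@pytest.mark.parametrize(
    "sums, expected",
    [((1.0, 1.0), 0.5), ((3.0, 0.0), 0.0), ((0.0, 2.0), 0.0), ((1.0, 1.5), 0.48)],
)
def test_weighted_gini_values(sums, expected):
    assert weighted_gini(sums) == pytest.approx(expected, abs=1e-12)


def test_weighted_gini_rejects_empty_node():
    with pytest.raises(ValueError):
        weighted_gini((0.0, 0.0))


# ---------------------------------------------------------------- split
def test_best_split_hand_example():
    X = np.array([[0.01], [0.02], [0.30], [0.40]])
    y = np.array([0, 0, 1, 1])
    w = np.full(4, 0.25)
    j, thr, gain = best_split(X, y, w)
    assert j == 0
    assert thr == pytest.approx(0.16)
    assert gain == pytest.approx(0.5)


def test_best_split_pure_node_returns_none():
    X = np.array([[1.0], [2.0], [3.0]])
    assert best_split(X, np.zeros(3, dtype=int), np.full(3, 1 / 3)) is None


def test_best_split_constant_features_returns_none():
    X = np.ones((4, 2))
    y = np.array([0, 1, 0, 1])
    assert best_split(X, y, np.full(4, 0.25)) is None


def test_best_split_prefers_perfect_separator():
    # feature 0 separates partially, feature 1 perfectly
    X = np.array([[0.1, 0.1], [0.2, 0.2], [0.15, 0.8], [0.9, 0.9]])
    y = np.array([0, 0, 1, 1])
    j, thr, _ = best_split(X, y, np.full(4, 0.25))
    assert j == 1
    assert thr == pytest.approx(0.5)


def test_best_split_matches_reference_cart_gain():
    """Root impurity decrease equals scikit-learn's on random instances."""
    sklearn = pytest.importorskip("sklearn.tree")
    rng = np.random.default_rng(7)
    for _ in range(100):
        X, y = random_instance(rng, n_lo=4, n_hi=12)
        wg = float(rng.choice([1.0, 1.5, 2.0]))
        w = observation_weights(y, (1.0, wg))
        ours = best_split(X, y, w)
        clf = sklearn.DecisionTreeClassifier(criterion="gini", max_depth=1)
        clf.fit(X, y, sample_weight=w)
        t = clf.tree_
        if ours is None:
            assert t.node_count == 1
            continue
        w_root = t.weighted_n_node_samples[0]
        sk_gain = t.impurity[0] - (
            t.weighted_n_node_samples[1] * t.impurity[1]
            + t.weighted_n_node_samples[2] * t.impurity[2]
        ) / w_root
        assert ours[2] == pytest.approx(float(sk_gain), abs=1e-10)


def test_stump_attains_enumeration_optimum():
    """With a single split, greedy Gini search reaches the best stump loss."""
    from rnflasym.tree import _make_leaf  # noqa: F401  (document internals exist)

    rng = np.random.default_rng(11)
    for _ in range(100):
        X, y = random_instance(rng)
        w = observation_weights(y, (1.0, 1.0))
        tree = grow_tree(X, y, TrainConfig(max_splits=1))
        assert training_loss(tree, X, y) == pytest.approx(
            optimal_tree_loss(X, y, w, 1), abs=1e-12
        )
        # and the chosen gain equals the brute-force maximal gain
        s = best_split(X, y, w)
        if s is not None:
            assert s[2] == pytest.approx(best_stump_gain(X, y, w), abs=1e-12)


# ---------------------------------------------------------------- growth
def test_grow_tree_stump_separates_hand_example():
    X = np.array([[0.01], [0.02], [0.30], [0.40]])
    y = np.array([0, 0, 1, 1])
    tree = grow_tree(X, y, TrainConfig(max_splits=1))
    assert tree.n_splits() == 1
    assert training_loss(tree, X, y) == 0.0


def test_grow_tree_single_class_yields_one_leaf():
    X = np.random.default_rng(0).random((5, 2))
    tree = grow_tree(X, np.zeros(5, dtype=int), TrainConfig(max_splits=3))
    assert tree.n_splits() == 0
    assert all(l == "healthy" for l in tree.predict(X))


def test_config_rejects_zero_split_budget():
    with pytest.raises(ValueError):
        TrainConfig(max_splits=0)


def test_split_budget_never_exceeded():
    rng = np.random.default_rng(5)
    for xi in (1, 2, 3, 5):
        X = rng.random((40, 3))
        y = (rng.random(40) < 0.4).astype(int)
        tree = grow_tree(X, y, TrainConfig(max_splits=xi))
        assert tree.n_splits() <= xi


def test_training_loss_monotone_in_budget():
    rng = np.random.default_rng(9)
    X = rng.random((60, 3))
    y = (X[:, 0] + 0.3 * rng.standard_normal(60) > 0.5).astype(int)
    losses = [
        training_loss(grow_tree(X, y, TrainConfig(max_splits=xi)), X, y)
        for xi in (1, 2, 3, 5, 8)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


def test_growth_is_deterministic():
    rng = np.random.default_rng(3)
    X = rng.random((30, 4))
    y = (rng.random(30) < 0.5).astype(int)
    cfg = TrainConfig(max_splits=4, class_weights=(1.0, 1.5), seed=2)
    t1, t2 = grow_tree(X, y, cfg), grow_tree(X, y, cfg)
    assert t1.to_dict() == t2.to_dict()


# ---------------------------------------------------------------- predict
def test_predict_single_leaf_and_threshold_tie():
    X = np.array([[0.01], [0.02], [0.30], [0.40]])
    y = np.array([0, 0, 1, 1])
    tree = grow_tree(X, y, TrainConfig(max_splits=1))
    thr = tree.root.threshold
    # exact equality goes right (>= branch)
    assert tree.predict_row([thr]) == tree.predict_row([thr + 1e-9])
    assert tree.predict_row([thr - 1e-9]) != tree.predict_row([thr])


def test_predict_rejects_wrong_width():
    X = np.array([[0.0], [1.0]])
    tree = grow_tree(X, np.array([0, 1]), TrainConfig(max_splits=1))
    with pytest.raises(ValueError, match="features"):
        tree.predict_row([0.1, 0.2])


def test_json_round_trip_preserves_predictions(tmp_path):
    rng = np.random.default_rng(8)
    X = rng.random((25, 7))
    y = (rng.random(25) < 0.4).astype(int)
    tree = grow_tree(X, y, TrainConfig(max_splits=3, class_weights=(1.0, 1.5)))
    path = tmp_path / "model.json"
    tree.to_json(path)
    back = DecisionTree.from_json(path)
    assert list(back.predict(X)) == list(tree.predict(X))
    assert back.config == tree.config


def test_rules_text_mentions_features_and_labels():
    X = np.array([[0.01, 0.5], [0.02, 0.5], [0.30, 0.5], [0.40, 0.5]])
    y = np.array([0, 0, 1, 1])
    tree = grow_tree(X, y, TrainConfig(max_splits=1))
    text = tree.rules_text()
    assert "if x0 <" in text
    assert "healthy" in text and "glaucoma" in text


# ---------------------------------------------------------------- weights
def test_raising_glaucoma_weight_weakly_increases_true_positives(default_cohort):
    fm = feature_matrix(default_cohort, "abs_Delta")
    y = feature_labels_binary(fm.labels)
    tps = []
    for wg in (1.0, 1.5, 2.5):
        tree = grow_tree(fm.values, y, TrainConfig(max_splits=3, class_weights=(1.0, wg)))
        cm = confusion(list(fm.labels), list(tree.predict(fm.values)))
        tps.append(cm.tp)
    assert tps[0] <= tps[1] <= tps[2]


# ---------------------------------------------------------------- CV loss
def test_cv_loss_zero_on_separable_data():
    rng = np.random.default_rng(2)
    X = np.vstack([rng.random((20, 2)), rng.random((20, 2)) + 5.0])
    y = np.array([0] * 20 + [1] * 20)
    for seed in (0, 1, 7):
        cfg = TrainConfig(max_splits=2, seed=seed)
        assert cv_classification_loss(X, y, cfg) == 0.0


def test_cv_loss_deterministic_for_fixed_seed(default_cohort):
    fm = feature_matrix(default_cohort, "abs_Delta")
    y = feature_labels_binary(fm.labels)
    cfg = TrainConfig(max_splits=3, class_weights=(1.0, 1.5), seed=4)
    assert cv_classification_loss(fm.values, y, cfg) == cv_classification_loss(
        fm.values, y, cfg
    )


def test_cv_loss_near_minority_share_when_labels_carry_no_signal():
    rng = np.random.default_rng(77)
    n = 300
    losses = []
    for seed in range(10):
        X = rng.random((n, 3))
        y = np.array([1] * 90 + [0] * 210)
        rng.shuffle(y)
        losses.append(cv_classification_loss(X, y, TrainConfig(max_splits=2, seed=seed)))
    assert np.mean(losses) == pytest.approx(0.30, abs=0.08)


def test_stratified_folds_cover_and_stratify():
    y = np.array([0] * 16 + [1] * 5)
    folds = stratified_folds(y, 5, seed=1)
    all_idx = np.sort(np.concatenate(folds))
    np.testing.assert_array_equal(all_idx, np.arange(21))
    for f in folds:
        assert (y[f] == 1).sum() == 1  # 5 positives over 5 folds


def test_cv_requires_enough_observations():
    X = np.random.default_rng(0).random((3, 2))
    with pytest.raises(ValueError):
        cv_classification_loss(X, np.array([0, 1, 0]), TrainConfig(max_splits=1, n_folds=5))


def test_unweighted_loss_option_differs_when_weights_do():
    rng = np.random.default_rng(10)
    X = rng.random((100, 2))
    y = (X[:, 0] + 0.5 * rng.standard_normal(100) > 0.7).astype(int)
    w_cfg = TrainConfig(max_splits=2, class_weights=(1.0, 1.5), seed=0, loss_weighted=True)
    u_cfg = TrainConfig(max_splits=2, class_weights=(1.0, 1.5), seed=0, loss_weighted=False)
    lw = cv_classification_loss(X, y, w_cfg)
    lu = cv_classification_loss(X, y, u_cfg)
    assert 0 <= lw <= 1 and 0 <= lu <= 1
    assert lw != pytest.approx(lu, abs=1e-9) or lw == 0 == lu


def test_greedy_tree_matches_exhaustive_optimum_on_realizable_data():
    """When the labels are generated by a stump on the features, greedy
    growth recovers a zero-loss tree, matching the enumeration optimum."""
    rng = np.random.default_rng(13)
    for _ in range(50):
        n = int(rng.integers(5, 9))
        X = rng.random((n, 2))
        j = int(rng.integers(2))
        y = (X[:, j] >= rng.random()).astype(int)
        if len(np.unique(y)) < 2:
            continue
        w = observation_weights(y, (1.0, 1.0))
        tree = grow_tree(X, y, TrainConfig(max_splits=1))
        assert training_loss(tree, X, y) == pytest.approx(
            optimal_tree_loss(X, y, w, 1), abs=1e-12
        )
        assert training_loss(tree, X, y) == 0.0
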