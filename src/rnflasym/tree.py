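"""Class-weighted binary classification tree (CART) with a split budget.

A from-scratch CART for the screening task: axis-aligned threshold splits
chosen by weighted Gini impurity decrease, grown best-first under a
budget of at most ``max_splits`` internal nodes (the complexity knob xi).
Best-first growth means the budget is spent where it reduces impurity
most, so a tree with xi=3 really has (at most) three splits wherever they
matter, rather than a depth limit filled breadth-first.

Observations carry class weights: every patient contributes its class's
weight (healthy w_h, glaucoma w_g), normalised to sum to one over the
training set.  Raising w_g makes glaucoma-heavy leaves cheaper to
dedicate, trading specificity for sensitivity.

Model selection uses stratified k-fold cross-validated classification
loss: the summed normalised weight of misclassified held-out
observations, which reduces to the plain misclassification rate when the
class weights are equal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import FEATURE_COLUMNS, GLAUCOMA, HEALTHY

_LABELS = (HEALTHY, GLAUCOMA)  # class index 0, 1


@dataclass(frozen=True)
class TrainConfig:
    """Tree-growing hyperparameters.

    ``max_splits`` is the split budget xi (>= 1).  ``class_weights`` is
    (w_healthy, w_glaucoma).  ``loss_weighted`` controls whether the CV
    loss itself uses the class weights or plain counts.
    """

    max_splits: int = 3
    class_weights: tuple[float, float] = (1.0, 1.0)
    n_folds: int = 5
    seed: int = 0
    loss_weighted: bool = True

    def __post_init__(self) -> None:
        if self.max_splits < 1:
            raise ValueError("max_splits (xi) must be >= 1")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def weighted_gini(class_weight_sums: tuple[float, float]) -> float:
    """Gini impurity of a node from its per-class weight totals.

    ``1 - p_h^2 - p_g^2`` with ``p_c = W_c / (W_h + W_g)``.
    """
    wh, wg = class_weight_sums
    if wh < 0 or wg < 0:
        raise ValueError("class weight sums must be non-negative")
    total = wh + wg
    if total == 0:
        raise ValueError("node has zero total weight")
    ph, pg = wh / total, wg / total
    return 1.0 - ph * ph - pg * pg


def best_split(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray
) -> Optional[tuple[int, float, float]]:
    """Exhaustive scan for the impurity-optimal threshold split.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each feature.  Returns ``(feature_index, threshold,
    impurity_decrease)`` maximising

        dI = I(node) - (W_L/W) I(L) - (W_R/W) I(R)

    or ``None`` when no split separates anything (all features constant or
    the node is pure).  Ties are broken by lowest feature index, then
    smallest threshold — the scan order makes this the first maximum found.
    """
    n = y.size
    if n < 2 or np.all(y == y[0]):
        return None
    w_class = np.array(
        [weights[y == 0].sum(), weights[y == 1].sum()]
    )
    total_w = w_class.sum()
    parent = weighted_gini((w_class[0], w_class[1]))
    best: Optional[tuple[int, float, float]] = None
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sv, sy, sw = col[order], y[order], weights[order]
        # running per-class weight on the left side
        left = np.zeros(2)
        for k in range(n - 1):
            left[sy[k]] += sw[k]
            if sv[k + 1] == sv[k]:
                continue
            # cancellation can leave a tiny negative residual
            right = np.maximum(w_class - left, 0.0)
            wl, wr = left.sum(), right.sum()
            gain = (
                parent
                - (wl / total_w) * weighted_gini((left[0], left[1]))
                - (wr / total_w) * weighted_gini((right[0], right[1]))
            )
            if best is None or gain > best[2]:
                thr = (sv[k] + sv[k + 1]) / 2.0
                best = (j, float(thr), float(gain))
    if best is None or best[2] <= 0.0:
        # no threshold separates observations, or nothing is gained
        return best if best is not None and best[2] > 0 else None
    return best


@dataclass
class TreeNode:
    """Either a split (``feature`` set) or a leaf (``label`` set).

    Split rule: ``value < threshold`` goes left; exact equality goes
    right.
    """

    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    label: Optional[str] = None
    proportions: Optional[tuple[float, float]] = None  # weighted (healthy, glaucoma)
    n_train: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def count_splits(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + self.left.count_splits() + self.right.count_splits()


def _make_leaf(y: np.ndarray, weights: np.ndarray) -> TreeNode:
    wh = float(weights[y == 0].sum())
    wg = float(weights[y == 1].sum())
    total = wh + wg
    props = (wh / total, wg / total) if total > 0 else (0.5, 0.5)
    # tie goes to the positive (glaucoma) class: screening prefers recall
    label = GLAUCOMA if props[1] >= props[0] else HEALTHY
    return TreeNode(label=label, proportions=props, n_train=int(y.size))


@dataclass
class DecisionTree:
    """Fitted screening tree over the 7 asymmetry features."""

    root: TreeNode
    config: TrainConfig
    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def predict_row(self, row: Sequence[float]) -> str:
        row = np.asarray(row, dtype=float)
        if row.size != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features, got {row.size}")
        node = self.root
        while not node.is_leaf:
            node = node.left if row[node.feature] < node.threshold else node.right
        return node.label

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.predict_row(r) for r in X])

    def n_splits(self) -> int:
        return self.root.count_splits()

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        def enc(node: TreeNode) -> dict:
            if node.is_leaf:
                return {
                    "leaf": {
                        "label": node.label,
                        "proportions": list(node.proportions),
                        "n_train": node.n_train,
                    }
                }
            return {
                "feature": self.feature_names[node.feature],
                "threshold": node.threshold,
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {
            "feature_names": list(self.feature_names),
            "config": {
                "max_splits": self.config.max_splits,
                "class_weights": list(self.config.class_weights),
                "n_folds": self.config.n_folds,
                "seed": self.config.seed,
                "loss_weighted": self.config.loss_weighted,
            },
            "tree": enc(self.root),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DecisionTree":
        names = tuple(payload["feature_names"])

        def dec(obj: dict) -> TreeNode:
            if "leaf" in obj:
                leaf = obj["leaf"]
                return TreeNode(
                    label=leaf["label"],
                    proportions=tuple(leaf["proportions"]),
                    n_train=int(leaf["n_train"]),
                )
            return TreeNode(
                feature=names.index(obj["feature"]),
                threshold=float(obj["threshold"]),
                left=dec(obj["left"]),
                right=dec(obj["right"]),
            )

        cfg = payload.get("config", {})
        config = TrainConfig(
            max_splits=cfg.get("max_splits", 3),
            class_weights=tuple(cfg.get("class_weights", (1.0, 1.0))),
            n_folds=cfg.get("n_folds", 5),
            seed=cfg.get("seed", 0),
            loss_weighted=cfg.get("loss_weighted", True),
        )
        return cls(root=dec(payload["tree"]), config=config, feature_names=names)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DecisionTree":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def rules_text(self) -> str:
        """Clinician-readable if-then rendering of the tree."""
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "  " * indent
            if node.is_leaf:
                ph, pg = node.proportions
                lines.append(
                    f"{pad}-> predict {node.label} "
                    f"(weighted healthy/glaucoma proportions {ph:.3f}/{pg:.3f}, "
                    f"n={node.n_train})"
                )
                return
            name = self.feature_names[node.feature]
            lines.append(f"{pad}if {name} < {node.threshold:.6g}:")
            walk(node.left, indent + 1)
            lines.append(f"{pad}else (>= {node.threshold:.6g}):")
            walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def observation_weights(y: np.ndarray, class_weights: tuple[float, float]) -> np.ndarray:
    """Per-observation weights (class weight of each label), summing to 1."""
    w = np.where(y == 1, class_weights[1], class_weights[0]).astype(float)
    return w / w.sum()


@dataclass
class _Frontier:
    node: TreeNode
    idx: np.ndarray
    split: Optional[tuple[int, float, float]]
    weight: float
    order: int = field(default=0)


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    feature_names: tuple[str, ...] | None = None,
) -> DecisionTree:
    """Best-first growth under the split budget.

    At each step the leaf whose best split gives the largest *global*
    impurity decrease (the leaf-local decrease scaled by the leaf's share
    of total weight) is split; growth stops when ``max_splits`` splits are
    placed or no leaf can improve.  Single-class input yields a one-leaf
    tree.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one label per row")
    if feature_names is None:
        feature_names = (
            FEATURE_COLUMNS if X.shape[1] == len(FEATURE_COLUMNS)
            else tuple(f"x{j}" for j in range(X.shape[1]))
        )
    elif len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length must match X's column count")
    w = observation_weights(y, config.class_weights)

    def frontier_entry(idx: np.ndarray, order: int) -> _Frontier:
        node = _make_leaf(y[idx], w[idx])
        split = best_split(X[idx], y[idx], w[idx])
        return _Frontier(node=node, idx=idx, split=split, weight=float(w[idx].sum()), order=order)

    counter = 0
    root_entry = frontier_entry(np.arange(y.size), counter)
    frontier = [root_entry]
    n_splits = 0
    while n_splits < config.max_splits:
        candidates = [f for f in frontier if f.split is not None]
        if not candidates:
            break
        # global decrease = leaf weight share * leaf-local gain; ties by
        # creation order for determinism
        target = max(candidates, key=lambda f: (f.weight * f.split[2], -f.order))
        j, thr, _ = target.split
        mask = X[target.idx, j] < thr
        left_idx, right_idx = target.idx[mask], target.idx[~mask]
        counter += 1
        left_entry = frontier_entry(left_idx, counter)
        counter += 1
        right_entry = frontier_entry(right_idx, counter)
        # mutate the leaf node in place into a split node
        node = target.node
        node.feature = j
        node.threshold = thr
        node.left = left_entry.node
        node.right = right_entry.node
        node.label = None
        node.proportions = None
        frontier.remove(target)
        frontier.extend([left_entry, right_entry])
        n_splits += 1
    return DecisionTree(root=root_entry.node, config=config, feature_names=feature_names)


def training_loss(tree: DecisionTree, X: np.ndarray, y: np.ndarray) -> float:
    """Weighted misclassification on the training inputs themselves."""
    w = observation_weights(np.asarray(y, dtype=int), tree.config.class_weights)
    pred = tree.predict(X)
    truth = np.array([_LABELS[c] for c in np.asarray(y, dtype=int)])
    return float(w[pred != truth].sum())


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Class-stratified fold index sets from a seeded shuffle.

    Within each class the (shuffled) observations are dealt round-robin
    over folds, so every fold holds both classes whenever each class has
    at least ``n_folds`` members.
    """
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        for pos, idx in enumerate(members):
            folds[pos % n_folds].append(int(idx))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cv_classification_loss(X: np.ndarray, y: np.ndarray, config: TrainConfig) -> float:
    """Stratified k-fold cross-validated classification loss in [0, 1].

    For each fold, a tree is grown on the remaining folds and applied to
    the held-out observations; the loss is the summed weight of
    misclassified held-out observations with weights normalised over the
    *full* dataset, so the per-fold contributions add up to a single rate.
    With ``loss_weighted=False`` every observation counts 1/n instead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.size < config.n_folds:
        raise ValueError("need at least n_folds observations")
    if config.loss_weighted:
        w_full = observation_weights(y, config.class_weights)
    else:
        w_full = np.full(y.size, 1.0 / y.size)
    truth = np.array([_LABELS[c] for c in y])
    folds = stratified_folds(y, config.n_folds, config.seed)
    loss = 0.0
    for held_out in folds:
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[held_out] = False
        if len(np.unique(y[train_mask])) < 2:
            raise ValueError("a training split lost one class entirely")
        tree = grow_tree(X[train_mask], y[train_mask], config)
        pred = tree.predict(X[held_out])
        loss += float(w_full[held_out][pred != truth[held_out]].sum())
    return loss
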