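"""Independent brute-force oracles used by the tree tests.

Kept free of any code path they are checking: the enumeration works
directly on index masks and weighted counts.
"""

import numpy as np


def candidate_splits(X):
    """All (feature, midpoint-threshold) pairs of a dataset."""
    out = []
    for j in range(X.shape[1]):
        v = np.unique(X[:, j])
        for a, b in zip(v, v[1:]):
            out.append((j, (a + b) / 2.0))
    return out


def leaf_loss(y, w):
    """Weighted misclassification of a majority-vote leaf."""
    return min(w[y == 0].sum(), w[y == 1].sum())


def optimal_tree_loss(X, y, w, budget):
    """Minimal weighted training loss over ALL threshold trees with at most
    ``budget`` splits, by exhaustive recursion over splits and child budgets."""
    best = leaf_loss(y, w)
    if budget == 0 or y.size < 2 or np.all(y == y[0]):
        return best
    for j, t in candidate_splits(X):
        m = X[:, j] < t
        if not m.any() or m.all():
            continue
        for left_budget in range(budget):
            right_budget = budget - 1 - left_budget
            loss = optimal_tree_loss(X[m], y[m], w[m], left_budget) + optimal_tree_loss(
                X[~m], y[~m], w[~m], right_budget
            )
            if loss < best:
                best = loss
    return best


def best_stump_gain(X, y, w):
    """Maximal weighted-Gini impurity decrease over all single splits."""

    def gini(wh, wg):
        t = wh + wg
        if t == 0:
            return 0.0
        return 1.0 - (wh / t) ** 2 - (wg / t) ** 2

    wh_all, wg_all = w[y == 0].sum(), w[y == 1].sum()
    total = wh_all + wg_all
    parent = gini(wh_all, wg_all)
    best = None
    for j, t in candidate_splits(X):
        m = X[:, j] < t
        lh, lg = w[m & (y == 0)].sum(), w[m & (y == 1)].sum()
        rh, rg = wh_all - lh, wg_all - lg
        gain = (
            parent
            - (lh + lg) / total * gini(lh, lg)
            - (rh + rg) / total * gini(rh, rg)
        )
        if best is None or gain > best:
            best = gain
    return best


def random_instance(rng, n_lo=4, n_hi=8, p=2):
    """A random small dataset with both classes present."""
    n = int(rng.integers(n_lo, n_hi + 1))
    X = rng.random((n, p))
    while True:
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) == 2:
            break
    return X, y.astype(int)
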