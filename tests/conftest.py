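import numpy as np
import pytest

from imdforest import ForestConfig, fit_forest
from imdforest.forest import standardize_node_responses


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_forest_data():
    """Small correlated X/Y pair where the first 3 predictors drive the
    first 2 responses."""
    rng = np.random.default_rng(11)
    n, p, q = 60, 10, 5
    u = rng.normal(size=n)
    X = rng.normal(size=(n, p))
    X[:, 0] = u + 0.2 * rng.normal(size=n)
    X[:, 1] = u + 0.4 * rng.normal(size=n)
    X[:, 2] = -u + 0.4 * rng.normal(size=n)
    Y = rng.normal(size=(n, q))
    Y[:, 0] = u + 0.3 * rng.normal(size=n)
    Y[:, 1] = u**2 + 0.3 * rng.normal(size=n)
    return X, Y


@pytest.fixture(scope="session")
def small_forest(small_forest_data):
    X, Y = small_forest_data
    return fit_forest(X, Y, ForestConfig(n_trees=25, seed=3))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def within_node_sse(Y_node, left_mask):
    """Direct evaluation of the split criterion: within-daughter sum of
    squared deviations, summed over responses."""
    total = 0.0
    for j in range(Y_node.shape[1]):
        for mask in (left_mask, ~left_mask):
            col = Y_node[mask, j]
            total += float(np.sum((col - col.mean()) ** 2))
    return total


def exhaustive_best_split(X_node, Y_node):
    """Brute force over every (predictor, midpoint threshold) pair using the
    maximization form of the criterion on node-standardized responses.
    Ties: lower predictor index, then lower threshold."""
    Z, _ = standardize_node_responses(Y_node)
    m, p = X_node.shape
    best = None
    for f in range(p):
        xs = np.unique(X_node[:, f])
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (lo + hi)
            left = X_node[:, f] <= thr
            score = 0.0
            for j in range(Z.shape[1]):
                s_l = Z[left, j].sum()
                s_r = Z[~left, j].sum()
                score += s_l**2 / left.sum() + s_r**2 / (~left).sum()
            if best is None or score > best[0] + 1e-12:
                best = (score, f, thr)
    return best


def bfs_minimal_depth(tree, side, n_vars):
    """Breadth-first traversal oracle for minimal depth (-1 = absent)."""
    md = {}
    queue = [(0, 0)]
    while queue:
        node, d = queue.pop(0)
        if tree.feature[node] < 0:
            continue
        v = tree.feature[node] if side == "predictor" else tree.msrv[node]
        if v not in md or d < md[v]:
            md[v] = d
        queue.append((int(tree.left[node]), d + 1))
        queue.append((int(tree.right[node]), d + 1))
    out = np.full(n_vars, -1, dtype=int)
    for v, d in md.items():
        out[v] = d
    return out


def brute_force_pr_auc(scores, truth_mask):
    """Stepwise PR-curve integration by explicit prefix enumeration over the
    stable descending-score order."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    n_pos = int(np.sum(truth_mask))
    auc = 0.0
    tp = 0
    prev_recall = 0.0
    for rank, i in enumerate(order, start=1):
        if truth_mask[i]:
            tp += 1
            recall = tp / n_pos
            auc += (recall - prev_recall) * (tp / rank)
            prev_recall = recall
    return auc
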