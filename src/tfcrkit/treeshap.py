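"""Exact Shapley attributions for scikit-learn decision-tree ensembles.

Implements the polynomial-time path-dependent algorithm for trees: the
conditional expectation of a subtree is approximated by the tree's own
training cover when a split feature is missing, and Shapley weights are
maintained incrementally along each root-to-leaf path.  For every sample,
the base value (root expectation) plus the per-feature attributions equals
the tree's prediction exactly (local accuracy).

The brute-force counterpart :func:`brute_force_shap` enumerates feature
subsets and is used as an independent oracle in the tests; it must agree
with the fast path on any tree.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

__all__ = ["tree_shap_values", "ensemble_shap", "brute_force_shap", "tree_expectation"]


class _Tree:
    def __init__(self, sk_tree):
        t = sk_tree.tree_
        self.left = t.children_left
        self.right = t.children_right
        self.feature = t.feature
        self.threshold = t.threshold
        self.value = t.value[:, 0, 0]
        self.cover = t.weighted_n_node_samples


def _extend(fi, zf, of, pw, depth, pz, po, pi):
    fi[depth] = pi
    zf[depth] = pz
    of[depth] = po
    pw[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        pw[i + 1] += po * pw[i] * (i + 1) / (depth + 1)
        pw[i] = pz * pw[i] * (depth - i) / (depth + 1)


def _unwound_sum(zf, of, pw, depth, path_index):
    one = of[path_index]
    zero = zf[path_index]
    total = 0.0
    nxt = pw[depth]
    if one != 0.0:
        for j in range(depth - 1, -1, -1):
            tmp = nxt * (depth + 1) / ((j + 1) * one)
            total += tmp
            nxt = pw[j] - tmp * zero * (depth - j) / (depth + 1)
    else:
        for j in range(depth - 1, -1, -1):
            total += pw[j] / (zero * (depth - j) / (depth + 1))
    return total


def _unwind(fi, zf, of, pw, depth, path_index):
    one = of[path_index]
    zero = zf[path_index]
    nxt = pw[depth]
    for j in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (depth + 1) / ((j + 1) * one)
            nxt = pw[j] - tmp * zero * (depth - j) / (depth + 1)
            pw[j] = tmp
        else:
            pw[j] = pw[j] * (depth + 1) / (zero * (depth - j))
    for j in range(path_index, depth):
        fi[j] = fi[j + 1]
        zf[j] = zf[j + 1]
        of[j] = of[j + 1]


def _recurse(tree, x, phi, node, depth, fi, zf, of, pw, pz, po, pi):
    fi, zf, of, pw = fi[:], zf[:], of[:], pw[:]
    fi += [-1]
    zf += [0.0]
    of += [0.0]
    pw += [0.0]
    _extend(fi, zf, of, pw, depth, pz, po, pi)
    if tree.left[node] < 0:  # leaf
        leaf = tree.value[node]
        for i in range(1, depth + 1):
            w = _unwound_sum(zf, of, pw, depth, i)
            phi[fi[i]] += w * (of[i] - zf[i]) * leaf
        return
    split = tree.feature[node]
    if x[split] <= tree.threshold[node]:
        hot, cold = tree.left[node], tree.right[node]
    else:
        hot, cold = tree.right[node], tree.left[node]
    iz, io = 1.0, 1.0
    path_index = -1
    for i in range(1, depth + 1):
        if fi[i] == split:
            path_index = i
            break
    if path_index >= 0:
        iz, io = zf[path_index], of[path_index]
        _unwind(fi, zf, of, pw, depth, path_index)
        depth -= 1
    cover = tree.cover[node]
    _recurse(tree, x, phi, hot, depth + 1, fi, zf, of, pw,
             iz * tree.cover[hot] / cover, io, split)
    _recurse(tree, x, phi, cold, depth + 1, fi, zf, of, pw,
             iz * tree.cover[cold] / cover, 0.0, split)


def tree_shap_values(sk_tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample Shapley values for one fitted sklearn regression tree.

    Returns (phi of shape (n, d), base value = root expectation).
    """
    tree = _Tree(sk_tree)
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    phi = np.zeros((n, d))
    for r in range(n):
        _recurse(tree, X[r], phi[r], 0, 0, [], [], [], [], 1.0, 1.0, -1)
    return phi, float(tree.value[0])


def tree_expectation(sk_tree, x: np.ndarray, known: frozenset) -> float:
    """Cover-weighted expectation of the tree when only the features in
    ``known`` are observed (the path-dependent conditioning rule)."""
    tree = _Tree(sk_tree)

    def walk(node: int) -> float:
        if tree.left[node] < 0:
            return float(tree.value[node])
        split = tree.feature[node]
        left, right = tree.left[node], tree.right[node]
        if split in known:
            child = left if x[split] <= tree.threshold[node] else right
            return walk(child)
        wl = tree.cover[left] / tree.cover[node]
        return wl * walk(left) + (1.0 - wl) * walk(right)

    return walk(0)


def brute_force_shap(sk_tree, x: np.ndarray) -> np.ndarray:
    """Exponential-time Shapley values for one tree; oracle for tests.

    Only features actually used by the tree get non-zero values, so the
    enumeration is over the used-feature set.
    """
    tree = _Tree(sk_tree)
    used = sorted({int(f) for f in tree.feature if f >= 0})
    d_total = len(x)
    phi = np.zeros(d_total)
    m = len(used)
    for i in used:
        others = [f for f in used if f != i]
        for size in range(m):
            weight = 1.0 / (m * comb(m - 1, size))
            for subset in combinations(others, size):
                s = frozenset(subset)
                gain = tree_expectation(sk_tree, x, s | {i}) - tree_expectation(
                    sk_tree, x, s
                )
                phi[i] += weight * gain
    return phi


def ensemble_shap(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shapley attributions for a sklearn tree model or additive ensemble.

    Supports DecisionTreeRegressor, RandomForestRegressor (mean of trees)
    and GradientBoostingRegressor (init + lr-weighted sum of trees).
    Returns (phi (n, d), base (n,)) with base + phi.sum(1) == predict(X).
    """
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.tree import DecisionTreeRegressor

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if isinstance(model, DecisionTreeRegressor):
        phi, base = tree_shap_values(model, X)
        return phi, np.full(n, base)
    if isinstance(model, RandomForestRegressor):
        phi = np.zeros(X.shape)
        base = 0.0
        for est in model.estimators_:
            p, b = tree_shap_values(est, X)
            phi += p
            base += b
        k = len(model.estimators_)
        return phi / k, np.full(n, base / k)
    if isinstance(model, GradientBoostingRegressor):
        phi = np.zeros(X.shape)
        base = np.asarray(model.init_.predict(X), dtype=float).reshape(n)
        lr = model.learning_rate
        for est in model.estimators_[:, 0]:
            p, b = tree_shap_values(est, X)
            phi += lr * p
            base = base + lr * b
        return phi, base
    raise TypeError(
        f"Shapley attribution is defined for tree models only, got {type(model).__name__}"
    )
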