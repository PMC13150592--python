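"""Exact additive (Shapley) attributions for decision-tree ensembles.

Implements the polynomial-time path-dependent algorithm for Shapley
values of a tree's cover-weighted expectation game: for a feature
subset S the tree is evaluated by following the split when the split
feature is in S and averaging the children by their training cover
otherwise.  The per-feature attributions phi satisfy local accuracy,

    E[f] + sum_j phi_j(x) = f(x),

exactly (to floating-point error).  A brute-force oracle over the
coalition lattice is provided for validation at small p.

The hot loops are numba-compiled when numba imports cleanly; a pure
Python fallback keeps the module usable (and the oracle independent)
everywhere.
"""
from __future__ import annotations

from typing import List, Sequence

import numpy as np

__all__ = [
    "tree_shap_values",
    "forest_shap_values",
    "expected_value",
    "tree_expvalue_subset",
    "brute_force_shapley",
]


def _extend_path(path, depth, zero_fraction, one_fraction, feature_index):
    path[depth, 0] = feature_index
    path[depth, 1] = zero_fraction
    path[depth, 2] = one_fraction
    path[depth, 3] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        path[i + 1, 3] += (one_fraction * path[i, 3] * (i + 1)
                           / (depth + 1))
        path[i, 3] = (zero_fraction * path[i, 3] * (depth - i)
                      / (depth + 1))


def _unwind_path(path, depth, index):
    one_fraction = path[index, 2]
    zero_fraction = path[index, 1]
    next_one = path[depth, 3]
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = path[i, 3]
            path[i, 3] = next_one * (depth + 1) / ((i + 1) * one_fraction)
            next_one = tmp - (path[i, 3] * zero_fraction * (depth - i)
                              / (depth + 1))
        else:
            path[i, 3] = (path[i, 3] * (depth + 1)
                          / (zero_fraction * (depth - i)))
    for i in range(index, depth):
        path[i, 0] = path[i + 1, 0]
        path[i, 1] = path[i + 1, 1]
        path[i, 2] = path[i + 1, 2]


def _unwound_path_sum(path, depth, index):
    one_fraction = path[index, 2]
    zero_fraction = path[index, 1]
    next_one = path[depth, 3]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one * (depth + 1) / ((i + 1) * one_fraction)
            total += tmp
            next_one = path[i, 3] - (tmp * zero_fraction * (depth - i)
                                     / (depth + 1))
        else:
            total += path[i, 3] * (depth + 1) / (zero_fraction * (depth - i))
    return total


def _recurse(left, right, feature, threshold, value, weight, x, phi,
             node, depth, parent_path, pzf, pof, pfi, maxd):
    path = np.empty((maxd, 4))
    path[:depth] = parent_path[:depth]
    _extend_path(path, depth, pzf, pof, pfi)
    if left[node] < 0:  # leaf
        for i in range(1, depth + 1):
            w = _unwound_path_sum(path, depth, i)
            phi[int(path[i, 0])] += (w * (path[i, 2] - path[i, 1])
                                     * value[node])
        return
    f = feature[node]
    if x[f] <= threshold[node]:
        hot, cold = left[node], right[node]
    else:
        hot, cold = right[node], left[node]
    hot_zf = weight[hot] / weight[node]
    cold_zf = weight[cold] / weight[node]
    inc_zf, inc_of = 1.0, 1.0
    d = depth
    found = -1
    for i in range(1, d + 1):
        if int(path[i, 0]) == f:
            found = i
            break
    if found >= 0:
        inc_zf = path[found, 1]
        inc_of = path[found, 2]
        _unwind_path(path, d, found)
        d -= 1
    _recurse(left, right, feature, threshold, value, weight, x, phi,
             hot, d + 1, path, hot_zf * inc_zf, inc_of, f, maxd)
    _recurse(left, right, feature, threshold, value, weight, x, phi,
             cold, d + 1, path, cold_zf * inc_zf, 0.0, f, maxd)


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _extend_path_jit = njit(cache=True)(_extend_path)
    _unwind_path_jit = njit(cache=True)(_unwind_path)
    _unwound_path_sum_jit = njit(cache=True)(_unwound_path_sum)

    @njit(cache=True)
    def _recurse_jit(left, right, feature, threshold, value, weight, x,
                     phi, node, depth, parent_path, pzf, pof, pfi, maxd):
        path = np.empty((maxd, 4))
        path[:depth] = parent_path[:depth]
        _extend_path_jit(path, depth, pzf, pof, pfi)
        if left[node] < 0:
            for i in range(1, depth + 1):
                w = _unwound_path_sum_jit(path, depth, i)
                phi[int(path[i, 0])] += (w * (path[i, 2] - path[i, 1])
                                         * value[node])
            return
        f = feature[node]
        if x[f] <= threshold[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        hot_zf = weight[hot] / weight[node]
        cold_zf = weight[cold] / weight[node]
        inc_zf, inc_of = 1.0, 1.0
        d = depth
        found = -1
        for i in range(1, d + 1):
            if int(path[i, 0]) == f:
                found = i
                break
        if found >= 0:
            inc_zf = path[found, 1]
            inc_of = path[found, 2]
            _unwind_path_jit(path, d, found)
            d -= 1
        _recurse_jit(left, right, feature, threshold, value, weight, x,
                     phi, hot, d + 1, path, hot_zf * inc_zf, inc_of, f,
                     maxd)
        _recurse_jit(left, right, feature, threshold, value, weight, x,
                     phi, cold, d + 1, path, cold_zf * inc_zf, 0.0, f,
                     maxd)

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _tree_arrays(tree):
    """Flat arrays of one fitted sklearn regression tree."""
    t = tree.tree_
    return (t.children_left.astype(np.int64),
            t.children_right.astype(np.int64),
            t.feature.astype(np.int64),
            t.threshold.astype(np.float64),
            t.value[:, 0, 0].astype(np.float64),
            t.weighted_n_node_samples.astype(np.float64),
            int(t.max_depth))


def tree_shap_values(tree, X: np.ndarray,
                     use_numba: bool = True) -> np.ndarray:
    """Per-feature Shapley attributions of one sklearn decision tree for
    every row of X; shape (n, p)."""
    left, right, feat, thr, val, w, maxdepth = _tree_arrays(tree)
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    phis = np.zeros((n, p))
    maxd = maxdepth + 2
    parent = np.zeros((maxd, 4))
    rec = (_recurse_jit if (use_numba and _HAVE_NUMBA) else _recurse)
    for i in range(n):
        phi = np.zeros(p)
        rec(left, right, feat, thr, val, w, X[i], phi, 0, 0, parent,
            1.0, 1.0, -1, maxd)
        phis[i] = phi
    return phis


def expected_value(forest) -> float:
    """Cover-weighted expectation of the ensemble (its base value)."""
    vals = []
    for est in forest.estimators_:
        _, _, _, _, val, _, _ = _tree_arrays(est)
        vals.append(val[0])
    return float(np.mean(vals))


def forest_shap_values(forest, X: np.ndarray,
                       use_numba: bool = True) -> np.ndarray:
    """Mean per-tree attributions of a RandomForestRegressor."""
    X = np.asarray(X, dtype=np.float64)
    total = np.zeros(X.shape)
    for est in forest.estimators_:
        total += tree_shap_values(est, X, use_numba=use_numba)
    return total / len(forest.estimators_)


# ----------------------------------------------------------------- oracle

def tree_expvalue_subset(tree, x: np.ndarray, subset: Sequence[int]
                         ) -> float:
    """Cover-weighted expectation of one tree conditioned on the
    features in ``subset`` taking their values from x.  This defines
    the coalition game whose Shapley values the fast algorithm
    computes; used as an independent brute-force oracle."""
    left, right, feat, thr, val, w, _ = _tree_arrays(tree)
    S = set(int(j) for j in subset)

    def rec(node: int) -> float:
        if left[node] < 0:
            return float(val[node])
        f = int(feat[node])
        if f in S:
            nxt = left[node] if x[f] <= thr[node] else right[node]
            return rec(nxt)
        lw, rw = w[left[node]], w[right[node]]
        return (lw * rec(left[node]) + rw * rec(right[node])) / (lw + rw)

    return rec(0)


def brute_force_shapley(tree, x: np.ndarray, p: int) -> np.ndarray:
    """Exact Shapley values by full enumeration of the coalition
    lattice (O(2^p)); feasible only for small p."""
    from itertools import combinations
    from math import factorial

    x = np.asarray(x, dtype=float)
    phi = np.zeros(p)
    others: List[int] = list(range(p))
    for j in range(p):
        rest = [k for k in others if k != j]
        for r in range(len(rest) + 1):
            for S in combinations(rest, r):
                wgt = (factorial(len(S)) * factorial(p - len(S) - 1)
                       / factorial(p))
                gain = (tree_expvalue_subset(tree, x, S + (j,))
                        - tree_expvalue_subset(tree, x, S))
                phi[j] += wgt * gain
    return phi
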