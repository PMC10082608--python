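"""Shapley-value feature attributions for tree-ensemble regressors.

Two routes are provided:

* :func:`exact_shapley` — brute-force enumeration of the Shapley formula

      phi_j = sum_{S subseteq F\\{j}} |S|! (p-|S|-1)! / p! * (nu(S u {j}) - nu(S))

  over all 2^p coalitions of an arbitrary value function ``nu``. Feasible
  for p <= 12; used as the independent oracle in tests.

* :func:`interventional_tree_shap` — exact per-sample Shapley values of a
  fitted scikit-learn decision tree or tree ensemble under the
  interventional value function

      nu_x(S) = mean over background rows b of f(x_S, b_{S^c}),

  i.e. features outside the coalition are marginalized over an empirical
  background distribution. For a single (x, b) pair the game decomposes
  over leaves: a leaf is reachable iff every feature on its path is
  satisfied by x or by b, and its indicator game depends only on the
  counts k of features satisfied by x alone and m satisfied by b alone,
  giving the closed-form per-feature weights (k-1)! m! / (k+m)! and
  -k! (m-1)! / (k+m)!. The numba kernel walks each tree once per pair,
  pruning branches that neither x nor b can enter.

The signed attributions satisfy the efficiency identity
``sum_j phi_j + mean_b f(b) = f(x)`` exactly (to float round-off).
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from numba import njit

__all__ = ["exact_shapley", "interventional_tree_shap", "tree_value_function"]

_MAX_EXACT_FEATURES = 12


def exact_shapley(value_function: Callable[[tuple[int, ...]], float], p: int) -> np.ndarray:
    """Enumerate Shapley values of an arbitrary p-player game.

    Parameters
    ----------
    value_function
        Callable evaluating the game on a tuple of feature indices
        (a subset of ``range(p)``, in increasing order).
    p
        Number of features. Must be at most 12; larger games must go
        through the tree-path computation instead.

    Returns
    -------
    Array of length ``p`` whose entries sum to
    ``value_function(full) - value_function(empty)``.
    """
    if p < 1:
        raise ValueError("p must be a positive integer")
    if p > _MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration is limited to p <= {_MAX_EXACT_FEATURES} features "
            f"(got {p}); use interventional_tree_shap for larger models"
        )
    fact = [math.factorial(k) for k in range(p + 1)]
    # cache nu on all subsets, keyed by bitmask
    nu = np.empty(2**p)
    for mask in range(2**p):
        subset = tuple(j for j in range(p) if mask >> j & 1)
        nu[mask] = float(value_function(subset))
    phi = np.zeros(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for size in range(p):
            weight = fact[size] * fact[p - size - 1] / fact[p]
            for subset in combinations(others, size):
                mask = 0
                for i in subset:
                    mask |= 1 << i
                phi[j] += weight * (nu[mask | (1 << j)] - nu[mask])
    return phi


def tree_value_function(
    model, x: np.ndarray, background: np.ndarray
) -> Callable[[tuple[int, ...]], float]:
    """Interventional value function of a fitted regressor at point ``x``.

    ``nu(S)`` pastes ``x`` into every background row on the coalition's
    columns and averages the model's predictions — the same game the tree
    kernel solves in closed form, evaluated here through ``model.predict``
    so the two routes share nothing but the fitted model.
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)

    def nu(subset: tuple[int, ...]) -> float:
        composite = background.copy()
        for j in subset:
            composite[:, j] = x[j]
        return float(np.mean(model.predict(composite)))

    return nu


@njit(cache=True)
def _pair_shap(children_left, children_right, feature, threshold, leaf_value,
               x, b, wx, wb, phi,
               xv, bv, onpath, pathf, st_node, st_phase, st_feat, st_dx, st_db):
    """Accumulate signed Shapley values of one (foreground, background) pair.

    ``wx[k, m] = (k-1)! m! / (k+m)!`` and ``wb[k, m] = k! (m-1)! / (k+m)!``
    are precomputed tables. Uses an explicit enter/exit stack; per-feature
    violation counts track whether x and b satisfy all path conditions on
    each feature, and k/m count features currently satisfied by x only /
    b only. Branches violated by both x and b are pruned.
    """
    n_path = 0
    k = 0
    m = 0
    top = 0
    st_node[top] = 0
    st_phase[top] = 0
    st_feat[top] = -1
    st_dx[top] = 0
    st_db[top] = 0
    top += 1

    while top > 0:
        top -= 1
        node = st_node[top]
        phase = st_phase[top]
        f = st_feat[top]
        dx = st_dx[top]
        db = st_db[top]

        if phase == 1:
            # restore the condition applied on entry
            old_cat = 0
            if xv[f] > 0 and bv[f] == 0:
                old_cat = 1
            elif xv[f] == 0 and bv[f] > 0:
                old_cat = 2
            xv[f] -= dx
            bv[f] -= db
            onpath[f] -= 1
            if onpath[f] == 0:
                n_path -= 1
            new_cat = 0
            if onpath[f] > 0:
                if xv[f] > 0 and bv[f] == 0:
                    new_cat = 1
                elif xv[f] == 0 and bv[f] > 0:
                    new_cat = 2
            if old_cat != new_cat:
                if old_cat == 1:
                    m -= 1
                elif old_cat == 2:
                    k -= 1
                if new_cat == 1:
                    m += 1
                elif new_cat == 2:
                    k += 1
            continue

        if f >= 0:
            # apply this branch's condition
            old_cat = 0
            if onpath[f] > 0:
                if xv[f] > 0 and bv[f] == 0:
                    old_cat = 1
                elif xv[f] == 0 and bv[f] > 0:
                    old_cat = 2
            if onpath[f] == 0:
                pathf[n_path] = f
                n_path += 1
            onpath[f] += 1
            xv[f] += dx
            bv[f] += db
            new_cat = 0
            if xv[f] > 0 and bv[f] == 0:
                new_cat = 1
            elif xv[f] == 0 and bv[f] > 0:
                new_cat = 2
            if old_cat != new_cat:
                if old_cat == 1:
                    m -= 1
                elif old_cat == 2:
                    k -= 1
                if new_cat == 1:
                    m += 1
                elif new_cat == 2:
                    k += 1
            # schedule the restoration
            st_node[top] = node
            st_phase[top] = 1
            st_feat[top] = f
            st_dx[top] = dx
            st_db[top] = db
            top += 1

        if children_left[node] == -1:
            # leaf: attribute its value to the currently decisive features
            w = leaf_value[node]
            if k + m > 0:
                for t in range(n_path):
                    ft = pathf[t]
                    if xv[ft] == 0 and bv[ft] > 0:
                        phi[ft] += w * wx[k, m]
                    elif bv[ft] == 0 and xv[ft] > 0:
                        phi[ft] -= w * wb[k, m]
            continue

        fs = feature[node]
        thr = threshold[node]
        x_left = x[fs] <= thr
        b_left = b[fs] <= thr
        # right child first so the left subtree is processed first (cosmetic)
        dxr = 0 if not x_left else 1
        dbr = 0 if not b_left else 1
        if not (xv[fs] + dxr > 0 and bv[fs] + dbr > 0):
            st_node[top] = children_right[node]
            st_phase[top] = 0
            st_feat[top] = fs
            st_dx[top] = dxr
            st_db[top] = dbr
            top += 1
        dxl = 0 if x_left else 1
        dbl = 0 if b_left else 1
        if not (xv[fs] + dxl > 0 and bv[fs] + dbl > 0):
            st_node[top] = children_left[node]
            st_phase[top] = 0
            st_feat[top] = fs
            st_dx[top] = dxl
            st_db[top] = dbl
            top += 1


@njit(cache=True)
def _tree_shap_all(children_left, children_right, feature, threshold, leaf_value,
                   X, B, wx, wb, out):
    n = X.shape[0]
    nb = B.shape[0]
    p = X.shape[1]
    # workspace shared across pairs; the exit discipline restores every
    # array to its zero state when a pair's traversal completes
    xv = np.zeros(p, dtype=np.int64)
    bv = np.zeros(p, dtype=np.int64)
    onpath = np.zeros(p, dtype=np.int64)
    pathf = np.empty(p, dtype=np.int64)
    max_stack = 4 * (children_left.shape[0] + 2)
    st_node = np.empty(max_stack, dtype=np.int64)
    st_phase = np.empty(max_stack, dtype=np.int64)
    st_feat = np.empty(max_stack, dtype=np.int64)
    st_dx = np.empty(max_stack, dtype=np.int64)
    st_db = np.empty(max_stack, dtype=np.int64)
    for i in range(n):
        for j in range(nb):
            _pair_shap(children_left, children_right, feature, threshold,
                       leaf_value, X[i], B[j], wx, wb, out[i],
                       xv, bv, onpath, pathf, st_node, st_phase, st_feat, st_dx, st_db)
        for c in range(p):
            out[i, c] /= nb


def _weight_tables(max_coalition: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form leaf weights, computed in log space to avoid overflow."""
    d = max_coalition + 2
    wx = np.zeros((d, d))
    wb = np.zeros((d, d))
    for k in range(d):
        for m in range(d):
            if k >= 1:
                wx[k, m] = math.exp(
                    math.lgamma(k) + math.lgamma(m + 1) - math.lgamma(k + m + 1)
                )
            if m >= 1:
                wb[k, m] = math.exp(
                    math.lgamma(k + 1) + math.lgamma(m) - math.lgamma(k + m + 1)
                )
    return wx, wb


def _iter_trees(model):
    if hasattr(model, "estimators_"):
        return list(model.estimators_)
    return [model]


def interventional_tree_shap(
    model, X: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sample signed Shapley values of a tree model against a background.

    Parameters
    ----------
    model
        A fitted sklearn decision-tree regressor or forest (averaging
        ensemble); forest attributions are the mean of per-tree
        attributions, matching the ensemble's mean prediction.
    X
        Foreground samples, shape (n_samples, n_features).
    background
        Background rows defining the marginalization distribution.

    Returns
    -------
    (phi, base) where ``phi`` has shape (n_samples, n_features) and
    ``base`` is the mean model prediction over the background, so that
    ``phi.sum(axis=1) + base == model.predict(X)``.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    background = np.ascontiguousarray(np.asarray(background, dtype=np.float64))
    if X.ndim != 2 or background.ndim != 2 or X.shape[1] != background.shape[1]:
        raise ValueError("X and background must be 2-D with matching feature counts")
    if background.shape[0] == 0:
        raise ValueError("background must contain at least one row")
    trees = _iter_trees(model)
    max_depth = max(t.tree_.max_depth for t in trees)
    wx, wb = _weight_tables(min(X.shape[1], max_depth))
    phi = np.zeros_like(X)
    out = np.empty_like(X)
    for est in trees:
        t = est.tree_
        out[:] = 0.0
        _tree_shap_all(
            t.children_left.astype(np.int64),
            t.children_right.astype(np.int64),
            t.feature.astype(np.int64),
            t.threshold.astype(np.float64),
            np.ascontiguousarray(t.value[:, 0, 0], dtype=np.float64),
            X, background, wx, wb, out,
        )
        phi += out
    phi /= len(trees)
    base = float(np.mean(model.predict(background)))
    return phi, base
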