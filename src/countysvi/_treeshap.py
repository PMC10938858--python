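"""Interventional Tree-Shapley kernel.

Computes exact Shapley values of a tree ensemble under the marginal
(interventional) value function v(S) = E_b[f(x_S, b_{~S})], averaging
over an explicit background sample.  For a single (foreground x,
background b) pair and one tree, a leaf is reached by coalition S iff
every split on its path is satisfied by x (feature in S) or by b
(feature not in S).  Collecting the distinct divergent features on the
path — k that must come from x, m that must come from b — the leaf's
weight contribution to each such feature has the closed form

    phi_i += v_leaf * PW[k, m]   (i one of the k x-side features)
    phi_i -= v_leaf * NW[k, m]   (i one of the m b-side features)

where, with p features and r = p - k - m unconstrained features,

    PW[k, m] = sum_t C(r, t) (k-1+t)! (p-k-t)! / p!
    NW[k, m] = sum_t C(r, t) (k+t)!   (p-k-1-t)! / p! ,

obtained by summing the classical Shapley coalition weights over the
free features.  The traversal only descends into hybrid-reachable
subtrees, pruning children inconsistent with both x and b or with an
earlier constraint on the same feature.

Everything here is numba-compiled; per-pair efficiency
(sum_i phi_i = f(x) - f(b)) holds by construction and is asserted in
the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


def shapley_pair_weights(p: int, dmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Tables PW[k, m], NW[k, m] for k, m up to dmax with p features."""
    dmax = min(dmax, p)
    PW = np.zeros((dmax + 1, dmax + 1))
    NW = np.zeros((dmax + 1, dmax + 1))
    fact = [math.factorial(i) for i in range(p + 1)]
    for k in range(dmax + 1):
        for m in range(dmax + 1):
            if k + m > p or k + m == 0:
                continue
            r = p - k - m
            pw = 0.0
            nw = 0.0
            for t in range(r + 1):
                c = math.comb(r, t)
                if k >= 1:
                    pw += c * fact[k - 1 + t] * fact[p - k - t] / fact[p]
                if m >= 1:
                    nw += c * fact[k + t] * fact[p - k - 1 - t] / fact[p]
            PW[k, m] = pw
            NW[k, m] = nw
    return PW, NW


@njit(cache=False)
def predict_margin(X, root, feature, threshold, left, right, value):
    n = X.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for t in range(root.shape[0]):
            node = root[t]
            while left[node] >= 0:
                if X[i, feature[node]] < threshold[node]:
                    node = left[node]
                else:
                    node = right[node]
            out[i] += value[node]
    return out


@njit(cache=False)
def shap_interventional(X, B, root, feature, threshold, left, right, value, PW, NW):
    """phi[i, j]: mean over background rows of the per-pair Shapley value."""
    n, p = X.shape
    nb = B.shape[0]
    phi = np.zeros((n, p))

    cap = 4 * (PW.shape[0] + 2)  # DFS stack bound: <= 2 entries per level
    stack_node = np.empty(cap, dtype=np.int64)
    stack_nu = np.empty(cap, dtype=np.int64)
    stack_feat = np.empty(cap, dtype=np.int64)
    stack_state = np.empty(cap, dtype=np.int64)
    uf = np.empty(cap, dtype=np.int64)  # divergent features on current path
    ust = np.empty(cap, dtype=np.int64)  # 1: from x, 2: from background

    for i in range(n):
        for j in range(nb):
            for t in range(root.shape[0]):
                top = 0
                stack_node[top] = root[t]
                stack_nu[top] = 0
                stack_feat[top] = -1
                stack_state[top] = 0
                top += 1
                while top > 0:
                    top -= 1
                    node = stack_node[top]
                    nu = stack_nu[top]
                    if stack_feat[top] >= 0:
                        uf[nu] = stack_feat[top]
                        ust[nu] = stack_state[top]
                        nu += 1
                    if left[node] < 0:  # leaf
                        k = 0
                        m = 0
                        for q in range(nu):
                            if ust[q] == 1:
                                k += 1
                            else:
                                m += 1
                        if k + m == 0:
                            continue
                        v = value[node]
                        for q in range(nu):
                            if ust[q] == 1:
                                phi[i, uf[q]] += v * PW[k, m]
                            else:
                                phi[i, uf[q]] -= v * NW[k, m]
                        continue
                    f = feature[node]
                    thr = threshold[node]
                    x_left = X[i, f] < thr
                    b_left = B[j, f] < thr
                    if x_left == b_left:  # no divergence: one reachable child
                        child = left[node] if x_left else right[node]
                        stack_node[top] = child
                        stack_nu[top] = nu
                        stack_feat[top] = -1
                        stack_state[top] = 0
                        top += 1
                        continue
                    # x and b route differently: feature f becomes constrained
                    prev = 0
                    for q in range(nu):
                        if uf[q] == f:
                            prev = ust[q]
                            break
                    x_child = left[node] if x_left else right[node]
                    b_child = left[node] if b_left else right[node]
                    if prev != 2:  # x-side child viable unless f pinned to b
                        stack_node[top] = x_child
                        stack_nu[top] = nu
                        stack_feat[top] = -1 if prev == 1 else f
                        stack_state[top] = 1
                        top += 1
                    if prev != 1:  # b-side child viable unless f pinned to x
                        stack_node[top] = b_child
                        stack_nu[top] = nu
                        stack_feat[top] = -1 if prev == 2 else f
                        stack_state[top] = 2
                        top += 1
    return phi / nb
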