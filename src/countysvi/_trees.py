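"""Flat-array view of an xgboost tree ensemble.

The explainer needs direct access to split structure (feature, threshold,
children, leaf values), which we take from the booster's JSON model
serialisation — unlike the text dump, it round-trips the float32 splits
exactly, so float64 comparisons reproduce the booster's routing for
float32 inputs bit-for-bit.

For link-function objectives (e.g. Poisson's log link) the arrays
represent the margin; ``predict`` returns margins and the caller applies
the inverse link where needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


@dataclass
class TreeEnsemble:
    """Node-array representation of a boosted regression forest.

    Arrays are concatenated over trees; ``root`` holds each tree's root
    offset and ``left[i] < 0`` marks node i as a leaf whose value is
    ``value[i]``.
    """

    root: np.ndarray  # (T,) int32 offsets into the node arrays
    feature: np.ndarray  # (N,) int32, -1 for leaves
    threshold: np.ndarray  # (N,) float64
    left: np.ndarray  # (N,) int32, -1 for leaves
    right: np.ndarray  # (N,) int32, -1 for leaves
    value: np.ndarray  # (N,) float64, leaf weight (0 for internal nodes)
    base_score: float
    n_features: int
    max_depth: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Margin prediction in float64 (base_score + sum of leaf values)."""
        from ._treeshap import predict_margin

        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32), dtype=np.float64)
        return predict_margin(
            X, self.root, self.feature, self.threshold, self.left, self.right, self.value
        ) + self.base_score


def _node_depths(left: np.ndarray, right: np.ndarray) -> int:
    depth = np.zeros(len(left), dtype=np.int64)
    max_d = 0
    stack = [(0, 0)]
    while stack:
        node, d = stack.pop()
        depth[node] = d
        if left[node] >= 0:
            stack.append((left[node], d + 1))
            stack.append((right[node], d + 1))
        else:
            max_d = max(max_d, d)
    return max_d


def parse_booster(model, n_features: int) -> TreeEnsemble:
    """Build a :class:`TreeEnsemble` from a fitted xgboost regressor.

    Accepts either an ``XGBRegressor`` or a raw ``Booster``.
    """
    booster = model.get_booster() if hasattr(model, "get_booster") else model
    raw = json.loads(bytes(booster.save_raw(raw_format="json")))
    learner = raw["learner"]
    base_score = float(learner["learner_model_param"]["base_score"])
    trees = learner["gradient_booster"]["model"]["trees"]

    roots, feats, thrs, lefts, rights, values = [], [], [], [], [], []
    max_depth = 0
    offset = 0
    for tree in trees:
        l = np.asarray(tree["left_children"], dtype=np.int32)
        r = np.asarray(tree["right_children"], dtype=np.int32)
        # serialized decimals are float32 quantities: snap back to float32
        # so threshold comparisons reproduce the booster's routing exactly
        cond = np.asarray(tree["split_conditions"], dtype=np.float32).astype(np.float64)
        idx = np.asarray(tree["split_indices"], dtype=np.int32)
        is_leaf = l < 0
        roots.append(offset)
        feats.append(np.where(is_leaf, -1, idx).astype(np.int32))
        thrs.append(np.where(is_leaf, 0.0, cond))
        # leaf value is stored in split_conditions for leaf nodes
        values.append(np.where(is_leaf, cond, 0.0))
        lefts.append(np.where(is_leaf, -1, np.where(l >= 0, l + offset, -1)).astype(np.int32))
        rights.append(np.where(is_leaf, -1, np.where(r >= 0, r + offset, -1)).astype(np.int32))
        max_depth = max(max_depth, _node_depths(l, r))
        offset += len(l)

    return TreeEnsemble(
        root=np.asarray(roots, dtype=np.int32),
        feature=np.concatenate(feats),
        threshold=np.concatenate(thrs),
        left=np.concatenate(lefts),
        right=np.concatenate(rights),
        value=np.concatenate(values),
        base_score=base_score,
        n_features=int(n_features),
        max_depth=int(max_depth),
    )
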