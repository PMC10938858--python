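"""Shapley-value attribution of the fitted suicide model.

Per-county, per-feature Shapley values under the interventional
(marginal) value function v(S) = E_b[f(x_S, b_{~S})], with the
expectation taken over an explicit, seeded background sample of design
rows.  The fast path is an exact tree-traversal computation
(:mod:`._treeshap`); :func:`exact_shapley` is an independent
subset-enumeration oracle using the classical Shapley formula, kept for
validation — both use the same value-function convention, so they agree
to numerical precision on small models.

Derived summaries: mean-|phi| feature importance ranking, effect
directions (sign of the correlation between a feature's values and its
Shapley column — the single-number version of reading a beeswarm
summary plot), and dependence-plot tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._trees import TreeEnsemble, parse_booster
from ._treeshap import shap_interventional, shapley_pair_weights


class AttributionError(ValueError):
    """Feature-set mismatch or ill-posed attribution request."""


@dataclass
class AttributionMatrix:
    """Shapley values phi (rows x features, units of the target), the
    background expectation ``base_value``, and the background rows used."""

    phi: pd.DataFrame
    base_value: float
    background: pd.DataFrame

    def efficiency_gap(self, predictions: np.ndarray) -> np.ndarray:
        """prediction − (base_value + Σ_j phi_ij); ≈ 0 row-wise."""
        return np.asarray(predictions, dtype=float) - (
            self.base_value + self.phi.to_numpy().sum(axis=1)
        )


@dataclass
class ImportanceReport:
    mean_abs: dict[str, float]  # feature -> mean |phi|
    rank: list[str]  # descending mean |phi|, alphabetical on ties
    direction: dict[str, int]  # feature -> +1 / -1 where defined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.rank,
                "mean_abs_shap": [self.mean_abs[f] for f in self.rank],
                "direction": [self.direction.get(f, 0) for f in self.rank],
            }
        )


class ShapExplainer:
    """Interventional Tree-Shapley explainer with a seeded background.

    Parameters
    ----------
    background_size : rows drawn (uniformly, without replacement) from
        the design to form the background sample; default 100.
    seed : RNG seed for the background draw.

    Fitted attributes
    -----------------
    background_ : the background rows.
    ensemble_ : flat-array view of the boosted trees.
    base_value_ : mean model prediction over the background.
    """

    def __init__(self, background_size: int = 100, seed: int = 0):
        self.background_size = background_size
        self.seed = seed

    def fit(self, model, X: pd.DataFrame):
        X = pd.DataFrame(X)
        booster = getattr(model, "booster_", model)
        feature_names = getattr(model, "feature_names_", list(X.columns))
        if list(X.columns) != list(feature_names):
            raise AttributionError(
                f"design features {list(X.columns)} do not match model features {list(feature_names)}"
            )
        self.feature_names_ = list(feature_names)
        self.ensemble_ = parse_booster(booster, n_features=len(self.feature_names_))
        rng = np.random.default_rng(self.seed)
        k = min(self.background_size, len(X))
        idx = np.sort(rng.choice(len(X), size=k, replace=False))
        self.background_ = X.iloc[idx]
        self.base_value_ = float(self.ensemble_.predict(self.background_.to_numpy()).mean())
        return self

    def transform(self, X: pd.DataFrame) -> AttributionMatrix:
        X = pd.DataFrame(X)
        if list(X.columns) != self.feature_names_:
            raise AttributionError("feature-set mismatch between fit and transform")
        ens = self.ensemble_
        # float32 cast first so comparisons reproduce the booster's routing
        Xa = np.ascontiguousarray(X.to_numpy(dtype=np.float32), dtype=np.float64)
        Ba = np.ascontiguousarray(
            self.background_.to_numpy(dtype=np.float32), dtype=np.float64
        )
        PW, NW = shapley_pair_weights(ens.n_features, ens.max_depth)
        phi = shap_interventional(
            Xa, Ba, ens.root, ens.feature, ens.threshold, ens.left, ens.right, ens.value, PW, NW
        )
        return AttributionMatrix(
            phi=pd.DataFrame(phi, index=X.index, columns=self.feature_names_),
            base_value=self.base_value_,
            background=self.background_,
        )

    def predict(self, X) -> np.ndarray:
        """Float64 margin prediction through the parsed ensemble."""
        return self.ensemble_.predict(pd.DataFrame(X).to_numpy())


def explain(model, design, background_size: int = 100, seed: int = 0) -> AttributionMatrix:
    """Attribute every design row against a seeded background sample."""
    X = design[0] if isinstance(design, tuple) else pd.DataFrame(design)
    return ShapExplainer(background_size=background_size, seed=seed).fit(model, X).transform(X)


def exact_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    features: Sequence[int] | None = None,
) -> np.ndarray:
    """Classical Shapley values by full subset enumeration (oracle).

    phi_i = sum over S ⊆ F∖{i} of |S|!(p−|S|−1)!/p! · [v(S∪{i}) − v(S)],
    with v(S) the mean prediction over background rows whose columns in S
    are replaced by x's values.  Refuses p > 20.
    """
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    features = list(range(x.shape[0])) if features is None else list(features)
    p = len(features)
    if p > 20:
        raise AttributionError(f"exact enumeration refused for p = {p} > 20 features")

    values: dict[frozenset, float] = {}
    for r in range(p + 1):
        for S in itertools.combinations(features, r):
            M = background.copy()
            if S:
                M[:, list(S)] = x[list(S)]
            values[frozenset(S)] = float(np.mean(predict(M)))

    fact = [math.factorial(i) for i in range(p + 1)]
    phi = np.zeros(x.shape[0])
    for i in features:
        rest = [f for f in features if f != i]
        for r in range(p):
            for S in itertools.combinations(rest, r):
                w = fact[r] * fact[p - r - 1] / fact[p]
                phi[i] += w * (values[frozenset(S) | {i}] - values[frozenset(S)])
    return phi


def importance(att: AttributionMatrix, design) -> ImportanceReport:
    """Mean-|phi| ranking and per-feature effect directions.

    direction(f) = sign of the Pearson correlation between feature f's
    values and its phi column; omitted when either side has zero
    variance (the correlation — hence a direction — is undefined).
    """
    X = design[0] if isinstance(design, tuple) else pd.DataFrame(design)
    if len(X) != len(att.phi):
        raise AttributionError("attribution rows do not align with design rows")
    phi = att.phi
    mean_abs = {f: float(phi[f].abs().mean()) for f in phi.columns}
    rank = sorted(mean_abs, key=lambda f: (-mean_abs[f], f))
    direction: dict[str, int] = {}
    for f in phi.columns:
        pv = phi[f].to_numpy()
        xv = X[f].to_numpy(dtype=float)
        if pv.std() == 0.0 or xv.std() == 0.0:
            continue
        r = float(np.corrcoef(xv, pv)[0, 1])
        if r != 0.0 and np.isfinite(r):
            direction[f] = int(np.sign(r))
    return ImportanceReport(mean_abs=mean_abs, rank=rank, direction=direction)


def dependence_data(
    att: AttributionMatrix, design, feature: str, color_feature: str = "Population"
) -> pd.DataFrame:
    """Scatter table for a dependence plot: one row per county, columns
    (value, phi, color), sorted by feature value, no aggregation."""
    X = design[0] if isinstance(design, tuple) else pd.DataFrame(design)
    for f in (feature, color_feature):
        if f not in X.columns:
            raise AttributionError(f"unknown feature {f!r}")
    if feature not in att.phi.columns:
        raise AttributionError(f"feature {feature!r} absent from attribution matrix")
    out = pd.DataFrame(
        {
            "value": X[feature].to_numpy(dtype=float),
            "phi": att.phi[feature].to_numpy(),
            "color": X[color_feature].to_numpy(dtype=float),
        },
        index=X.index,
    )
    return out.sort_values("value", kind="mergesort")
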