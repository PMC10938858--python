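"""Suicide Vulnerability Index (SVI) construction.

The index for a county is

    SVI = sum_{i=1..p} W_i * X_i,

where the X_i are directional percentile ranks of the top-p features by
mean-|SHAP| importance and the W_i are those mean magnitudes normalised
to sum to one.  Features whose Shapley direction is positive are ranked
highest-to-lowest (a large value means high vulnerability); negative-
direction features are ranked lowest-to-highest, so a *low* value of,
say, the share of female residents maps to a *high* percentile score.
With X_i in [0, 1] and the W_i a convex combination, the index lands on
the 0–1 vulnerability scale by construction.

Percentile convention: X = (rank − 1) / (N − 1) with ascending ranks
1..N and ties given their mean rank — the unique maximum scores exactly
1.00 and the unique minimum exactly 0.00, matching how the published
reference table prints extremes.

A reference table of ten counties with published percentile scores and
index values ships with the package (``load_reference_table``); since
the weights behind it were never published, :func:`estimate_weights`
recovers them by constrained least squares for validation.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata

from .attribution import ImportanceReport
from .panel import SVI_BINS, BinSpec


class SviError(ValueError):
    """Ill-posed index construction."""


DEFAULT_P = 5


@dataclass
class WeightVector:
    """Non-negative feature weights summing to one over exactly p features."""

    weights: dict[str, float]
    p: int = DEFAULT_P

    def __post_init__(self) -> None:
        if len(self.weights) != self.p:
            raise SviError(f"expected {self.p} weights, got {len(self.weights)}")
        w = np.asarray(list(self.weights.values()), dtype=float)
        if np.any(w < -1e-12):
            raise SviError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise SviError(f"weights must sum to 1, got {w.sum():.12f}")
        self.weights = {k: max(0.0, float(v)) for k, v in self.weights.items()}

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, dtype=float)


@dataclass
class SviTable:
    """Per-county index table: percentile scores X_i, the index on
    [0, 1] (full precision and 2-decimal), and the vulnerability bin."""

    table: pd.DataFrame  # index fips; columns X_<feature>..., svi, svi_rounded, bin
    weights: WeightVector
    directions: dict[str, int] = field(default_factory=dict)

    def to_csv(self, sink) -> None:
        self.table.to_csv(sink, float_format="%.10g", lineterminator="\n")


def select_top_features(
    report: ImportanceReport, p: int = DEFAULT_P
) -> list[tuple[str, int]]:
    """The first p ranked features, each tagged with its direction."""
    if p < 1 or p > len(report.rank):
        raise SviError(f"cannot select top {p} of {len(report.rank)} ranked features")
    out = []
    for f in report.rank[:p]:
        if f not in report.direction:
            raise SviError(f"selected feature {f!r} has no defined direction")
        out.append((f, report.direction[f]))
    return out


def directional_percentile(
    values: Mapping[str, float], direction: int
) -> dict[str, float]:
    """Percentile scores X in [0, 1] after orienting toward vulnerability.

    X = (rank(direction × value) − 1) / (N − 1), ascending mean ranks.
    """
    if direction not in (+1, -1):
        raise SviError(f"direction must be +1 or -1, got {direction}")
    keys = list(values)
    n = len(keys)
    if n < 2:
        raise SviError("directional percentile needs at least 2 counties")
    t = direction * np.asarray([values[k] for k in keys], dtype=float)
    ranks = rankdata(t, method="average")
    x = (ranks - 1.0) / (n - 1.0)
    return {k: float(v) for k, v in zip(keys, x)}


def weights_from_importance(
    report: ImportanceReport, selected: Sequence[str]
) -> WeightVector:
    """W_i = mean|phi|_i normalised over the selected features."""
    missing = [f for f in selected if f not in report.mean_abs]
    if missing:
        raise SviError(f"features absent from importance report: {missing}")
    mags = np.asarray([report.mean_abs[f] for f in selected], dtype=float)
    total = mags.sum()
    if total <= 0:
        raise SviError("all selected mean-|SHAP| magnitudes are zero")
    return WeightVector(
        weights={f: float(m / total) for f, m in zip(selected, mags)}, p=len(selected)
    )


def compute_svi(
    X: Mapping[str, Mapping[str, float]], W: WeightVector
) -> dict[str, float]:
    """Weighted sum Σ W_i X_i per county.

    ``X`` maps feature -> (fips -> percentile score); every county must
    carry a score for every weighted feature.
    """
    feats = list(W.weights)
    missing_feats = [f for f in feats if f not in X]
    if missing_feats:
        raise SviError(f"percentile scores missing for feature(s) {missing_feats}")
    counties = sorted(set().union(*(X[f].keys() for f in feats)))
    out: dict[str, float] = {}
    for c in counties:
        total = 0.0
        for f in feats:
            if c not in X[f]:
                raise SviError(f"county {c} lacks a percentile score for feature {f!r}")
            total += W.weights[f] * X[f][c]
        out[c] = total
    return out


def classify(svi: Mapping[str, float], bins: BinSpec = SVI_BINS) -> dict[str, str]:
    """Vulnerability bin per county over [0,0.2) … [0.8,1] (top closed)."""
    keys = list(svi)
    vals = np.asarray([svi[k] for k in keys], dtype=float)
    if len(vals) and (vals.min() < 0.0 or vals.max() > 1.0):
        raise SviError("index values outside [0, 1]")
    labels = bins.assign(vals) if len(vals) else np.array([], dtype=object)
    return {k: str(l) for k, l in zip(keys, labels)}


def estimate_weights(
    rows: Sequence[tuple[Sequence[float], float]], p: int | None = None
) -> tuple[WeightVector, np.ndarray]:
    """Recover weights from (percentile vector, printed index) pairs.

    Constrained least squares: minimise Σ (x·W − svi)² subject to W ≥ 0
    and Σ W = 1.  Returns the weights (keyed w1..wp unless the caller
    re-labels them) and the per-row residual vector.  Deterministic.
    """
    if len(rows) < 5:
        raise SviError("weight estimation needs at least 5 rows")
    A = np.asarray([list(r[0]) for r in rows], dtype=float)
    y = np.asarray([r[1] for r in rows], dtype=float)
    p = p or A.shape[1]
    if A.shape[1] != p:
        raise SviError(f"expected {p}-vectors, got width {A.shape[1]}")
    if np.linalg.matrix_rank(A) < p:
        warnings.warn(
            f"rank-deficient percentile matrix (rank {np.linalg.matrix_rank(A)} < {p}); "
            "fitted weights are not unique",
            RuntimeWarning,
            stacklevel=2,
        )

    def objective(w: np.ndarray) -> float:
        return float(((A @ w - y) ** 2).sum())

    res = minimize(
        objective,
        np.full(p, 1.0 / p),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * p,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    residuals = A @ w - y
    weights = WeightVector(weights={f"w{i + 1}": float(v) for i, v in enumerate(w)}, p=p)
    return weights, residuals


def load_reference_table() -> pd.DataFrame:
    """Ten published worked examples of the index: county, state, the
    five percentile scores (Population, MedianAge, %White,
    %AfricanAmerican, %Female) and the printed 2-decimal index."""
    ref = importlib.resources.files("countysvi.data") / "reference_svi_examples.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


REFERENCE_FEATURE_ORDER = ("Population", "MedianAge", "%White", "%AfricanAmerican", "%Female")


def estimate_reference_weights() -> tuple[WeightVector, np.ndarray]:
    """Weights recovered once from all ten reference rows, keyed by the
    reference table's feature order."""
    ref = load_reference_table()
    rows = [
        (row[list(REFERENCE_FEATURE_ORDER)].to_numpy(dtype=float), float(row["svi"]))
        for _, row in ref.iterrows()
    ]
    w, resid = estimate_weights(rows, p=len(REFERENCE_FEATURE_ORDER))
    keyed = WeightVector(
        weights=dict(zip(REFERENCE_FEATURE_ORDER, w.as_series().to_numpy())),
        p=len(REFERENCE_FEATURE_ORDER),
    )
    return keyed, resid


class VulnerabilityIndex:
    """Transformer building the index from a design matrix.

    Parameters
    ----------
    p : number of top features (default 5).
    weights : optional fixed weights (feature -> W_i); when omitted the
        weights come from mean-|SHAP| magnitudes of the fitted report.
    bins : vulnerability bin spec.

    Fitted attributes: ``features_`` (selected, with directions),
    ``weights_`` (a :class:`WeightVector`), ``directions_``.
    """

    def __init__(
        self,
        p: int = DEFAULT_P,
        weights: Mapping[str, float] | None = None,
        bins: BinSpec = SVI_BINS,
    ):
        self.p = p
        self.weights = weights
        self.bins = bins

    def fit(self, report: ImportanceReport):
        selected = select_top_features(report, self.p)
        self.features_ = [f for f, _ in selected]
        self.directions_ = dict(selected)
        if self.weights is not None:
            if set(self.weights) != set(self.features_):
                raise SviError(
                    f"fixed weights keys {sorted(self.weights)} do not match "
                    f"selected features {sorted(self.features_)}"
                )
            self.weights_ = WeightVector(weights=dict(self.weights), p=self.p)
        else:
            self.weights_ = weights_from_importance(report, self.features_)
        return self

    def transform(self, design) -> SviTable:
        X = design[0] if isinstance(design, tuple) else pd.DataFrame(design)
        scores: dict[str, dict[str, float]] = {}
        for f in self.features_:
            if f not in X.columns:
                raise SviError(f"design lacks selected feature {f!r}")
            values = {str(i): float(v) for i, v in X[f].items()}
            scores[f] = directional_percentile(values, self.directions_[f])
        svi = compute_svi(scores, self.weights_)
        assert all(-1e-12 <= v <= 1.0 + 1e-12 for v in svi.values()), "index left [0, 1]"
        svi = {k: min(max(v, 0.0), 1.0) for k, v in svi.items()}
        bins = classify(svi, self.bins)
        counties = sorted(svi)
        table = pd.DataFrame(
            {
                **{f"X_{f}": [scores[f][c] for c in counties] for f in self.features_},
                "svi": [svi[c] for c in counties],
                "svi_rounded": [round(svi[c], 2) for c in counties],
                "bin": [bins[c] for c in counties],
            },
            index=pd.Index(counties, name="fips"),
        )
        return SviTable(table=table, weights=self.weights_, directions=dict(self.directions_))
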