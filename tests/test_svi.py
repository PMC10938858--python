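"""Vulnerability index: percentiles, weights, Eq.-style weighted sum, bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countysvi import (
    VulnerabilityIndex,
    WeightVector,
    classify,
    compute_svi,
    directional_percentile,
    estimate_reference_weights,
    estimate_weights,
    load_reference_table,
    select_top_features,
    weights_from_importance,
)
from countysvi.attribution import ImportanceReport
from countysvi.svi import REFERENCE_FEATURE_ORDER, SviError


def _report(mean_abs, direction=None):
    rank = sorted(mean_abs, key=lambda f: (-mean_abs[f], f))
    return ImportanceReport(
        mean_abs=dict(mean_abs),
        rank=rank,
        direction=direction or {f: 1 for f in mean_abs},
    )


class TestSelectTopFeatures:
    def test_published_selection_shape(self):
        # The published analysis selects Population(+), %AfricanAmerican(-),
        # %White(+), MedianAge(+), %Female(-) as its top five.
        rep = _report(
            {"Population": 5, "%AfricanAmerican": 4, "%White": 3, "MedianAge": 2, "%Female": 1, "%Poverty": 0.5},
            direction={"Population": 1, "%AfricanAmerican": -1, "%White": 1, "MedianAge": 1, "%Female": -1, "%Poverty": 1},
        )
        sel = select_top_features(rep, p=5)
        assert sel == [
            ("Population", 1),
            ("%AfricanAmerican", -1),
            ("%White", 1),
            ("MedianAge", 1),
            ("%Female", -1),
        ]

    def test_p_one_and_guard(self):
        rep = _report({"a": 2.0, "b": 1.0})
        assert select_top_features(rep, p=1) == [("a", 1)]
        with pytest.raises(SviError):
            select_top_features(rep, p=3)

    def test_missing_direction_rejected(self):
        rep = _report({"a": 2.0, "b": 1.0}, direction={"a": 1})
        with pytest.raises(SviError):
            select_top_features(rep, p=2)


class TestDirectionalPercentile:
    def test_ascending_convention(self):
        values = {f"c{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5])}
        x = directional_percentile(values, +1)
        assert [x[f"c{i}"] for i in range(5)] == [0.0, 0.25, 0.5, 0.75, 1.0]

    def test_negative_direction_reverses(self):
        values = {f"c{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5])}
        x = directional_percentile(values, -1)
        assert [x[f"c{i}"] for i in range(5)] == [1.0, 0.75, 0.5, 0.25, 0.0]

    def test_low_value_under_negative_direction_scores_high(self):
        # e.g. a county with a very small minority share, when that share
        # carries a negative effect, lands near the top of the score range
        values = {"todd": 1.0, "a": 20.0, "b": 30.0, "c": 40.0}
        x = directional_percentile(values, -1)
        assert x["todd"] == 1.0

    def test_ties_get_mean_rank(self):
        x = directional_percentile({"a": 1.0, "b": 2.0, "c": 2.0, "d": 3.0}, +1)
        assert x["b"] == x["c"] == pytest.approx(0.5)

    def test_needs_two_counties(self):
        with pytest.raises(SviError):
            directional_percentile({"a": 1.0}, +1)


class TestWeights:
    def test_normalization(self):
        rep = _report({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        w = weights_from_importance(rep, ["a", "b", "c", "d"])
        assert w.as_series().tolist() == pytest.approx([0.4, 0.3, 0.2, 0.1])

    def test_equal_magnitudes_uniform(self):
        rep = _report({f: 2.0 for f in "abcde"})
        w = weights_from_importance(rep, list("abcde"))
        assert all(v == pytest.approx(0.2) for v in w.weights.values())

    def test_scale_invariance(self):
        rep1 = _report({"a": 4.0, "b": 1.0})
        rep7 = _report({"a": 28.0, "b": 7.0})
        w1 = weights_from_importance(rep1, ["a", "b"])
        w7 = weights_from_importance(rep7, ["a", "b"])
        assert w1.weights == pytest.approx(w7.weights)

    def test_weight_vector_invariants_enforced(self):
        with pytest.raises(SviError):
            WeightVector(weights={"a": 0.7, "b": 0.7}, p=2)
        with pytest.raises(SviError):
            WeightVector(weights={"a": 1.2, "b": -0.2}, p=2)


class TestComputeSvi:
    def test_extremes(self):
        w = WeightVector(weights={"a": 0.6, "b": 0.4}, p=2)
        lo = compute_svi({"a": {"c1": 0.0}, "b": {"c1": 0.0}}, w)
        hi = compute_svi({"a": {"c1": 1.0}, "b": {"c1": 1.0}}, w)
        assert lo["c1"] == 0.0 and hi["c1"] == 1.0

    def test_missing_feature_named(self):
        w = WeightVector(weights={"a": 0.6, "b": 0.4}, p=2)
        with pytest.raises(SviError, match="c1.*'b'"):
            compute_svi({"a": {"c1": 0.5}, "b": {}}, w)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(
        x=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        bump=st.floats(0.01, 0.5),
    )
    def test_monotone_in_any_percentile(self, x, bump):
        w = WeightVector(weights={"a": 0.5, "b": 0.3, "c": 0.2}, p=3)
        scores = {f: {"c1": v} for f, v in zip("abc", x)}
        base = compute_svi(scores, w)["c1"]
        scores["a"]["c1"] = min(1.0, x[0] + bump)
        assert compute_svi(scores, w)["c1"] >= base


class TestReferenceTable:
    """The ten published worked examples pin down the weighted-sum form."""

    def test_weights_estimated_once_reproduce_printed_indices(self):
        w, resid = estimate_reference_weights()
        ref = load_reference_table().set_index("county")
        for county in ("Orange County", "Suffolk County", "Jones County", "Todd County"):
            row = ref.loc[county]
            x = row[list(REFERENCE_FEATURE_ORDER)].to_numpy(dtype=float)
            svi = float(np.dot(x, w.as_series().to_numpy()))
            assert round(svi, 2) == pytest.approx(row["svi"], abs=0.011)

    def test_residuals_stay_below_flag_threshold(self):
        _, resid = estimate_reference_weights()
        assert np.abs(resid).max() <= 0.02

    def test_population_weight_dominates(self):
        w, _ = estimate_reference_weights()
        assert w.weights["Population"] == max(w.weights.values())


class TestEstimateWeights:
    def test_exact_recovery_from_noiseless_rows(self):
        rng = np.random.default_rng(0)
        true_w = np.array([0.5, 0.2, 0.15, 0.1, 0.05])
        A = rng.uniform(size=(12, 5))
        rows = [(a, float(a @ true_w)) for a in A]
        w, resid = estimate_weights(rows)
        np.testing.assert_allclose(w.as_series().to_numpy(), true_w, atol=1e-8)
        assert np.abs(resid).max() < 1e-8

    def test_duplicated_rows_do_not_change_fit(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(size=(8, 5))
        true_w = np.array([0.3, 0.3, 0.2, 0.1, 0.1])
        rows = [(a, float(a @ true_w) + 0.01 * rng.standard_normal()) for a in A]
        w1, _ = estimate_weights(rows)
        w2, _ = estimate_weights(rows + rows)
        np.testing.assert_allclose(
            w1.as_series().to_numpy(), w2.as_series().to_numpy(), atol=1e-6
        )

    def test_rank_deficiency_warns_but_returns(self):
        rows = [([0.5, 0.5, 0.0, 0.0, 0.0], 0.5)] * 6
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            w, _ = estimate_weights(rows)
        assert sum(w.weights.values()) == pytest.approx(1.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(SviError):
            estimate_weights([([0.1] * 5, 0.1)] * 4)


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected", [(0.90, "0.8–1"), (0.05, "0–0.2"), (0.2, "0.2–0.4"), (1.0, "0.8–1")]
    )
    def test_bin_assignment(self, value, expected):
        assert classify({"c": value})["c"] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(SviError):
            classify({"c": 1.0001})


class TestVulnerabilityIndexTransformer:
    def test_fixed_weights_override_importance(self):
        rep = _report({"a": 9.0, "b": 1.0}, direction={"a": 1, "b": -1})
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, index=["x", "y", "z"])
        vi = VulnerabilityIndex(p=2, weights={"a": 0.5, "b": 0.5}).fit(rep)
        table = vi.transform(X).table
        # a ascends, b reversed: every county scores 0.5 exactly
        assert table["svi"].tolist() == pytest.approx([0.5, 0.5, 0.5])

    def test_index_bounded_and_binned(self, medium_panel):
        from countysvi import ModelSpec, explain, fit, importance, make_design

        panel, _ = medium_panel
        spec = ModelSpec(grid={"max_depth": (3,), "learning_rate": (0.1,), "n_estimators": (100,)}, cv_folds=3, split_seed=1)
        design = make_design(panel, spec)
        model = fit(design, spec)
        att = explain(model, design, background_size=40, seed=1)
        rep = importance(att, design)
        table = VulnerabilityIndex(p=5).fit(rep).transform(design).table
        assert table["svi"].between(0, 1).all()
        assert set(table["bin"]).issubset(set(classify({"a": 0.1})["a"] for _ in [0]) | {"0–0.2", "0.2–0.4", "0.4–0.6", "0.6–0.8", "0.8–1"})
        assert len(table) == len(panel.counties)

    def test_permutation_invariance_of_scores(self):
        rep = _report({"a": 3.0, "b": 1.0}, direction={"a": 1, "b": -1})
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {"a": rng.normal(size=20), "b": rng.normal(size=20)},
            index=[f"{i:05d}" for i in range(20)],
        )
        vi = VulnerabilityIndex(p=2).fit(rep)
        t1 = vi.transform(X).table
        t2 = vi.transform(X.sample(frac=1.0, random_state=4)).table
        pd.testing.assert_frame_equal(t1, t2)
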