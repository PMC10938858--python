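"""Shapley attribution: axioms, oracle agreement, summaries."""

import numpy as np
import pandas as pd
import pytest

from countysvi import ShapExplainer, dependence_data, exact_shapley, explain, importance
from countysvi.attribution import AttributionError, AttributionMatrix


class TestExactOracle:
    """The enumeration oracle satisfies the Shapley axioms in closed form."""

    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(0)
        c = np.array([2.0, -1.0, 0.5, 3.0])
        bg = rng.normal(size=(30, 4))
        x = rng.normal(size=4)
        phi = exact_shapley(lambda M: M @ c, x, bg)
        np.testing.assert_allclose(phi, c * (x - bg.mean(axis=0)), atol=1e-10)

    def test_dummy_feature_gets_zero(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(20, 3))
        phi = exact_shapley(lambda M: M[:, 0] ** 2 + M[:, 2], rng.normal(size=3), bg)
        assert phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_for_exchangeable_features(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=20)
        bg = np.column_stack([col, col, rng.normal(size=20)])  # identical marginals
        x = np.array([1.3, 1.3, -0.2])
        phi = exact_shapley(lambda M: M[:, 0] * M[:, 1] + M[:, 2], x, bg)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_refuses_wide_problems(self):
        with pytest.raises(AttributionError):
            exact_shapley(lambda M: M.sum(axis=1), np.zeros(21), np.zeros((5, 21)))


class TestFastExplainer:
    def test_agrees_with_exact_enumeration_on_small_tree(self, fitted_small_tree):
        model, Xq, bg = fitted_small_tree
        explainer = ShapExplainer(background_size=50, seed=0)
        explainer.fit(model, pd.concat([Xq, bg]))
        explainer.background_ = bg  # pin the exact background used by the oracle
        explainer.base_value_ = float(explainer.predict(bg).mean())
        att = explainer.transform(Xq)
        for i in range(len(Xq)):
            phi_exact = exact_shapley(explainer.predict, Xq.iloc[i].to_numpy(), bg.to_numpy())
            np.testing.assert_allclose(att.phi.iloc[i].to_numpy(), phi_exact, atol=1e-6)

    def test_parsed_trees_reproduce_booster_predictions(self, fitted_small_tree):
        model, Xq, bg = fitted_small_tree
        explainer = ShapExplainer(background_size=50, seed=0).fit(model, pd.concat([Xq, bg]))
        ours = explainer.predict(Xq)
        theirs = model.predict(Xq.to_numpy(dtype=np.float32))
        np.testing.assert_allclose(ours, theirs, rtol=1e-5, atol=1e-5)

    def test_efficiency_rows_sum_to_prediction_minus_base(self, fitted_small_tree):
        model, Xq, bg = fitted_small_tree
        design = pd.concat([Xq, bg])
        att = explain(model, design, background_size=30, seed=4)
        explainer = ShapExplainer(background_size=30, seed=4).fit(model, design)
        gap = att.efficiency_gap(explainer.predict(design))
        assert np.abs(gap).max() < 1e-6 * max(1.0, np.abs(explainer.predict(design)).max())

    def test_constant_model_attributes_nothing(self):
        import xgboost as xgb

        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = np.full(40, 7.0)
        model = xgb.XGBRegressor(n_estimators=5, max_depth=2, n_jobs=1, random_state=0)
        model.fit(X.to_numpy(np.float32), y)
        att = explain(model, X, background_size=20, seed=0)
        np.testing.assert_allclose(att.phi.to_numpy(), 0.0, atol=1e-9)
        assert att.base_value == pytest.approx(7.0, rel=1e-6)

    def test_feature_mismatch_rejected(self, fitted_small_tree):
        model, Xq, bg = fitted_small_tree
        explainer = ShapExplainer(background_size=10, seed=0).fit(model, Xq)
        with pytest.raises(AttributionError):
            explainer.transform(Xq.rename(columns={"a": "zz"}))


class TestImportance:
    def _att(self, phi: pd.DataFrame) -> AttributionMatrix:
        return AttributionMatrix(phi=phi, base_value=0.0, background=phi.iloc[:2])

    def test_rank_by_mean_abs_with_alphabetical_ties(self):
        phi = pd.DataFrame({"b": [1.0, -1.0], "a": [1.0, 1.0], "c": [0.5, 0.5]})
        X = pd.DataFrame({"b": [0.0, 1.0], "a": [0.0, 1.0], "c": [0.0, 1.0]})
        rep = importance(self._att(phi), X)
        assert rep.rank == ["a", "b", "c"]  # |b| ties |a| at 1.0 -> alphabetical

    def test_direction_is_sign_of_correlation(self):
        x = np.linspace(0, 1, 10)
        phi = pd.DataFrame({"up": x * 2, "down": -x})
        X = pd.DataFrame({"up": x, "down": x})
        rep = importance(self._att(phi), X)
        assert rep.direction == {"up": 1, "down": -1}

    def test_zero_variance_phi_column_omitted_from_directions(self):
        phi = pd.DataFrame({"flat": [0.0, 0.0, 0.0], "live": [1.0, 2.0, 3.0]})
        X = pd.DataFrame({"flat": [1.0, 2.0, 3.0], "live": [1.0, 2.0, 3.0]})
        rep = importance(self._att(phi), X)
        assert "flat" not in rep.direction and rep.direction["live"] == 1

    def test_misaligned_rows_rejected(self):
        phi = pd.DataFrame({"a": [1.0, 2.0]})
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(AttributionError):
            importance(self._att(phi), X)


class TestDependenceData:
    def test_one_row_per_county_sorted_with_fixed_columns(self, fitted_small_tree):
        model, Xq, bg = fitted_small_tree
        att = explain(model, Xq, background_size=10, seed=0)
        out = dependence_data(att, Xq, "b", color_feature="a")
        assert list(out.columns) == ["value", "phi", "color"]
        assert len(out) == len(Xq)
        assert out["value"].is_monotonic_increasing

    def test_unknown_feature_rejected(self, fitted_small_tree):
        model, Xq, _ = fitted_small_tree
        att = explain(model, Xq, background_size=10, seed=0)
        with pytest.raises(AttributionError):
            dependence_data(att, Xq, "nope")

    def test_monotone_effect_yields_positive_rank_correlation(self):
        import xgboost as xgb
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["m", "n"])
        y = 3.0 * X["m"].to_numpy()  # noiseless monotone effect
        model = xgb.XGBRegressor(n_estimators=50, max_depth=3, n_jobs=1, random_state=0)
        model.fit(X.to_numpy(np.float32), y)
        att = explain(model, X, background_size=50, seed=1)
        out = dependence_data(att, X, "m", color_feature="n")
        rho = spearmanr(out["value"], out["phi"]).statistic
        assert rho > 0.9
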