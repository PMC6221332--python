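import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import heatthresh as ht
from heatthresh.mars import (
    FitConfig,
    HingeFactor,
    backward_prune,
    fit,
    forward_pass,
    gcv_score,
    hinge_value,
    load_model,
    serialize_model,
    variable_importance,
)

from .oracles import best_single_pair, best_subset_gcv


class TestHinge:
    def test_zero_at_knot(self):
        for d in ("upward", "downward"):
            assert hinge_value(32.95, HingeFactor("x", 32.95, d)) == 0.0

    def test_unit_offset(self):
        assert hinge_value(6.0, HingeFactor("x", 5.0, "upward")) == 1.0
        assert hinge_value(6.0, HingeFactor("x", 5.0, "downward")) == 0.0

    def test_published_knot_offset(self):
        assert hinge_value(34.0, HingeFactor("x", 32.95, "upward")) == pytest.approx(1.05)

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            HingeFactor("x", 1.0, "sideways")


class TestPredict:
    def test_additive_model_at_knots(self, additive_model):
        assert additive_model.predict(
            {"AvgTmaxLag1": 32.95, "Nindex1": 79.65}
        ) == pytest.approx(0.08, abs=1e-15)

    def test_additive_model_above_knot(self, additive_model):
        assert additive_model.predict(
            {"AvgTmaxLag1": 34.0, "Nindex1": 70.0}
        ) == pytest.approx(0.26795, abs=1e-12)

    def test_interaction_model_at_knots(self, interaction_model):
        assert interaction_model.predict(
            {"Tavg": 25.1, "AvgTmaxLag1": 32.0, "Whum": 81.3}
        ) == pytest.approx(0.028, abs=1e-15)

    def test_missing_covariate_named(self, additive_model):
        with pytest.raises(ValueError, match="Nindex1"):
            additive_model.predict({"AvgTmaxLag1": 33.0})

    def test_dataframe_vectorised(self, additive_model):
        df = pd.DataFrame({"AvgTmaxLag1": [30.0, 34.0], "Nindex1": [70.0, 70.0]})
        out = additive_model.predict(df)
        np.testing.assert_allclose(out, [0.08 - 0.009 * 2.95, 0.26795])

    def test_piecewise_continuity_in_each_covariate(self, additive_model):
        # dense sweep: |f(x+h) - f(x)| bounded by Lipschitz constant * h
        grid = np.linspace(20.0, 45.0, 5001)
        vals = additive_model.predict(
            {"AvgTmaxLag1": grid, "Nindex1": np.full_like(grid, 80.0)}
        )
        max_slope = sum(abs(t.coefficient) for t in additive_model.terms)
        assert np.max(np.abs(np.diff(vals))) <= max_slope * (grid[1] - grid[0]) + 1e-12


class TestGCV:
    def test_zero_rss(self):
        assert gcv_score(0.0, 100, 3, 2, 3.0) == 0.0

    def test_formula_value(self):
        # (10/100) / (1 - 10/100)^2 with C = 1 + 3 + 3*2 = 10
        assert gcv_score(10.0, 100, 3, 2, 3.0) == pytest.approx(0.12345679012345678)

    def test_increasing_in_knots(self):
        vals = [gcv_score(10.0, 100, 3, k, 3.0) for k in range(5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_saturated_error(self):
        with pytest.raises(ValueError):
            gcv_score(1.0, 10, 5, 2, 3.0)


class TestForwardPass:
    def test_constant_response_intercept_only(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        model, _ = forward_pass(X, np.full(20, 3.0), FitConfig())
        assert model.terms == []
        assert model.rss == pytest.approx(0.0, abs=1e-20)

    def test_requires_10_obs(self):
        X = pd.DataFrame({"x": np.arange(5.0)})
        with pytest.raises(ValueError):
            forward_pass(X, np.arange(5.0))

    def test_rejects_missing_values(self):
        X = pd.DataFrame({"x": [1.0, np.nan] + list(range(10))})
        with pytest.raises(ValueError, match="missing"):
            forward_pass(X, np.arange(12.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_first_pair_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        X = pd.DataFrame(
            {
                "a": rng.uniform(0, 10, n),
                "b": rng.normal(0, 3, n),
                "c": rng.uniform(-5, 5, n),
            }
        )
        y = (
            2.0 * np.maximum(X["a"] - 5.0, 0.0)
            - 1.0 * np.maximum(0.5 - X["b"], 0.0)
            + rng.normal(0, 0.2, n)
        )
        cfg = FitConfig(max_terms=3, min_span=2)
        _, trace = forward_pass(X, y.to_numpy(), cfg)
        step = trace["forward"][0]
        rss_o, var_o, knot_o = best_single_pair(X, y.to_numpy(), min_span=2)
        assert step["variable"] == var_o
        assert step["knot"] == pytest.approx(knot_o, abs=1e-12)
        assert step["rss_after"] == pytest.approx(rss_o, abs=1e-8)

    def test_rss_non_increasing_over_steps(self, hinge_data):
        X, y = hinge_data
        _, trace = forward_pass(X, y, FitConfig())
        rss = [s["rss_before"] for s in trace["forward"]] + [
            trace["forward"][-1]["rss_after"]
        ]
        assert all(b <= a + 1e-12 for a, b in zip(rss, rss[1:]))

    def test_true_variables_selected_over_decoys(self, additive_model):
        rng = np.random.default_rng(11)
        n = 600
        X = pd.DataFrame(
            {
                "AvgTmaxLag1": rng.uniform(25, 40, n),
                "Nindex1": rng.uniform(60, 100, n),
                "d1": rng.normal(size=n),
                "d2": rng.normal(size=n),
                "d3": rng.normal(size=n),
            }
        )
        y = additive_model.predict(X) + rng.normal(0, 0.02, n)
        model, _ = forward_pass(X, y, FitConfig())
        assert {"AvgTmaxLag1", "Nindex1"} <= set(model.variables)


class TestBackwardPrune:
    def test_intercept_only_unchanged(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        model, trace = forward_pass(X, np.full(20, 1.5), FitConfig())
        pruned = backward_prune(model, X, np.full(20, 1.5), FitConfig(), trace)
        assert pruned.terms == []

    @pytest.mark.parametrize("seed", range(4))
    def test_selected_subset_attains_exhaustive_best_gcv(self, seed):
        # one true hinge plus a pure-noise covariate, small noise: the
        # greedy delete-one path visits the exhaustive-best subset
        rng = np.random.default_rng(100 + seed)
        n = 200
        X = pd.DataFrame({"a": rng.uniform(0, 10, n), "b": rng.normal(size=n)})
        y = 2.0 * np.maximum(X["a"] - 5.0, 0.0) + rng.normal(0, 0.05, n)
        cfg = FitConfig(max_terms=5, min_span=3)
        unpruned, trace = forward_pass(X, y.to_numpy(), cfg)
        assert len(unpruned.terms) <= 5
        pruned = backward_prune(unpruned, X, y.to_numpy(), cfg, trace)
        assert set(pruned.variables) == {"a"}
        g_best, _ = best_subset_gcv(unpruned, X, y.to_numpy(), cfg)
        assert pruned.gcv == pytest.approx(g_best, rel=1e-9)

    def test_noise_term_pruned(self):
        rng = np.random.default_rng(8)
        n = 200
        X = pd.DataFrame({"x": rng.uniform(0, 10, n), "z": rng.normal(size=n)})
        y = 2.0 * np.maximum(X["x"] - 5.0, 0.0) + rng.normal(0, 0.05, n)
        res = ht.MarsRegression(y, X).fit()
        assert set(res.spline.variables) == {"x"}


class TestFit:
    def test_pruned_gcv_not_worse_than_unpruned(self, hinge_data):
        X, y = hinge_data
        cfg = FitConfig()
        unpruned, trace = forward_pass(X, y, cfg)
        pruned = backward_prune(unpruned, X, y, cfg, trace)
        assert pruned.gcv <= unpruned.gcv + 1e-15

    def test_linear_response_recovers_slope_on_both_sides(self):
        rng = np.random.default_rng(21)
        n = 300
        x = rng.uniform(-5, 5, n)
        y = 2.0 * x + rng.normal(0, 0.05, n)
        model = fit(pd.DataFrame({"x": x}), y, FitConfig())
        grid = {"x": np.array([-4.0, -3.0, 3.0, 4.0])}
        pred = model.predict(grid)
        assert (pred[1] - pred[0]) == pytest.approx(2.0, abs=0.05)
        assert (pred[3] - pred[2]) == pytest.approx(2.0, abs=0.05)

    def test_covariate_shift_shifts_knots_not_predictions(self, hinge_data):
        X, y = hinge_data
        cfg = FitConfig()
        m0 = fit(X, y, cfg)
        shift = 100.0
        X2 = X.copy()
        X2["x"] = X2["x"] + shift
        m1 = fit(X2, y, cfg)
        knots0 = sorted(f.knot for t in m0.terms for f in t.factors if f.variable == "x")
        knots1 = sorted(f.knot for t in m1.terms for f in t.factors if f.variable == "x")
        np.testing.assert_allclose(np.array(knots1) - shift, knots0, atol=1e-8)
        np.testing.assert_allclose(m1.predict(X2), m0.predict(X), atol=1e-8)

    def test_single_knot_recovery_median_over_seeds(self):
        # noise sd = 2% of the response range; the extracted threshold
        # (dominant slope-increase knot) recovers the generating knot in
        # the median over seeds
        found = []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            n = 400
            x = rng.uniform(0.0, 10.0, n)
            y = 1.5 * np.maximum(x - 6.2, 0.0) + rng.normal(0, 0.1, n)
            model = fit(pd.DataFrame({"x": x}), y, FitConfig())
            thr = ht.extract_thresholds(model).as_dict()
            found.append(thr.get("x", np.nan))
        assert abs(np.nanmedian(found) - 6.2) < 0.1


class TestImportance:
    def test_single_variable_ranks_first(self, hinge_data):
        X, y = hinge_data
        model = fit(X, y, FitConfig())
        assert model.importance[0][0] == "x"

    def test_intercept_only_empty_ranking(self):
        X = pd.DataFrame({"x": np.arange(30.0)})
        model = fit(X, np.full(30, 2.0), FitConfig())
        assert model.importance == []

    def test_steeper_variable_ranks_first(self):
        rng = np.random.default_rng(5)
        n = 400
        X = pd.DataFrame({"big": rng.uniform(0, 10, n), "small": rng.uniform(0, 10, n)})
        y = (
            1.0 * np.maximum(X["big"] - 5.0, 0.0)
            + 0.01 * np.maximum(X["small"] - 5.0, 0.0)
            + rng.normal(0, 0.05, n)
        )
        model = fit(X, y.to_numpy(), FitConfig())
        assert model.importance[0][0] == "big"


class TestSerialization:
    def test_round_trip_predictions(self, hinge_data):
        X, y = hinge_data
        model = fit(X, y, FitConfig())
        doc = serialize_model(model)
        again = load_model(json.dumps(doc))
        np.testing.assert_allclose(again.predict(X), model.predict(X), atol=0)

    def test_published_fixture_values_survive_load(self, additive_model):
        assert additive_model.intercept == 0.08
        knots = {(f.variable, f.knot) for t in additive_model.terms for f in t.factors}
        assert knots == {("AvgTmaxLag1", 32.95), ("Nindex1", 79.65)}

    def test_bad_direction_token_rejected_with_location(self):
        doc = {
            "intercept": 0.0,
            "terms": [
                {"coef": 1.0, "factors": [{"variable": "x", "knot": 1.0, "direction": "up"}]}
            ],
        }
        with pytest.raises(ValueError, match="term 0, factor 0"):
            load_model(doc)

    def test_save_load_file(self, tmp_path, additive_model):
        p = tmp_path / "m.json"
        ht.save_model(additive_model, p)
        m = ht.load_model(str(p))
        assert m.predict({"AvgTmaxLag1": 32.95, "Nindex1": 79.65}) == 0.08


class TestModelSurface:
    def test_from_dataframe_and_summary(self, hinge_data):
        X, y = hinge_data
        data = X.copy()
        data["y"] = y
        res = ht.MarsRegression.from_dataframe(data, "y").fit()
        text = res.summary()
        assert "GCV" in text and "(Intercept)" in text and "max(x" in text
        assert res.rsquared > 0.99

    def test_missing_rows_dropped_with_count(self, hinge_data):
        X, y = hinge_data
        X = X.copy()
        X.iloc[0, 0] = np.nan
        reg = ht.MarsRegression(y, X)
        assert reg.n_dropped == 1
        assert len(reg.endog) == len(y) - 1

    @given(x=st.floats(25.0, 40.0), ni=st.floats(60.0, 85.0))
    def test_prediction_matches_term_sum(self, additive_model, x, ni):
        data = {"AvgTmaxLag1": x, "Nindex1": ni}
        expected = additive_model.intercept + sum(
            t.coefficient * float(t.design_column(data))
            for t in additive_model.terms
        )
        assert additive_model.predict(data) == pytest.approx(expected, abs=1e-12)
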