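"""Feature-selection cascade: stage behavior, routing, recovery, null control."""

import numpy as np
import pandas as pd
import pytest

from phyllotex.selection import (
    CascadeConfig,
    multivariate_backward,
    run_cascade,
    standardize,
    univariate_logistic_screen,
    univariate_screen,
    variance_filter,
)


def make_table(rng, n=40, n_features=6, effects=None):
    """Two balanced classes; ``effects[name]`` shifts class 1 by that many sd."""
    y = np.repeat([0, 1], n // 2)
    data = {}
    effects = effects or {}
    for i in range(n_features):
        name = f"f{i}"
        x = rng.normal(size=n)
        x[y == 1] += effects.get(name, 0.0)
        data[name] = x
    return pd.DataFrame(data), y


class TestStandardize:
    def test_closed_form_z_scores(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, params = standardize(t)
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])
        assert params["a"] == (2.0, 1.0)

    def test_constant_column_flagged_and_unchanged(self):
        t = pd.DataFrame({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 4.0]})
        out, params = standardize(t)
        np.testing.assert_array_equal(out["a"], t["a"])
        assert params["a"][1] == 0.0

    def test_moments_after_standardization(self, rng):
        t = pd.DataFrame(rng.normal(5, 3, size=(50, 4)), columns=list("abcd"))
        out, _ = standardize(t)
        np.testing.assert_allclose(out.mean().to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=1).to_numpy(), 1.0, atol=1e-12)


class TestVarianceFilter:
    def test_zero_variance_removed(self):
        t = pd.DataFrame({"const": np.ones(10), "var": np.arange(10.0)})
        out, record = variance_filter(t)
        assert "const" not in out.columns and "var" in out.columns
        assert record.details["const"]["reason"] is not None

    def test_strict_boundary_at_threshold(self):
        # columns constructed to have sample variance exactly 0.79 and 0.81
        def col(var, n=10):
            x = np.zeros(n)
            x[0] = np.sqrt(var * (n - 1) / (1 - 1 / n) / n) * np.sqrt(n / (n - 1))
            x = np.array([0.0, 1.0] * (n // 2))
            return x / x.std(ddof=1) * np.sqrt(var)

        t = pd.DataFrame({"low": col(0.79), "high": col(0.81)})
        assert t["low"].var(ddof=1) == pytest.approx(0.79)
        out, _ = variance_filter(t, threshold=0.8)
        assert list(out.columns) == ["high"]

    def test_threshold_zero_keeps_everything(self, rng):
        t = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        out, _ = variance_filter(t, threshold=0.0)
        assert list(out.columns) == list(t.columns)


class TestUnivariateScreen:
    def test_identical_groups_dropped(self, rng):
        x = np.tile(rng.normal(size=10), 2)
        t = pd.DataFrame({"f": x})
        y = np.repeat([0, 1], 10)
        kept, record = univariate_screen(t, y)
        assert kept == []
        assert record.details["f"]["p"] > 0.5

    def test_strong_shift_detected(self, rng):
        t, y = make_table(rng, n=40, effects={"f0": 5.0})
        kept, record = univariate_screen(t, y)
        assert "f0" in kept
        assert record.details["f0"]["p"] < 0.05

    def test_skewed_feature_routes_to_mann_whitney(self, rng):
        x = np.concatenate([rng.lognormal(0, 1.5, 20), rng.lognormal(1.5, 1.5, 20)])
        t = pd.DataFrame({"f": x})
        y = np.repeat([0, 1], 20)
        _, record = univariate_screen(t, y)
        assert record.details["f"]["test"] == "mann-whitney"

    def test_normal_homogeneous_feature_routes_to_t_test(self, rng):
        t, y = make_table(rng, n=60, effects={"f0": 1.0})
        _, record = univariate_screen(t, y)
        assert record.details["f0"]["test"] == "t-test"

    def test_all_tied_feature_dropped_with_reason(self, rng):
        t = pd.DataFrame({"f": np.ones(20)})
        y = np.repeat([0, 1], 10)
        kept, record = univariate_screen(t, y)
        assert kept == [] and record.details["f"]["reason"] == "all values tied"

    def test_type_one_error_control_on_null(self):
        """Per-feature rejection rate ~5% when both classes share one
        distribution (1000 null features)."""
        rng = np.random.default_rng(7)
        t = pd.DataFrame(
            rng.normal(size=(40, 1000)), columns=[f"f{i}" for i in range(1000)]
        )
        y = np.repeat([0, 1], 20)
        kept, _ = univariate_screen(t, y)
        rate = len(kept) / 1000
        assert 0.02 <= rate <= 0.09


class TestUnivariateLogistic:
    def test_pure_noise_dropped(self, rng):
        t, y = make_table(rng, n=60)
        kept, record = univariate_logistic_screen(t, y)
        assert len(kept) <= 1  # chance survivors only

    def test_perfect_separation_flagged_and_retained(self):
        y = np.repeat([0, 1], 10)
        t = pd.DataFrame({"f": y.astype(float)})
        kept, record = univariate_logistic_screen(t, y)
        assert kept == ["f"]
        assert record.details["f"]["separated"] is True

    def test_wald_p_consistent_with_likelihood_ratio(self, rng):
        t, y = make_table(rng, n=120, effects={"f0": 0.8})
        _, record = univariate_logistic_screen(t, y)
        wald_p = record.details["f0"]["p"]
        # independent LR p for the same single-predictor model
        import statsmodels.api as sm
        from scipy import stats as ss

        x = t["f0"].to_numpy()
        full = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        lr_p = ss.chi2.sf(2 * (full.llf - null.llf), 1)
        assert wald_p == pytest.approx(lr_p, abs=0.05)
        assert np.log10(max(wald_p, 1e-12)) == pytest.approx(
            np.log10(max(lr_p, 1e-12)), abs=1.0
        )


class TestBackwardStepwise:
    def test_single_candidate_returned_as_is(self, rng):
        t, y = make_table(rng, n=60, n_features=1, effects={"f0": 2.0})
        model, record = multivariate_backward(t, y)
        assert model.feature_names == ["f0"]

    def test_selection_consistency_with_noise_predictors(self):
        """Two strong true predictors survive and most noise predictors are
        removed, across seeds."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 200
            X = pd.DataFrame(
                rng.normal(size=(n, 5)), columns=["t1", "t2", "n1", "n2", "n3"]
            )
            eta = 2.0 * X["t1"] - 2.0 * X["t2"]
            y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
            model, _ = multivariate_backward(X, y)
            kept = set(model.feature_names)
            noise_removed = len({"n1", "n2", "n3"} - kept)
            if {"t1", "t2"} <= kept and noise_removed >= 2:
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_removal_order_and_trace_replay(self, rng):
        t, y = make_table(rng, n=80, n_features=5, effects={"f0": 2.0})
        model, record = multivariate_backward(t, y)
        removals = [
            s for s in record.details["steps"]["list"] if s["action"] == "remove"
        ]
        # replaying the recorded removals from the full set gives the final set
        remaining = list(t.columns)
        for s in removals:
            remaining.remove(s["feature"])
        assert set(remaining) == set(model.feature_names)
        for s in removals:
            assert s["removal_p"] > 0.10

    def test_empty_final_model_is_intercept_only(self, rng):
        t, y = make_table(rng, n=40, n_features=3)  # pure noise
        model, _ = multivariate_backward(t, y, p_remove=0.0001)
        assert model.coefficients == {}
        assert model.n == 40


class TestCascade:
    def test_kept_sets_are_nested_and_signal_recovered(self, rng):
        t, y = make_table(rng, n=50, n_features=8, effects={"f0": 3.0, "f1": 2.5})
        t = t * 4.0  # keep raw variances above the 0.8 threshold
        model, trace = run_cascade(t, y)
        stages = [set(rec.kept) for rec in trace.stages]
        for earlier, later in zip(stages, stages[1:]):
            assert later <= earlier
        assert set(model.feature_names) & {"f0", "f1"}

    def test_cascade_is_deterministic(self, rng):
        t, y = make_table(rng, n=50, n_features=6, effects={"f0": 2.0})
        t = t * 3.0
        m1, tr1 = run_cascade(t, y)
        m2, tr2 = run_cascade(t, y)
        assert m1.coefficients == m2.coefficients
        assert tr1.to_json() == tr2.to_json()

    def test_variance_stage_respects_configured_threshold(self, rng):
        t, y = make_table(rng, n=50, n_features=6)
        cfg = CascadeConfig(variance_threshold=0.0)
        _, trace = run_cascade(t, y, cfg)
        assert set(trace.kept_at("variance")) == set(t.columns)

    def test_null_cohort_yields_tiny_or_empty_model(self):
        """With permuted labels the final model keeps at most one feature in
        most replicates."""
        small = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            t, y = make_table(rng, n=40, n_features=15)
            t = t * 3.0
            y = rng.permutation(y)
            model, _ = run_cascade(t, y)
            if len(model.feature_names) <= 1:
                small += 1
        assert small / reps >= 0.8
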