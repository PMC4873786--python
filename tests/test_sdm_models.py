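import numpy as np
import pandas as pd
import pytest

from enmrisk.errors import DomainError, SchemaError
from enmrisk.evaluation import SplitPlan, cross_validate, roc_auc
from enmrisk.grids import RasterGrid
from enmrisk.predictors import PredictorStack
from enmrisk.sdm_models import (
    METHODS,
    ModelSpec,
    fit,
    fit_sre,
    predict_raster,
    predict_sre,
)

FAST_METHODS = ("CTA", "FDA", "GAM", "GBM", "GLM", "MARS", "SRE")


def make_table(n=200, p=3, seed=0, signal=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if signal:
        eta = 2.0 * X[:, 0] - 1.5 * X[:, 1] ** 2 + 0.5
        prob = 1 / (1 + np.exp(-eta))
    else:
        prob = np.full(n, 0.5)
    y = rng.binomial(1, prob)
    if y.sum() in (0, n):  # guard: force both classes
        y[0], y[1] = 0, 1
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    df["label"] = y
    df["weight"] = 1.0
    return df


class TestFitPredictContract:
    def test_glm_separable_data_reaches_auc_one(self):
        x = np.r_[np.linspace(-2, -1, 50), np.linspace(1, 2, 50)]
        df = pd.DataFrame({"x0": x, "label": (x > 0).astype(int), "weight": 1.0})
        m = fit(ModelSpec("GLM"), df)
        p = m.predict(df)
        assert roc_auc(p, df["label"]) == 1.0

    def test_rf_seed_reproducibility(self):
        df = make_table(seed=1)
        p1 = fit(ModelSpec("RF", seed=7), df).predict(df)
        p2 = fit(ModelSpec("RF", seed=7), df).predict(df)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("method", ("GLM", "CTA", "GAM"))
    def test_null_data_cv_auc_near_half(self, method):
        df = make_table(n=500, seed=2, signal=False)
        aucs, _, mean_auc = cross_validate(ModelSpec(method, seed=0), df, SplitPlan(0.7, 5, seed=3))
        assert mean_auc == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("method", FAST_METHODS)
    def test_outputs_in_unit_interval(self, method):
        df = make_table(n=150, seed=4)
        m = fit(ModelSpec(method, seed=0), df)
        p = m.predict(df)
        assert len(p) == len(df)
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(np.isfinite(p))

    def test_column_order_irrelevant(self):
        df = make_table(seed=5)
        m = fit(ModelSpec("GLM"), df)
        shuffled = df[["x2", "x0", "x1", "label", "weight"]]
        np.testing.assert_allclose(m.predict(df), m.predict(shuffled))

    def test_missing_column_raises_schema_error(self):
        df = make_table(seed=6)
        m = fit(ModelSpec("GLM"), df)
        with pytest.raises(SchemaError, match="x2"):
            m.predict(df.drop(columns=["x2"]))

    def test_mean_row_prediction_in_range(self):
        df = make_table(seed=7)
        m = fit(ModelSpec("GBM", seed=0), df)
        mean_row = df[["x0", "x1", "x2"]].mean().to_frame().T
        p = m.predict(mean_row)
        assert 0 <= p[0] <= 1

    def test_single_class_table_raises(self):
        df = make_table(seed=8)
        df["label"] = 1
        with pytest.raises(DomainError):
            fit(ModelSpec("GLM"), df)

    def test_case_weights_change_the_fit(self):
        df = make_table(n=300, seed=9)
        base = fit(ModelSpec("GLM"), df).predict(df)
        rew = df.copy()
        rew.loc[rew.label == 0, "weight"] = 25.0
        skew = fit(ModelSpec("GLM"), rew).predict(rew)
        assert np.mean(skew) < np.mean(base)

    def test_glm_recovers_signal_over_permuted_labels(self):
        df = make_table(n=500, seed=10)
        plan = SplitPlan(0.7, 5, seed=11)
        _, _, auc_true = cross_validate(ModelSpec("GLM"), df, plan)
        permuted = df.copy()
        permuted["label"] = np.random.default_rng(12).permutation(df["label"].to_numpy())
        _, _, auc_null = cross_validate(ModelSpec("GLM"), permuted, plan)
        assert auc_true - auc_null >= 0.3


class TestSurfaceRangeEnvelope:
    def test_zero_quantile_gives_min_max_bounds(self):
        X = np.array([[1.0, 10.0], [5.0, 20.0], [3.0, 30.0]])
        env = fit_sre(X, quantile=0.0)
        np.testing.assert_allclose(env.lower, [1.0, 10.0])
        np.testing.assert_allclose(env.upper, [5.0, 30.0])

    def test_linear_interpolation_quantiles(self):
        X = np.arange(1.0, 101.0).reshape(-1, 1)
        env = fit_sre(X, quantile=0.025)
        assert env.lower[0] == pytest.approx(np.quantile(X[:, 0], 0.025))
        assert env.lower[0] == pytest.approx(3.475)
        assert env.upper[0] == pytest.approx(97.525)

    def test_constant_variable_degenerate_bounds(self):
        X = np.column_stack([np.full(10, 4.2), np.arange(10.0)])
        env = fit_sre(X, quantile=0.1)
        assert env.lower[0] == env.upper[0] == 4.2

    def test_quantile_half_or_more_raises(self):
        with pytest.raises(DomainError):
            fit_sre(np.zeros((5, 2)), quantile=0.5)

    def test_median_row_inside_envelope(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(100, 3))
        env = fit_sre(X, quantile=0.025)
        assert predict_sre(env, np.median(X, axis=0)[None, :])[0] == 1.0

    def test_epsilon_above_upper_bound_is_outside(self):
        X = np.arange(1.0, 101.0).reshape(-1, 1)
        env = fit_sre(X, quantile=0.0)
        assert predict_sre(env, np.array([[100.0 + 1e-9]]))[0] == 0.0
        assert predict_sre(env, np.array([[100.0]]))[0] == 1.0

    def test_zero_quantile_envelope_contains_training_data(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(50, 4))
        env = fit_sre(X, quantile=0.0)
        assert predict_sre(env, X).min() == 1.0

    def test_envelope_monotone_in_quantile(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(200, 3))
        grid = rng.normal(size=(500, 3))
        inside_0 = predict_sre(fit_sre(X, 0.0), grid)
        inside_q = predict_sre(fit_sre(X, 0.025), grid)
        assert np.all(inside_0 >= inside_q)


class TestRasterPrediction:
    def _stack(self, values_by_name, spec):
        return PredictorStack({n: RasterGrid(spec, v) for n, v in values_by_name.items()})

    def test_constant_stack_constant_prediction(self, small_grid):
        df = make_table(seed=16, p=2).rename(columns={"x0": "a", "x1": "b"})
        m = fit(ModelSpec("GLM"), df)
        stack = self._stack({"a": np.full((3, 3), 0.3), "b": np.full((3, 3), -0.2)}, small_grid)
        out = predict_raster(m, stack)
        assert np.ptp(out.values[out.mask]) == pytest.approx(0.0, abs=1e-12)

    def test_raster_matches_tabular_predictions(self, ref_stack, ref_table):
        vars_ = ref_stack.names[:4]
        m = fit(ModelSpec("GLM"), ref_table[vars_ + ["label", "weight"]])
        grid_pred = predict_raster(m, ref_stack)
        spec = ref_stack.spec
        rows, cols = spec.cell_of(ref_table["lon"], ref_table["lat"])
        np.testing.assert_allclose(grid_pred.values[rows, cols], m.predict(ref_table), atol=1e-12)

    def test_masked_cell_propagates(self, small_grid):
        df = make_table(seed=17, p=2)[["x0", "label", "weight"]].rename(columns={"x0": "a"})
        m = fit(ModelSpec("GLM"), df)
        mask = np.ones((3, 3), dtype=bool)
        mask[2, 2] = False
        stack = PredictorStack({"a": RasterGrid(small_grid, np.zeros((3, 3)), mask)})
        out = predict_raster(m, stack)
        assert not out.mask[2, 2]

    def test_missing_layer_raises(self, small_grid):
        df = make_table(seed=18, p=2)
        m = fit(ModelSpec("GLM"), df)
        stack = self._stack({"x0": np.zeros((3, 3))}, small_grid)
        with pytest.raises(SchemaError):
            predict_raster(m, stack)


def test_unknown_method_rejected():
    with pytest.raises(DomainError):
        ModelSpec("SVM")
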