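import numpy as np
import pandas as pd
import pytest

from enmrisk.errors import ConfigError, DegenerateInputError, DomainError, SchemaError
from enmrisk.evaluation import (
    SplitPlan,
    build_ensemble,
    cross_validate,
    ensemble_cv_records,
    ensemble_importance,
    ensemble_predict,
    ensemble_weights,
    importance_to_percent,
    randomization_importance,
    roc_auc,
    run_design,
    select_members,
    welch_t,
)
from enmrisk.sdm_models import ModelSpec, fit


def brute_force_auc(scores, labels, weights=None):
    """Independent all-pairs oracle: weighted concordance with 0.5 for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    w = np.ones(len(scores)) if weights is None else np.asarray(weights, dtype=float)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    num = den = 0.0
    for i in pos:
        for j in neg:
            pair_w = w[i] * w[j]
            den += pair_w
            if scores[i] > scores[j]:
                num += pair_w
            elif scores[i] == scores[j]:
                num += 0.5 * pair_w
    return num / den


def separable_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x = np.r_[rng.uniform(-2, -0.5, n // 2), rng.uniform(0.5, 2, n // 2)]
    return pd.DataFrame({"x0": x, "label": (x > 0).astype(int), "weight": 1.0})


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant_pairs(self):
        assert roc_auc([0.9, 0.4, 0.3, 0.8], [1, 1, 0, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_one_class_raises(self):
        with pytest.raises(DomainError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(30):
            n = rng.integers(5, 200)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            weights = rng.uniform(0.2, 3.0, size=n) if trial % 2 else None
            assert roc_auc(scores, labels, weights) == pytest.approx(
                brute_force_auc(scores, labels, weights), rel=1e-10
            )

    def test_complement_identity_for_tie_free_scores(self):
        rng = np.random.default_rng(2)
        scores = rng.permutation(np.linspace(0, 1, 60))
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 3, 4, 5])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / len(a) + vb / len(b)
        t_exp = (a.mean() - b.mean()) / np.sqrt(se2)
        df_exp = se2**2 / ((va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
        t, df, p = welch_t(a, b)
        assert t == pytest.approx(t_exp)
        assert df == pytest.approx(df_exp)

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        ta, _, pa = welch_t(a, b)
        tb, _, pb = welch_t(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            welch_t([1.0, 1.0, 1.0], [2.0, 2.0])


class TestCrossValidate:
    def test_single_repeat_separable(self):
        aucs, final, mean_auc = cross_validate(
            ModelSpec("GLM"), separable_table(), SplitPlan(0.7, 1, seed=1)
        )
        assert aucs == [1.0]
        assert final.score == 1.0

    def test_seed_determinism(self):
        table = separable_table(seed=4)
        r1 = cross_validate(ModelSpec("GLM"), table, SplitPlan(0.7, 4, seed=5))[0]
        r2 = cross_validate(ModelSpec("GLM"), table, SplitPlan(0.7, 4, seed=5))[0]
        assert r1 == r2

    def test_final_model_trained_on_all_rows(self):
        table = separable_table(seed=6)
        _, final, _ = cross_validate(ModelSpec("GLM"), table, SplitPlan(0.7, 2, seed=7))
        assert roc_auc(final.predict(table), table["label"]) == 1.0


@pytest.fixture(scope="module")
def mini_design(ref_presences, ref_absences, ref_stack):
    specs = [ModelSpec("GLM"), ModelSpec("SRE")]
    stack = ref_stack.subset(ref_stack.names[:5])
    plan = SplitPlan(0.7, 2, seed=21)
    return run_design(specs, ref_absences, ref_presences, stack, plan)


class TestRunDesign:
    def test_record_count_is_full_factorial(self, mini_design):
        records, *_ = mini_design
        assert len(records) == 2 * 2 * 2
        assert (records.groupby("method").size() == 4).all()

    def test_empty_method_list_gives_empty_records(self, ref_presences, ref_absences, ref_stack):
        records, *_ = run_design([], ref_absences, ref_presences, ref_stack, SplitPlan(0.7, 1, 0))
        assert len(records) == 0

    def test_ensemble_cv_within_member_envelope(self, mini_design):
        records, final_models, tables, cv_preds = mini_design
        retained, _ = select_members(records, auc_floor=0.0)
        ens = build_ensemble(records, final_models, retained)
        em = ensemble_cv_records(ens, tables, cv_preds)
        assert len(em) == 2 * 2
        assert em["auc"].between(0, 1).all()


class TestMemberSelection:
    def records(self, means):
        return pd.DataFrame(
            [{"method": m, "absence_dataset_id": 1, "repeat_id": 1, "auc": a} for m, a in means.items()]
        )

    def test_threshold_rule(self):
        retained, log = select_members(self.records({"A": 0.9, "B": 0.88, "C": 0.6}), auc_floor=0.8)
        assert retained == ["A", "B"]
        assert "dropped" in log.loc[log.method == "C", "decision"].iloc[0]

    def test_all_above_floor_all_retained(self):
        retained, _ = select_members(self.records({"A": 0.9, "B": 0.85}), auc_floor=0.8)
        assert retained == ["A", "B"]

    def test_explicit_drop_list_overrides(self):
        retained, log = select_members(self.records({"A": 0.95, "SRE": 0.99}), drop=["SRE"])
        assert retained == ["A"]
        assert "explicit" in log.loc[log.method == "SRE", "decision"].iloc[0]

    def test_dropping_everything_is_config_error(self):
        with pytest.raises(ConfigError):
            select_members(self.records({"A": 0.5}), auc_floor=0.9)


class TestEnsembleWeights:
    def test_equal_aucs_equal_weights(self):
        w = ensemble_weights({"A": 0.9, "B": 0.9, "C": 0.9})
        assert all(x == pytest.approx(1 / 3) for x in w.values())

    def test_proportional_to_auc(self):
        w = ensemble_weights({"A": 0.9, "B": 0.6})
        assert w["A"] == pytest.approx(0.6)
        assert w["B"] == pytest.approx(0.4)

    def test_single_member_weight_one(self):
        assert ensemble_weights({"A": 0.7}) == {"A": 1.0}

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            ensemble_weights({})


class TestEnsemblePredict:
    def _toy_ensemble(self, tables=1):
        table = separable_table(seed=8)
        mA = fit(ModelSpec("GLM"), table)
        mB = fit(ModelSpec("CTA"), table)
        from enmrisk.evaluation import EnsembleModel

        return (
            EnsembleModel(
                members={"GLM": [mA], "CTA": [mB]},
                weights={"GLM": 0.25, "CTA": 0.75},
                member_mean_auc={"GLM": 0.9, "CTA": 0.9},
            ),
            table,
        )

    def test_weighted_mean_of_members(self, small_grid):
        ens, table = self._toy_ensemble()
        pa = ens.members["GLM"][0].predict(table)
        pb = ens.members["CTA"][0].predict(table)
        out = ensemble_predict(ens, table)
        np.testing.assert_allclose(out, 0.25 * pa + 0.75 * pb)

    def test_within_member_envelope(self):
        ens, table = self._toy_ensemble()
        pa = ens.members["GLM"][0].predict(table)
        pb = ens.members["CTA"][0].predict(table)
        out = ensemble_predict(ens, table)
        assert np.all(out >= np.minimum(pa, pb) - 1e-12)
        assert np.all(out <= np.maximum(pa, pb) + 1e-12)

    def test_single_member_identity(self):
        from enmrisk.evaluation import EnsembleModel

        table = separable_table(seed=9)
        m = fit(ModelSpec("GLM"), table)
        ens = EnsembleModel(members={"GLM": [m]}, weights={"GLM": 1.0}, member_mean_auc={"GLM": 1.0})
        np.testing.assert_allclose(ensemble_predict(ens, table), m.predict(table))


class _IdentityModel:
    """Stub model: prediction equals one feature column."""

    variables = ["x"]

    def predict(self, table):
        return table["x"].to_numpy(dtype=float)


class TestRandomizationImportance:
    def test_ignored_variable_scores_zero(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame({"x0": rng.normal(size=100), "x1": rng.normal(size=100)})
        table["label"] = (table["x0"] > 0).astype(int)
        table["weight"] = 1.0
        m = fit(ModelSpec("CTA", seed=0), table[["x0", "label", "weight"]].assign(x1=0.0)[["x0", "x1", "label", "weight"]])
        # x1 is constant in training: the tree cannot split on it
        assert randomization_importance(m, table, "x1", n_shuffles=2, seed=1) == pytest.approx(0.0, abs=1e-12)

    def test_identity_model_matches_hand_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        table = pd.DataFrame({"x": x})
        seed = 5
        got = randomization_importance(_IdentityModel(), table, "x", n_shuffles=1, seed=seed)
        oracle_rng = np.random.default_rng(np.random.SeedSequence(seed))
        perm = oracle_rng.permutation(x)
        expected = 1.0 - np.corrcoef(x, perm)[0, 1]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_seed_determinism(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame({"x": rng.normal(size=50)})
        a = randomization_importance(_IdentityModel(), table, "x", n_shuffles=1, seed=3)
        b = randomization_importance(_IdentityModel(), table, "x", n_shuffles=1, seed=3)
        assert a == b

    def test_constant_predictions_raise(self):
        table = pd.DataFrame({"x": np.zeros(10)})
        with pytest.raises(DegenerateInputError):
            randomization_importance(_IdentityModel(), table, "x", seed=0)


class TestImportanceAggregation:
    def test_percent_conversion(self):
        assert importance_to_percent({"a": 0.2, "b": 0.2, "c": 0.6}) == pytest.approx(
            {"a": 20.0, "b": 20.0, "c": 60.0}
        )

    def test_single_variable_is_hundred(self):
        assert importance_to_percent({"a": 0.42}) == {"a": 100.0}

    def test_proportional_scores(self):
        pct = importance_to_percent({f"v{i}": i for i in range(1, 5)})
        assert [pct[f"v{i}"] for i in range(1, 5)] == pytest.approx([10, 20, 30, 40])

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateInputError):
            importance_to_percent({"a": 0.0, "b": 0.0})

    def test_identical_member_vectors_preserved(self):
        scores = {"m1": {"a": 0.3, "b": 0.7}, "m2": {"a": 0.3, "b": 0.7}}
        _, pct = ensemble_importance({"m1": 0.6, "m2": 0.4}, scores)
        assert pct == pytest.approx({"a": 30.0, "b": 70.0})

    def test_single_member_proportionality(self):
        _, pct = ensemble_importance({"m1": 1.0}, {"m1": {"a": 1.0, "b": 3.0}})
        assert pct == pytest.approx({"a": 25.0, "b": 75.0})

    def test_disjoint_signal_splits_evenly(self):
        scores = {"m1": {"a": 1.0, "b": 0.0}, "m2": {"a": 0.0, "b": 1.0}}
        _, pct = ensemble_importance({"m1": 0.5, "m2": 0.5}, scores)
        assert pct == pytest.approx({"a": 50.0, "b": 50.0})

    def test_misaligned_members_raise(self):
        with pytest.raises(SchemaError):
            ensemble_importance({"m1": 1.0}, {"m1": {"a": 1.0}, "m2": {"a": 1.0}})
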