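"""Cross-validation, AUC-weighted ensemble construction, and variable importance.

The evaluation design mirrors classic ensemble niche modelling: every
(method x absence-dataset) pair is scored by repeated random 70/30
train/test splits using the ROC AUC (weighted Mann-Whitney formulation,
honouring the equal-prevalence case weights), the per-method mean AUC over
all datasets and repeats drives both member selection and the ensemble
weights ``w_i = AUC_i / sum_j AUC_j``, and the ensemble prediction (EMmw)
is the weighted mean of member predictions.

Variable importance is the randomization (permutation) measure: shuffle one
predictor column, re-predict, and score ``1 - r`` where ``r`` is the Pearson
correlation between original and shuffled-input predictions.  Method-level
scores are combined into the ensemble importance by applying the ensemble
weights, summing per variable, dividing by the number of members, and
converting to percentages of the per-method total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import ConfigError, DegenerateInputError, DomainError, SchemaError
from .grids import RasterGrid
from .occurrences import AbsenceDataset, PresenceCellSet, assemble_response
from .predictors import PredictorStack, extract_values
from .sdm_models import FittedModel, ModelSpec, fit, predict_raster
from .seeds import derive_seed as _derive_seed

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "EnsembleModel",
    "roc_auc",
    "cross_validate",
    "run_design",
    "select_members",
    "ensemble_weights",
    "ensemble_predict",
    "ensemble_cv_records",
    "welch_t",
    "randomization_importance",
    "importance_to_percent",
    "ensemble_importance",
    "importance_table",
]


@dataclass(frozen=True)
class SplitPlan:
    """Repeated random train/test split schedule."""

    train_fraction: float = 0.70
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise DomainError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.n_repeats < 1:
            raise DomainError("n_repeats must be >= 1")


@dataclass
class EnsembleModel:
    """Retained members (per method, one final model per absence dataset) + weights."""

    members: dict  # method -> list[FittedModel]
    weights: dict  # method -> float, sums to 1
    member_mean_auc: dict  # method -> float

    def __post_init__(self) -> None:
        if set(self.members) != set(self.weights):
            raise SchemaError("members and weights name different methods")
        total = sum(self.weights.values())
        if self.members and abs(total - 1.0) > 1e-9:
            raise DomainError(f"weights must sum to 1, got {total}")


def roc_auc(scores, labels, weights=None) -> float:
    """ROC AUC: probability a random positive outscores a random negative.

    Ties count 0.5; with case weights each (positive, negative) pair
    contributes ``w+ * w-``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DomainError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float), sample_weight=weights))


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("Welch's t needs at least 2 values per sample")
    if np.allclose(a, a.mean()) and np.allclose(b, b.mean()):
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise DegenerateInputError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _split_indices(rng: np.random.Generator, labels: np.ndarray, train_fraction: float, max_retries: int = 100):
    """Random train/test split; re-drawn (with warning) if a part is one-class."""
    n = len(labels)
    n_train = max(1, min(n - 1, int(round(train_fraction * n))))
    for attempt in range(max_retries):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if len(np.unique(labels[train])) == 2 and len(np.unique(labels[test])) == 2:
            if attempt:
                logger.warning("re-drew split %d time(s) to get both classes in both parts", attempt)
            return train, test
    raise DomainError(f"could not obtain a two-class 70/30 split in {max_retries} tries")


def cross_validate(
    spec: ModelSpec, table: pd.DataFrame, plan: SplitPlan, *, keep_predictions: bool = False
):
    """Repeated 70/30 evaluation plus a final fit on all rows.

    Returns ``(auc_list, final_model, mean_auc)`` — the final model carries
    ``mean_auc`` as its ``score``.  With ``keep_predictions`` the held-out
    indices and predictions of every repeat are returned too (used to score
    the ensemble under the identical splits).
    """
    labels = table["label"].to_numpy(dtype=int)
    weights = table["weight"].to_numpy(dtype=float)
    aucs: list[float] = []
    preds_out: list[tuple[np.ndarray, np.ndarray]] = []
    root = np.random.SeedSequence(plan.seed)
    children = root.spawn(plan.n_repeats)
    for r in range(plan.n_repeats):
        rng = np.random.default_rng(children[r])
        train_idx, test_idx = _split_indices(rng, labels, plan.train_fraction)
        model = fit(spec, table.iloc[train_idx])
        scores = model.predict(table.iloc[test_idx])
        aucs.append(roc_auc(scores, labels[test_idx], weights[test_idx]))
        if keep_predictions:
            preds_out.append((test_idx, scores))
    final = fit(spec, table)
    final.score = float(np.mean(aucs))
    if keep_predictions:
        return aucs, final, final.score, preds_out
    return aucs, final, final.score


def run_design(
    method_specs: list[ModelSpec],
    absence_datasets: list[AbsenceDataset],
    presences: PresenceCellSet,
    stack: PredictorStack,
    plan: SplitPlan,
):
    """Full factorial evaluation: every method on every absence dataset.

    Splits are shared across methods within an absence dataset (fair
    comparison); model seeds and split seeds derive deterministically from
    ``plan.seed``.  Returns ``(records, final_models, tables, cv_predictions)``:

    - records: DataFrame (method, absence_dataset_id, repeat_id, auc) with
      n_methods x n_datasets x n_repeats rows;
    - final_models: method -> list of all-data FittedModel, one per dataset;
    - tables: absence_dataset_id -> feature table;
    - cv_predictions: (method, dataset_id) -> list of (test_idx, scores).
    """
    records: list[dict] = []
    final_models: dict[str, list[FittedModel]] = {s.method: [] for s in method_specs}
    tables: dict[int, pd.DataFrame] = {}
    cv_predictions: dict[tuple[str, int], list] = {}
    for ds in absence_datasets:
        response = assemble_response(presences, ds)
        table = extract_values(stack, response)
        tables[ds.dataset_id] = table
        split_seed = _derive_seed(plan.seed, "split", ds.dataset_id)
        ds_plan = SplitPlan(plan.train_fraction, plan.n_repeats, split_seed)
        for spec in method_specs:
            model_seed = _derive_seed(plan.seed, spec.method, ds.dataset_id)
            ds_spec = ModelSpec(spec.method, spec.hyperparameters, model_seed)
            aucs, final, mean_auc, preds = cross_validate(
                ds_spec, table, ds_plan, keep_predictions=True
            )
            final_models[spec.method].append(final)
            cv_predictions[(spec.method, ds.dataset_id)] = preds
            for r, auc in enumerate(aucs):
                records.append(
                    {
                        "method": spec.method,
                        "absence_dataset_id": ds.dataset_id,
                        "repeat_id": r + 1,
                        "auc": auc,
                    }
                )
            logger.info(
                "dataset %d method %s: mean AUC %.3f", ds.dataset_id, spec.method, mean_auc
            )
    return pd.DataFrame(records), final_models, tables, cv_predictions


def select_members(
    records: pd.DataFrame, auc_floor: float = 0.8, drop: list[str] | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Retain methods for the ensemble; drop weak or explicitly excluded ones.

    Default rule: drop any method whose mean AUC over all records falls
    below ``auc_floor``.  An explicit ``drop`` list (e.g. the envelope
    method, which scores systematically lower) overrides the threshold.
    Returns (retained method names, per-method decision log).
    """
    if records.empty:
        raise DomainError("no evaluation records")
    means = records.groupby("method", sort=False)["auc"].mean()
    drop = list(drop) if drop else []
    rows = []
    retained = []
    for method, mean_auc in means.items():
        if method in drop:
            decision = "dropped (explicit)"
        elif mean_auc < auc_floor:
            decision = f"dropped (mean AUC {mean_auc:.3f} < floor {auc_floor})"
        else:
            decision = "retained"
            retained.append(method)
        rows.append({"method": method, "mean_auc": mean_auc, "decision": decision})
        logger.info("select_members: %s -> %s", method, decision)
    if not retained:
        raise ConfigError("member selection dropped every method")
    return retained, pd.DataFrame(rows)


def ensemble_weights(member_mean_aucs: dict) -> dict:
    """Proportional AUC weights: ``w_i = auc_i / sum(auc)``; sums to 1."""
    if not member_mean_aucs:
        raise DomainError("empty member set")
    if any(a <= 0 for a in member_mean_aucs.values()):
        raise DomainError("mean AUCs must be positive")
    total = sum(member_mean_aucs.values())
    return {m: a / total for m, a in member_mean_aucs.items()}


def build_ensemble(records: pd.DataFrame, final_models: dict, retained: list[str]) -> EnsembleModel:
    means = records.groupby("method")["auc"].mean()
    member_auc = {m: float(means[m]) for m in retained}
    weights = ensemble_weights(member_auc)
    members = {m: final_models[m] for m in retained}
    return EnsembleModel(members=members, weights=weights, member_mean_auc=member_auc)


def ensemble_predict(ensemble: EnsembleModel, features_or_stack):
    """AUC-weighted mean of member predictions (tabular or raster).

    Each method's models (one per absence dataset) are averaged first, then
    combined across methods with the ensemble weights, so the output always
    lies inside the member prediction envelope.
    """
    if not ensemble.members:
        raise DomainError("ensemble has no members")
    if isinstance(features_or_stack, PredictorStack):
        stack = features_or_stack
        acc = None
        mask = None
        for method, models in ensemble.members.items():
            per = np.mean([predict_raster(m, stack).values for m in models], axis=0)
            g0 = predict_raster(models[0], stack)
            mask = g0.mask if mask is None else (mask & g0.mask)
            acc = ensemble.weights[method] * per if acc is None else acc + ensemble.weights[method] * per
        out = np.where(mask, acc, 0.0)
        return RasterGrid(stack.spec, out, mask)
    features = features_or_stack
    acc = None
    for method, models in ensemble.members.items():
        per = np.mean([m.predict(features) for m in models], axis=0)
        acc = ensemble.weights[method] * per if acc is None else acc + ensemble.weights[method] * per
    return acc


def ensemble_cv_records(
    ensemble: EnsembleModel, tables: dict, cv_predictions: dict
) -> pd.DataFrame:
    """Score the ensemble on the identical held-out splits as its members.

    For each (absence dataset, repeat), member test predictions are combined
    with the ensemble weights and scored; returns records shaped like the
    individual-model ones with method = "EMmw".
    """
    rows = []
    for ds_id, table in tables.items():
        labels = table["label"].to_numpy(dtype=int)
        weights = table["weight"].to_numpy(dtype=float)
        n_rep = len(next(iter(cv_predictions.values())))
        for r in range(n_rep):
            acc = None
            idx_ref = None
            for method in ensemble.members:
                idx, scores = cv_predictions[(method, ds_id)][r]
                if idx_ref is None:
                    idx_ref = idx
                elif not np.array_equal(idx, idx_ref):
                    raise SchemaError("members were evaluated on different splits")
                acc = ensemble.weights[method] * scores if acc is None else acc + ensemble.weights[method] * scores
            rows.append(
                {
                    "method": "EMmw",
                    "absence_dataset_id": ds_id,
                    "repeat_id": r + 1,
                    "auc": roc_auc(acc, labels[idx_ref], weights[idx_ref]),
                }
            )
    return pd.DataFrame(rows)


def randomization_importance(
    model: FittedModel, table: pd.DataFrame, variable: str, n_shuffles: int = 3, seed: int = 0
) -> float:
    """Permutation importance as ``mean over shuffles of (1 - Pearson r)``.

    ``r`` correlates predictions before and after permuting one predictor
    column; a variable the model ignores scores 0, a dominant one scores
    near 1 (bounded by 2 since r >= -1).  If the permuted predictions are
    constant while the originals are not, the correlation carries no signal
    and ``r`` is taken as 0.
    """
    if variable not in model.variables:
        raise SchemaError(f"model does not use variable {variable!r}")
    if len(table) < 3:
        raise DomainError("need at least 3 rows for importance")
    base = model.predict(table)
    if np.std(base) == 0:
        raise DegenerateInputError("original predictions are constant; correlation undefined")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scores = []
    shuffled = table.copy()
    for _ in range(n_shuffles):
        shuffled[variable] = rng.permutation(table[variable].to_numpy())
        pred = model.predict(shuffled)
        r = 0.0 if np.std(pred) == 0 else float(np.corrcoef(base, pred)[0, 1])
        scores.append(1.0 - r)
    return float(np.mean(scores))


def importance_to_percent(scores: dict) -> dict:
    """Convert raw per-variable scores to percentages of their sum."""
    total = sum(scores.values())
    if total <= 0:
        raise DegenerateInputError("all importance scores are zero")
    return {v: 100.0 * s / total for v, s in scores.items()}


def ensemble_importance(weights: dict, member_scores: dict) -> tuple[dict, dict]:
    """Ensemble-level importance: weight, sum by variable, divide by n members.

    ``member_scores`` maps method -> {variable -> score}; all members must
    share the same variables.  Returns (raw EMmw scores, percents).  The
    divide-by-n rescales but never reorders.
    """
    if set(weights) != set(member_scores):
        raise SchemaError("weights and member scores name different methods")
    methods = list(weights)
    variables = list(member_scores[methods[0]])
    for m in methods[1:]:
        if set(member_scores[m]) != set(variables):
            raise SchemaError(f"member {m} scores different variables")
    n = len(methods)
    raw = {
        v: sum(weights[m] * member_scores[m][v] for m in methods) / n for v in variables
    }
    return raw, importance_to_percent(raw)


def importance_table(
    ensemble: EnsembleModel, tables: dict, n_shuffles: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Per-method and ensemble variable-importance percentages.

    Method-level scores average the randomization importance over that
    method's per-dataset final models; the EMmw row applies the ensemble
    weights.  Output: rows = methods + "EMmw", columns = variables,
    entries = percent of the row's total importance.
    """
    some_models = next(iter(ensemble.members.values()))
    variables = some_models[0].variables
    member_scores: dict[str, dict[str, float]] = {}
    for method, models in ensemble.members.items():
        per_var = {v: [] for v in variables}
        for m, ds_id in zip(models, tables):
            table = tables[ds_id]
            for i, v in enumerate(variables):
                s = randomization_importance(
                    m, table, v, n_shuffles=n_shuffles,
                    seed=_derive_seed(seed, f"imp:{method}:{v}", ds_id),
                )
                per_var[v].append(s)
        member_scores[method] = {v: float(np.mean(ss)) for v, ss in per_var.items()}
    rows = {}
    for method, scores in member_scores.items():
        rows[method] = importance_to_percent(scores)
    _, em_pct = ensemble_importance(ensemble.weights, member_scores)
    rows["EMmw"] = em_pct
    return pd.DataFrame(rows).T[variables]
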