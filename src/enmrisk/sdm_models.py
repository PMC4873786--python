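"""The nine base niche-model methods behind one fit/predict contract.

Every method consumes a feature table (predictor columns + binary ``label``
+ case ``weight``) and emits a probability-of-presence in [0, 1] per row.
Eight methods are adapters over established learners; the ninth, the
Surface Range Envelope (SRE), is a presence-only rectilinear climate
envelope implemented here.  "Default" hyperparameters are pinned explicitly
in :data:`METHOD_DEFAULTS` so runs are repeatable; all stochastic methods
honour the spec seed.

Method roster
-------------
ANN   multilayer perceptron (1 hidden layer; no case-weight support)
CTA   cost-complexity-pruned classification tree
FDA   flexible discriminant analysis: optimal-scoring least squares on a
      MARS hinge basis (two-class reduction)
GAM   logistic regression on per-variable B-spline bases
GBM   gradient boosted trees
GLM   logistic regression with linear + quadratic terms
MARS  logistic regression on a MARS hinge basis
RF    random forest
SRE   presence-only quantile envelope (binary output)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import DomainError, SchemaError
from .grids import RasterGrid
from .mars import fit_mars_basis, _wls_rss
from .predictors import PredictorStack, feature_columns

METHODS = ("ANN", "CTA", "FDA", "GAM", "GBM", "GLM", "MARS", "RF", "SRE")

#: Pinned per-method defaults (the repeatability contract: no hidden defaults).
METHOD_DEFAULTS: dict[str, dict] = {
    "ANN": {"hidden_layer_sizes": (5,), "alpha": 0.01, "max_iter": 500},
    "CTA": {"min_samples_leaf": 5, "ccp_alpha": 0.001},
    "FDA": {"max_terms": 15, "n_knots": 10},
    "GAM": {"n_knots": 5, "degree": 3, "C": 1.0, "max_iter": 1000},
    "GBM": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "GLM": {"max_iter": 1000},
    "MARS": {"max_terms": 15, "n_knots": 10, "C": 1e4, "max_iter": 1000},
    "RF": {"n_estimators": 500, "min_samples_leaf": 1},
    "SRE": {"quantile": 0.025},
}

__all__ = [
    "METHODS",
    "METHOD_DEFAULTS",
    "ModelSpec",
    "FittedModel",
    "SREEnvelope",
    "fit",
    "predict",
    "fit_sre",
    "predict_sre",
    "predict_raster",
]


@dataclass(frozen=True)
class ModelSpec:
    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DomainError(f"unknown method {self.method!r}; choose from {METHODS}")

    def resolved(self) -> dict:
        params = dict(METHOD_DEFAULTS[self.method])
        params.update(self.hyperparameters)
        return params


@dataclass
class SREEnvelope:
    """Per-variable presence-quantile bounds; predicts inside-the-box membership."""

    lower: np.ndarray
    upper: np.ndarray
    variables: list

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise DomainError("envelope lower bound exceeds upper bound")


@dataclass
class FittedModel:
    spec: ModelSpec
    variables: list
    _state: object  # backend estimator / (basis, beta) / SREEnvelope
    score: float | None = None  # mean cross-validated AUC, attached later

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = _extract_matrix(features, self.variables)
        return _predict_matrix(self, X)


def _extract_matrix(features, variables) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [v for v in variables if v not in features.columns]
        if missing:
            raise SchemaError(f"feature table lacks column(s) {missing}")
        return features[variables].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(variables):
        raise SchemaError(f"expected {len(variables)} feature columns, got shape {X.shape}")
    return X


def _quadratic_expand(X: np.ndarray) -> np.ndarray:
    return np.column_stack([X, X * X])


def fit_sre(presence_rows: pd.DataFrame | np.ndarray, quantile: float = 0.025, variables=None) -> SREEnvelope:
    """Presence-only envelope: bounds at the q and 1-q empirical quantiles.

    Quantiles use the linear-interpolation definition.  ``quantile`` must be
    in [0, 0.5); q = 0 gives the min/max envelope.
    """
    if not (0 <= quantile < 0.5):
        raise DomainError(f"SRE quantile must be in [0, 0.5), got {quantile}")
    if isinstance(presence_rows, pd.DataFrame):
        variables = variables or feature_columns(presence_rows)
        X = presence_rows[variables].to_numpy(dtype=float)
    else:
        X = np.asarray(presence_rows, dtype=float)
        variables = variables or [f"x{i}" for i in range(X.shape[1])]
    if len(X) < 2:
        raise DomainError("need at least 2 presence rows for an envelope")
    lower = np.quantile(X, quantile, axis=0, method="linear")
    upper = np.quantile(X, 1.0 - quantile, axis=0, method="linear")
    return SREEnvelope(lower=lower, upper=upper, variables=list(variables))


def predict_sre(envelope: SREEnvelope, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """1 iff every variable lies within its closed bounds, else 0."""
    X = _extract_matrix(features, envelope.variables)
    inside = (X >= envelope.lower) & (X <= envelope.upper)
    return inside.all(axis=1).astype(float)


def fit(spec: ModelSpec, table: pd.DataFrame) -> FittedModel:
    """Fit one method to a feature table; returns a [0,1]-probability model.

    Case weights are honoured by every backend that supports them (all but
    ANN).  Stochastic methods (ANN, GBM, RF) are reproducible under
    ``spec.seed``.
    """
    variables = feature_columns(table)
    if not variables:
        raise DomainError("feature table has no predictor columns")
    y = table["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2 and spec.method != "SRE":
        raise DomainError("feature table contains a single class")
    w = table["weight"].to_numpy(dtype=float) if "weight" in table.columns else np.ones(len(table))
    if np.any(w <= 0):
        raise DomainError("case weights must be positive")
    X = table[variables].to_numpy(dtype=float)
    p = spec.resolved()
    seed = int(spec.seed) % (2**31)

    if spec.method == "SRE":
        pres = table[table["label"] == 1]
        if len(pres) < 2:
            raise DomainError("SRE needs at least 2 presence rows")
        state = fit_sre(pres, quantile=p["quantile"], variables=variables)
    elif spec.method == "ANN":
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("mlp", MLPClassifier(
                    hidden_layer_sizes=tuple(p["hidden_layer_sizes"]),
                    alpha=p["alpha"], max_iter=p["max_iter"], random_state=seed,
                )),
            ]
        )
        est.fit(X, y)  # MLP has no sample_weight support
        state = est
    elif spec.method == "CTA":
        est = DecisionTreeClassifier(
            min_samples_leaf=p["min_samples_leaf"], ccp_alpha=p["ccp_alpha"], random_state=seed
        )
        est.fit(X, y, sample_weight=w)
        state = est
    elif spec.method == "GBM":
        est = GradientBoostingClassifier(
            n_estimators=p["n_estimators"], max_depth=p["max_depth"],
            learning_rate=p["learning_rate"], random_state=seed,
        )
        est.fit(X, y, sample_weight=w)
        state = est
    elif spec.method == "RF":
        est = RandomForestClassifier(
            n_estimators=p["n_estimators"], min_samples_leaf=p["min_samples_leaf"],
            random_state=seed, n_jobs=1,
        )
        est.fit(X, y, sample_weight=w)
        state = est
    elif spec.method == "GLM":
        est = LogisticRegression(C=np.inf, max_iter=p["max_iter"])
        est.fit(_quadratic_expand(X), y, sample_weight=w)
        state = est
    elif spec.method == "GAM":
        est = Pipeline(
            [
                ("spline", SplineTransformer(n_knots=p["n_knots"], degree=p["degree"])),
                ("logreg", LogisticRegression(C=p["C"], max_iter=p["max_iter"])),
            ]
        )
        est.fit(X, y, logreg__sample_weight=w)
        state = est
    elif spec.method == "MARS":
        basis = fit_mars_basis(X, y.astype(float), w, max_terms=p["max_terms"], n_knots=p["n_knots"])
        B = basis.transform(X)
        head = LogisticRegression(C=p["C"], max_iter=p["max_iter"], fit_intercept=False)
        head.fit(B, y, sample_weight=w)
        state = (basis, head)
    elif spec.method == "FDA":
        # two-class optimal scoring: weighted least squares of the 0/1 label
        # on the MARS basis, predictions clipped into [0, 1]
        basis = fit_mars_basis(X, y.astype(float), w, max_terms=p["max_terms"], n_knots=p["n_knots"])
        B = basis.transform(X)
        _, beta = _wls_rss(B, y.astype(float), w)
        state = (basis, beta)
    else:  # pragma: no cover - guarded by ModelSpec
        raise DomainError(spec.method)

    return FittedModel(spec=spec, variables=variables, _state=state)


def _predict_matrix(model: FittedModel, X: np.ndarray) -> np.ndarray:
    method = model.spec.method
    state = model._state
    if method == "SRE":
        out = predict_sre(state, X)
    elif method == "GLM":
        out = state.predict_proba(_quadratic_expand(X))[:, 1]
    elif method == "MARS":
        basis, head = state
        out = head.predict_proba(basis.transform(X))[:, 1]
    elif method == "FDA":
        basis, beta = state
        out = basis.transform(X) @ beta
    else:
        out = state.predict_proba(X)[:, 1]
    out = np.clip(np.asarray(out, dtype=float), 0.0, 1.0)
    if not np.all(np.isfinite(out)):
        raise DomainError(f"{method} produced non-finite predictions")
    return out


def predict(model: FittedModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Probability of presence per row, matched to training columns by name."""
    return model.predict(features)


def predict_raster(model: FittedModel, stack: PredictorStack) -> RasterGrid:
    """Cell-wise prediction; output masked wherever any input layer is masked."""
    missing = [v for v in model.variables if v not in stack.layers]
    if missing:
        raise SchemaError(f"stack lacks layer(s) {missing}")
    sub = stack.subset(model.variables)
    mask = sub.combined_mask
    rows, cols = np.nonzero(mask)
    X = np.column_stack([sub.layers[v].values[rows, cols] for v in model.variables])
    preds = _predict_matrix(model, X)
    out = np.zeros(sub.spec.shape)
    out[rows, cols] = preds
    return RasterGrid(sub.spec, out, mask)
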