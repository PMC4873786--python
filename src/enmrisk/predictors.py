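"""Predictor stacks, point extraction, and VIF-based collinearity pruning.

The variance inflation factor of a predictor is ``1 / (1 - R^2)`` where
``R^2`` comes from an ordinary least squares regression of that predictor on
all the others (with intercept).  Stepwise pruning repeatedly removes the
worst offender until every remaining VIF falls below a threshold (default
10, the classical rule of thumb), yielding a reduced suite of quasi-
independent variables that is then fixed for all downstream model fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, DomainError, SchemaError
from .grids import GridSpec, RasterGrid, require_same_spec

logger = logging.getLogger(__name__)

RESERVED_COLUMNS = ("label", "weight", "lon", "lat", "absence_dataset_id")

__all__ = ["PredictorStack", "feature_columns", "extract_values", "vif", "vif_stepwise"]


@dataclass
class PredictorStack:
    """Named, ordered set of co-registered raster layers."""

    layers: dict  # name -> RasterGrid, insertion-ordered

    def __post_init__(self) -> None:
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise DomainError("duplicate layer names")
        if not names:
            raise DomainError("empty predictor stack")
        spec0 = self.layers[names[0]].spec
        for name in names[1:]:
            require_same_spec(spec0, self.layers[name].spec, f"layers {names[0]!r} and {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.layers.values())).spec

    @property
    def combined_mask(self) -> np.ndarray:
        m = np.ones(self.spec.shape, dtype=bool)
        for g in self.layers.values():
            m &= g.mask
        return m

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise SchemaError(f"stack lacks layers {missing}")
        return PredictorStack({n: self.layers[n] for n in names})


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Predictor column names of a feature table (everything non-reserved)."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def extract_values(stack: PredictorStack, response: pd.DataFrame) -> pd.DataFrame:
    """Look up each response point's cell value in every layer.

    Rows falling on a masked cell in *any* layer are dropped (count logged).
    Returns a feature table: one column per predictor plus the carried
    ``label``/``weight`` (and bookkeeping) columns.
    """
    spec = stack.spec
    lon = response["lon"].to_numpy(dtype=float)
    lat = response["lat"].to_numpy(dtype=float)
    inside = spec.contains(lon, lat)
    if not inside.all():
        raise DomainError(f"{int((~inside).sum())} response point(s) outside predictor extent")
    rows, cols = spec.cell_of(lon, lat)
    out = response.reset_index(drop=True).copy()
    keep = np.ones(len(out), dtype=bool)
    for name, grid in stack.layers.items():
        out[name] = grid.values[rows, cols]
        keep &= grid.mask[rows, cols]
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("extract_values: dropped %d row(s) on masked cells", n_drop)
    return out[keep].reset_index(drop=True)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return float(model.rsquared)


def vif(table: pd.DataFrame, variable: str) -> float:
    """Variance inflation factor of ``variable`` against all other predictors.

    Returns ``math.inf`` when the regression is a perfect fit (R^2 = 1
    within 1e-12).
    """
    cols = feature_columns(table)
    if variable not in cols:
        raise SchemaError(f"unknown variable {variable!r}")
    if len(table) < 3:
        raise DomainError("need at least 3 rows to compute a VIF")
    others = [c for c in cols if c != variable]
    if not others:
        raise DomainError("need at least 2 predictor variables")
    y = table[variable].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise DegenerateInputError(f"variable {variable!r} has zero variance")
    r2 = _ols_r2(y, table[others].to_numpy(dtype=float))
    if 1.0 - r2 < 1e-12:
        return math.inf
    return 1.0 / (1.0 - r2)


def vif_stepwise(
    table: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop the highest-VIF variable until all fall below ``threshold``.

    Ties are broken by current column order (first wins removal).  Returns
    the retained names in original order and a removal log of
    ``(name, vif_at_removal)`` pairs.
    """
    remaining = feature_columns(table)
    if len(remaining) < 2:
        raise DomainError("need at least 2 variables for stepwise VIF selection")
    removal_log: list[tuple[str, float]] = []
    while len(remaining) >= 2:
        vifs = [vif(table[remaining], v) for v in remaining]
        worst = int(np.argmax(vifs))  # argmax takes the first maximum: column-order tie-break
        if vifs[worst] < threshold:
            break
        removal_log.append((remaining[worst], vifs[worst]))
        logger.info("vif_stepwise: removing %s (VIF %.3g)", remaining[worst], vifs[worst])
        remaining = [v for i, v in enumerate(remaining) if i != worst]
    return remaining, removal_log
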