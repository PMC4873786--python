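"""Virtual-species generator: every input the pipeline needs, simulated.

The generator stands in for real occurrence and climate downloads so the
whole workflow is testable and parameter recovery is measurable against a
known truth:

- environmental predictors are spatially autocorrelated Gaussian fields
  (smoothed white noise, standardized) with controllable pairwise
  collinearity;
- the virtual species' true suitability is a logistic function of a few
  effect variables with negative quadratic terms (unimodal niche
  preferences); presences are distinct cells sampled with probability
  proportional to true suitability;
- introduction-pressure inputs are Voronoi-block regions, a positive
  log-Gaussian discharge field, and log-uniform national totals.

The defaults constitute the reference study conditions used throughout the
test suite: a 64 x 64 grid of 0.125-degree (~10 km at mid-latitudes) cells,
10 candidate predictors of which 3 carry the niche signal and one is a
near-copy (r = 0.99) of another, and 300 presence cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import DegenerateInputError, DomainError
from .grids import GridSpec, RasterGrid, RegionMap
from .predictors import PredictorStack
from .risk import PressureInputs

__all__ = [
    "VirtualSpeciesConfig",
    "VirtualTruth",
    "generate_environment",
    "generate_virtual_species",
    "generate_pressure_inputs",
]

REFERENCE_GRID = GridSpec(n_rows=64, n_cols=64, lon_origin=0.0, lat_origin=50.0, cell_size=0.125)


def _var_name(i: int) -> str:
    return f"env{i + 1:02d}"


@dataclass
class VirtualSpeciesConfig:
    """Reference study conditions for the simulated system."""

    grid: GridSpec = REFERENCE_GRID
    n_vars: int = 10
    autocorr_cells: float = 6.0
    collinear_pairs: list = field(default_factory=lambda: [("env04", "env10", 0.99)])
    effect_vars: list = field(default_factory=lambda: ["env01", "env02", "env03"])
    linear_coefs: dict = field(default_factory=lambda: {"env01": 1.0, "env02": 0.8, "env03": 0.6})
    quadratic_coefs: dict = field(default_factory=lambda: {"env01": -2.0, "env02": -1.6, "env03": -1.2})
    intercept: float = 1.0
    n_presences: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        names = [_var_name(i) for i in range(self.n_vars)]
        unknown = [v for v in self.effect_vars if v not in names]
        if unknown:
            raise DomainError(f"effect variables {unknown} not among generated names {names[:3]}...")
        for a, b, r in self.collinear_pairs:
            if a == b:
                raise DomainError("collinear pair must reference two distinct variables")
            if not (-1 <= r <= 1):
                raise DomainError(f"target correlation {r} outside [-1, 1]")
        if self.n_presences < 1:
            raise DomainError("n_presences must be >= 1")

    @property
    def var_names(self) -> list:
        return [_var_name(i) for i in range(self.n_vars)]


@dataclass
class VirtualTruth:
    """Ground truth for recovery tests: the generating suitability surface."""

    true_suitability: RasterGrid
    effect_vars: list
    linear_coefs: dict
    quadratic_coefs: dict
    intercept: float


def _smoothed_standard_field(rng: np.random.Generator, shape, autocorr_cells: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if autocorr_cells > 0:
        z = gaussian_filter(z, sigma=autocorr_cells, mode="reflect")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def generate_environment(config: VirtualSpeciesConfig) -> PredictorStack:
    """Autocorrelated predictor stack with the configured collinearity.

    Each layer is Gaussian-smoothed white noise standardized to mean 0,
    sd 1.  A collinear pair (a, b, r) rebuilds layer b as
    ``r*a + sqrt(1-r^2)*b`` (then re-standardizes), giving sample
    correlation close to r by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    shape = config.grid.shape
    fields = {
        name: _smoothed_standard_field(rng, shape, config.autocorr_cells)
        for name in config.var_names
    }
    for a, b, r in config.collinear_pairs:
        mixed = r * fields[a] + np.sqrt(max(0.0, 1 - r * r)) * fields[b]
        mixed = mixed - mixed.mean()
        sd = mixed.std()
        fields[b] = mixed / sd if sd > 0 else mixed
    layers = {name: RasterGrid(config.grid, fields[name]) for name in config.var_names}
    return PredictorStack(layers)


def true_suitability_surface(stack: PredictorStack, config: VirtualSpeciesConfig) -> RasterGrid:
    eta = np.full(config.grid.shape, float(config.intercept))
    for v in config.effect_vars:
        x = stack.layers[v].values
        eta = eta + config.linear_coefs.get(v, 0.0) * x + config.quadratic_coefs.get(v, 0.0) * x * x
    return RasterGrid(config.grid, expit(eta), stack.combined_mask)


def generate_virtual_species(
    stack: PredictorStack, config: VirtualSpeciesConfig
) -> tuple[VirtualTruth, pd.DataFrame]:
    """Known-truth suitability plus presence records sampled from it.

    Presences occupy distinct cells, drawn without replacement with
    probability proportional to true suitability, and are placed at the
    sampled cells' centroids.
    """
    missing = [v for v in config.effect_vars if v not in stack.layers]
    if missing:
        raise DomainError(f"stack lacks effect variable(s) {missing}")
    truth = true_suitability_surface(stack, config)
    s = np.where(truth.mask, truth.values, 0.0).ravel()
    if s.sum() <= 0:
        raise DegenerateInputError("true suitability is zero everywhere")
    n_cells = s.size
    if config.n_presences > int((s > 0).sum()):
        raise DomainError("more presences requested than cells with positive suitability")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    chosen = rng.choice(n_cells, size=config.n_presences, replace=False, p=s / s.sum())
    rows, cols = np.unravel_index(chosen, config.grid.shape)
    lon, lat = config.grid.centroids(rows, cols)
    records = pd.DataFrame({"lon": lon, "lat": lat, "source_tag": "virtual", "year": 2016})
    return (
        VirtualTruth(
            true_suitability=truth,
            effect_vars=list(config.effect_vars),
            linear_coefs=dict(config.linear_coefs),
            quadratic_coefs=dict(config.quadratic_coefs),
            intercept=config.intercept,
        ),
        records,
    )


def generate_pressure_inputs(grid: GridSpec, n_regions: int = 4, seed: int = 0) -> PressureInputs:
    """Voronoi-block regions, log-Gaussian discharge, log-uniform totals."""
    if n_regions < 1:
        raise DomainError("n_regions must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    centres = rng.uniform(0, 1, size=(n_regions, 2)) * np.array([grid.n_rows, grid.n_cols])
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    d2 = (rr[..., None] - centres[:, 0]) ** 2 + (cc[..., None] - centres[:, 1]) ** 2
    region_id = np.argmin(d2, axis=-1) + 1
    regions = RegionMap(grid, region_id)
    raw = rng.standard_normal(grid.shape)
    discharge = RasterGrid(grid, np.exp(gaussian_filter(raw, sigma=4.0, mode="reflect") * 2.0))
    totals = {r: float(10.0 ** rng.uniform(0, 2)) for r in range(1, n_regions + 1)}
    return PressureInputs(regions=regions, national_total=totals, discharge=discharge)
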