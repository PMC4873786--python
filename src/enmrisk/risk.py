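"""Introduction-pressure surrogate and the final invasion-risk surface.

Introduction pressure emulates an aquaculture-pressure layer: a national
(per-region) annual harvest total is spread over that region's cells in
proportion to each cell's river discharge, the distributed layer is
bilinearly resampled onto the analysis grid, and min-max rescaled to [0, 1].
The risk map is the cell-wise product of the [0, 1] habitat-suitability
surface and the [0, 1] pressure surface: 0 = no risk, 1 = high risk, equal
weighting of the two factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .grids import GridSpec, RasterGrid, RegionMap, bilinear_resample, normalize01, require_same_spec

__all__ = ["PressureInputs", "distribute_national_pressure", "build_pressure_layer", "make_risk_map"]


@dataclass
class PressureInputs:
    """Region map + per-region totals + discharge raster (all co-registered)."""

    regions: RegionMap
    national_total: dict  # region id -> non-negative total
    discharge: RasterGrid

    def __post_init__(self) -> None:
        require_same_spec(self.regions.spec, self.discharge.spec, "regions and discharge")
        present = set(np.unique(self.regions.region_id)) - {0}
        missing = set(self.national_total) - present
        if missing:
            raise DomainError(f"totals given for region id(s) {sorted(missing)} absent from the map")
        if any(t < 0 for t in self.national_total.values()):
            raise DomainError("national totals must be non-negative")


def distribute_national_pressure(inputs: PressureInputs) -> RasterGrid:
    """Spread each region's total over its cells proportionally to discharge.

    Cell value = total[region] * discharge / (sum of discharge over the
    region); per-region sums equal the totals exactly (to rounding).  Cells
    with region id 0, or in regions with no stated total, are masked.
    """
    rid = inputs.regions.region_id
    disch = np.where(inputs.discharge.mask, inputs.discharge.values, 0.0)
    if np.any(disch < 0):
        raise DomainError("discharge must be non-negative")
    out = np.zeros(rid.shape)
    mask = np.zeros(rid.shape, dtype=bool)
    for region, total in inputs.national_total.items():
        cells = rid == region
        mask |= cells
        if total == 0:
            continue
        dsum = disch[cells].sum()
        if dsum <= 0:
            raise DomainError(
                f"region {region} has positive total {total} but zero summed discharge"
            )
        out[cells] = total * disch[cells] / dsum
    return RasterGrid(inputs.regions.spec, out, mask)


def build_pressure_layer(
    inputs: PressureInputs, target: GridSpec, *, normalize_first: bool = False
) -> RasterGrid:
    """Distributed pressure, resampled to the analysis grid, rescaled to [0, 1].

    Default order distributes, resamples, then normalises; set
    ``normalize_first`` to rescale before resampling (strict emulation of a
    pre-made 0-1 layer).
    """
    layer = distribute_national_pressure(inputs)
    if normalize_first:
        layer = normalize01(layer)
    layer = bilinear_resample(layer, target)
    return normalize01(layer)


def make_risk_map(suitability: RasterGrid, pressure: RasterGrid) -> RasterGrid:
    """Risk = suitability x pressure, masked where either factor is masked."""
    require_same_spec(suitability.spec, pressure.spec, "suitability and pressure")
    for name, g in (("suitability", suitability), ("pressure", pressure)):
        v = g.values[g.mask]
        if len(v) and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise DomainError(f"{name} values must lie in [0, 1]")
    mask = suitability.mask & pressure.mask
    values = np.where(mask, suitability.values * pressure.values, 0.0)
    return RasterGrid(suitability.spec, values, mask)
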