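"""Presence thinning, annulus-constrained pseudo-absences, and the response table.

Occurrence records are spatially thinned to one representative per grid cell
("presence cells"), which removes duplicate-coordinate records and damps
sampling-effort clustering.  Pseudo-absences are random points constrained to
an annulus around the presence cloud: strictly more than ``r_inner_km`` (50 km)
but at most ``r_outer_km`` (100 km) from the nearest presence-cell centroid.
Presences and absences are then stacked into a binary response table whose
case weights give the two classes equal total prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InfeasibleGeometryError
from .grids import GridSpec, RasterGrid, great_circle_km

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceCellSet",
    "AbsenceDataset",
    "read_occurrences",
    "thin_to_cells",
    "generate_pseudo_absences",
    "assemble_response",
]


@dataclass
class PresenceCellSet:
    """Thinned occurrences: one geometric cell centre per occupied cell."""

    spec: GridSpec
    cells: list  # ordered (row, col) pairs
    centroids: np.ndarray  # (n, 2) lon, lat, aligned with cells

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.cells) != len(self.centroids):
            raise DomainError("cells and centroids must align")

    def __len__(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows, cols = zip(*self.cells) if self.cells else ((), ())
        return pd.DataFrame(
            {
                "row": list(rows),
                "col": list(cols),
                "lon": self.centroids[:, 0] if len(self) else [],
                "lat": self.centroids[:, 1] if len(self) else [],
            }
        )


@dataclass
class AbsenceDataset:
    """One replicate set of pseudo-absence points."""

    dataset_id: int
    points: np.ndarray  # (n, 2) lon, lat
    seed: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


def read_occurrences(path, lon_col: str = "lon", lat_col: str = "lat") -> pd.DataFrame:
    """Read a delimited occurrence table; returns columns lon, lat (+ extras)."""
    df = pd.read_csv(path)
    for col in (lon_col, lat_col):
        if col not in df.columns:
            raise DomainError(f"occurrence file {path} lacks column {col!r}")
    df = df.rename(columns={lon_col: "lon", lat_col: "lat"})
    bad = df[(df.lon < -180) | (df.lon > 180) | (df.lat < -90) | (df.lat > 90)]
    if len(bad):
        raise DomainError(f"{len(bad)} records have coordinates outside valid ranges")
    return df


def thin_to_cells(records: pd.DataFrame, spec: GridSpec) -> PresenceCellSet:
    """Collapse records to the set of occupied cells, one centroid each.

    The representative point of each occupied cell is the *geometric* cell
    centre, not any record's coordinates.
    """
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    inside = spec.contains(lon, lat)
    if not inside.all():
        offenders = records.index[~inside].tolist()
        raise DomainError(
            f"{len(offenders)} occurrence record(s) outside grid extent (indices {offenders[:10]}"
            + ("...)" if len(offenders) > 10 else ")")
        )
    rows, cols = spec.cell_of(lon, lat)
    cells = sorted(set(zip(rows.tolist(), cols.tolist())))
    r = np.array([c[0] for c in cells])
    c = np.array([c[1] for c in cells])
    clon, clat = spec.centroids(r, c)
    return PresenceCellSet(spec=spec, cells=cells, centroids=np.column_stack([clon, clat]))


def _min_distance_km(lon, lat, centroids: np.ndarray) -> np.ndarray:
    """Distance from each query point to its nearest presence centroid."""
    d = great_circle_km(
        np.asarray(lon)[:, None], np.asarray(lat)[:, None], centroids[None, :, 0], centroids[None, :, 1]
    )
    return np.min(d, axis=1)


def generate_pseudo_absences(
    presences: PresenceCellSet,
    grid: RasterGrid | None = None,
    *,
    n_per_dataset: int = 1000,
    n_datasets: int = 10,
    r_inner_km: float = 50.0,
    r_outer_km: float = 100.0,
    seed: int = 0,
    max_attempts_per_point: int = 10_000,
) -> list[AbsenceDataset]:
    """Rejection-sample ``n_datasets`` replicate pseudo-absence sets.

    Each point is drawn by picking a uniform random unmasked cell, jittering
    uniformly within it, and accepting iff the distance to the nearest
    presence centroid lies in ``(r_inner_km, r_outer_km]``.  Sampling is
    unbiased over the eligible annulus region.  Identical seeds give
    identical output.
    """
    if len(presences) == 0:
        raise DomainError("presence set is empty")
    spec = presences.spec
    if grid is None:
        grid = RasterGrid(spec, np.zeros(spec.shape), np.ones(spec.shape, dtype=bool))
    valid_rows, valid_cols = np.nonzero(grid.mask)
    if len(valid_rows) == 0:
        raise DomainError("grid has no unmasked cells")

    centroids = presences.centroids
    datasets: list[AbsenceDataset] = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_datasets)
    batch = max(4 * n_per_dataset, 256)
    for d in range(n_datasets):
        rng = np.random.default_rng(children[d])
        pts: list[np.ndarray] = []
        attempts = 0
        budget = max_attempts_per_point * n_per_dataset
        while sum(len(p) for p in pts) < n_per_dataset:
            if attempts >= budget:
                raise InfeasibleGeometryError(
                    f"dataset {d + 1}: placed {sum(len(p) for p in pts)}/{n_per_dataset} points "
                    f"after {attempts} attempts; the {r_inner_km}-{r_outer_km} km annulus may be "
                    "empty on this grid"
                )
            idx = rng.integers(0, len(valid_rows), size=batch)
            jitter = rng.random(size=(batch, 2))
            attempts += batch
            lon = spec.lon_origin + (valid_cols[idx] + jitter[:, 0]) * spec.cell_size
            lat = spec.lat_origin - (valid_rows[idx] + jitter[:, 1]) * spec.cell_size
            dmin = _min_distance_km(lon, lat, centroids)
            ok = (dmin > r_inner_km) & (dmin <= r_outer_km)
            if ok.any():
                pts.append(np.column_stack([lon[ok], lat[ok]]))
        all_pts = np.concatenate(pts)[:n_per_dataset]
        datasets.append(AbsenceDataset(dataset_id=d + 1, points=all_pts, seed=seed))
        logger.info("absence dataset %d: %d points (%d candidate draws)", d + 1, n_per_dataset, attempts)
    return datasets


def assemble_response(presences: PresenceCellSet, absences: AbsenceDataset) -> pd.DataFrame:
    """Stack presences (label 1) and absences (label 0) with equal-prevalence weights.

    Presence rows carry weight 1; absence rows carry ``n_presences/n_absences``
    so that the summed weight of each class is identical.
    """
    if len(presences) == 0 or len(absences) == 0:
        raise DomainError("both presences and absences must be non-empty")
    n1, n0 = len(presences), len(absences)
    pres = pd.DataFrame(
        {
            "lon": presences.centroids[:, 0],
            "lat": presences.centroids[:, 1],
            "label": 1,
            "weight": 1.0,
            "absence_dataset_id": pd.NA,
        }
    )
    absn = pd.DataFrame(
        {
            "lon": absences.points[:, 0],
            "lat": absences.points[:, 1],
            "label": 0,
            "weight": n1 / n0,
            "absence_dataset_id": absences.dataset_id,
        }
    )
    return pd.concat([pres, absn], ignore_index=True)
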