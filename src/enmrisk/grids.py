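"""Raster data model and spatial primitives.

All mapped quantities in the pipeline — environmental predictors, habitat
suitability, introduction pressure, invasion risk — live on a common
rectangular geographic (lon/lat, WGS84-style) grid of square cells measured
in degrees.  The convention is north-up: cell (0, 0) sits at the north-west
corner, rows increase southward, columns eastward, and each cell is the
half-open box ``[edge, edge + cell_size)`` so point-in-cell assignment is a
floor operation.

File formats: ESRI ASCII grid (the plain-text fixture format) and minimal
single-band GeoTIFF via :mod:`tifffile`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError, DomainError, RasterFormatError, SchemaError

EARTH_RADIUS_KM = 6371.0
DEFAULT_NODATA = -9999.0

__all__ = [
    "GridSpec",
    "RasterGrid",
    "RegionMap",
    "read_raster",
    "write_raster",
    "great_circle_km",
    "bilinear_resample",
    "normalize01",
    "cell_centroid",
    "EARTH_RADIUS_KM",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up lat/lon raster.

    ``lon_origin``/``lat_origin`` are the west and *north* edges of cell
    (0, 0); ``cell_size`` is the square cell edge in degrees.
    """

    n_rows: int
    n_cols: int
    lon_origin: float
    lat_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise DomainError(f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise DomainError(f"cell_size must be positive, got {self.cell_size}")
        eps = 1e-9
        lon_max = self.lon_origin + self.n_cols * self.cell_size
        lat_min = self.lat_origin - self.n_rows * self.cell_size
        if self.lon_origin < -180 - eps or lon_max > 180 + eps:
            raise DomainError(f"grid longitude span [{self.lon_origin}, {lon_max}] leaves [-180, 180]")
        if self.lat_origin > 90 + eps or lat_min < -90 - eps:
            raise DomainError(f"grid latitude span [{lat_min}, {self.lat_origin}] leaves [-90, 90]")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_max(self) -> float:
        return self.lon_origin + self.n_cols * self.cell_size

    @property
    def lat_min(self) -> float:
        return self.lat_origin - self.n_rows * self.cell_size

    def contains(self, lon, lat) -> np.ndarray:
        """Vectorised extent test under the half-open cell convention."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= self.lon_origin) & (lon < self.lon_max) & (lat <= self.lat_origin) & (lat > self.lat_min)

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; caller checks extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_origin) / self.cell_size).astype(int)
        row = np.floor((self.lat_origin - lat) / self.cell_size).astype(int)
        # points exactly on the south/east extent edge belong to the last cell
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def centroids(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        lon = self.lon_origin + (cols + 0.5) * self.cell_size
        lat = self.lat_origin - (rows + 0.5) * self.cell_size
        return lon, lat


@dataclass
class RasterGrid:
    """One variable on a :class:`GridSpec`; ``mask`` is True where valid."""

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.spec.shape or self.mask.shape != self.spec.shape:
            raise DomainError(
                f"values/mask shape {self.values.shape}/{self.mask.shape} "
                f"does not match spec {self.spec.shape}"
            )
        if not np.all(np.isfinite(self.values[self.mask])):
            raise DomainError("non-finite values on unmasked cells")

    def copy_with(self, values=None, mask=None) -> "RasterGrid":
        return RasterGrid(
            self.spec,
            self.values.copy() if values is None else values,
            self.mask.copy() if mask is None else mask,
        )


@dataclass
class RegionMap:
    """Integer region (nation) id per cell; 0 means no region."""

    spec: GridSpec
    region_id: np.ndarray

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id)
        if self.region_id.shape != self.spec.shape:
            raise DomainError("region_id shape does not match spec")
        if np.any(self.region_id < 0):
            raise DomainError("region ids must be non-negative")


def cell_centroid(spec: GridSpec, row: int, col: int) -> tuple[float, float]:
    """(lon, lat) of the centre of cell (row, col)."""
    if not (0 <= row < spec.n_rows and 0 <= col < spec.n_cols):
        raise IndexError(f"cell ({row}, {col}) outside {spec.n_rows}x{spec.n_cols} grid")
    lon, lat = spec.centroids(row, col)
    return float(lon), float(lat)


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _read_ascii_grid(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS:
                if len(tokens) != 2:
                    raise RasterFormatError(f"{path}: header line for '{key}' must have one value")
                header[key] = float(tokens[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise RasterFormatError(f"{path}: missing required header field '{req}'")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    cell = header["cellsize"]
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        lon_origin=header["xllcorner"],
        lat_origin=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
    )
    rows = []
    for i, line in enumerate(data_lines):
        vals = line.split()
        if len(vals) != n_cols:
            raise RasterFormatError(f"{path}: data row {i} has {len(vals)} values, ncols header says {n_cols}")
        rows.append([float(v) for v in vals])
    if len(rows) != n_rows:
        raise RasterFormatError(f"{path}: found {len(rows)} data rows, nrows header says {n_rows}")
    values = np.array(rows, dtype=float)
    mask = values != nodata
    values = np.where(mask, values, 0.0)
    return RasterGrid(spec, values, mask)


def _fmt(v: float) -> str:
    """Shortest decimal that re-parses to the same float (round-trip exact)."""
    return repr(float(v))


def _write_ascii_grid(grid: RasterGrid, path: Path, nodata: float = DEFAULT_NODATA) -> None:
    spec = grid.spec
    out = np.where(grid.mask, grid.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {_fmt(spec.lon_origin)}\n")
        fh.write(f"yllcorner {_fmt(spec.lat_min)}\n")
        fh.write(f"cellsize {_fmt(spec.cell_size)}\n")
        fh.write(f"NODATA_value {_fmt(nodata)}\n")
        for r in range(spec.n_rows):
            fh.write(" ".join(_fmt(v) for v in out[r]) + "\n")


# GeoTIFF tag ids: pixel scale, tie point, GDAL nodata
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(grid: RasterGrid, path: Path, nodata: float = DEFAULT_NODATA) -> None:
    import tifffile

    spec = grid.spec
    out = np.where(grid.mask, grid.values, nodata).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.lon_origin, spec.lat_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, _fmt(nodata)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def _read_geotiff(path: Path) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise RasterFormatError(f"{path}: expected a single-band raster, got shape {values.shape}")
        tags = {t.code: t.value for t in page.tags.values()}
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterFormatError(f"{path}: missing georeferencing tag (ModelPixelScale/ModelTiepoint)")
        sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise RasterFormatError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
        tie = tags[_TAG_TIEPOINT]
        lon_origin = tie[3] - tie[0] * sx
        lat_origin = tie[4] + tie[1] * sy
        nodata = float(tags[_TAG_GDAL_NODATA]) if _TAG_GDAL_NODATA in tags else DEFAULT_NODATA
    n_rows, n_cols = values.shape
    spec = GridSpec(n_rows=n_rows, n_cols=n_cols, lon_origin=lon_origin, lat_origin=lat_origin, cell_size=sx)
    mask = values != nodata
    return RasterGrid(spec, np.where(mask, values, 0.0), mask)


def read_raster(path, format: str = "ascii-grid") -> RasterGrid:
    """Read a single-band raster (``ascii-grid`` or ``geotiff``)."""
    path = Path(path)
    if format == "ascii-grid":
        return _read_ascii_grid(path)
    if format == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {format!r}")


def write_raster(grid: RasterGrid, path, format: str = "ascii-grid", nodata: float = DEFAULT_NODATA) -> None:
    """Write a raster; masked cells become the nodata sentinel."""
    path = Path(path)
    try:
        if format == "ascii-grid":
            _write_ascii_grid(grid, path, nodata)
        elif format == "geotiff":
            _write_geotiff(grid, path, nodata)
        else:
            raise ValueError(f"unknown raster format {format!r}")
    except OSError as exc:
        raise OSError(f"failed writing raster to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Resampling and normalisation
# ---------------------------------------------------------------------------

def bilinear_resample(grid: RasterGrid, target: GridSpec) -> RasterGrid:
    """Bilinear interpolation of cell-centre values onto ``target``.

    If some of a target cell's four surrounding source centres are masked,
    weights are renormalised over the valid ones (keeps coastlines from
    eroding); a cell with all four masked, or falling outside the source
    extent, is masked.  At the outer half-cell rim the interpolation
    extrapolates linearly from the nearest cell pair, which reproduces
    planar fields exactly.
    """
    src = grid.spec
    if (
        target.lon_origin >= src.lon_max
        or target.lon_max <= src.lon_origin
        or target.lat_origin <= src.lat_min
        or target.lat_min >= src.lat_origin
    ):
        raise DomainError("target extent is disjoint from source extent")

    t_lon = target.lon_origin + (np.arange(target.n_cols) + 0.5) * target.cell_size
    t_lat = target.lat_origin - (np.arange(target.n_rows) + 0.5) * target.cell_size
    # fractional position in source cell-centre coordinates
    fx = (t_lon - (src.lon_origin + 0.5 * src.cell_size)) / src.cell_size
    fy = ((src.lat_origin - 0.5 * src.cell_size) - t_lat) / src.cell_size
    FX, FY = np.meshgrid(fx, fy)
    inside = (
        (FX >= -0.5) & (FX <= src.n_cols - 0.5) & (FY >= -0.5) & (FY <= src.n_rows - 0.5)
    )

    i0 = np.clip(np.floor(FY).astype(int), 0, max(src.n_rows - 2, 0))
    j0 = np.clip(np.floor(FX).astype(int), 0, max(src.n_cols - 2, 0))
    dy = FY - i0
    dx = FX - j0
    i1 = np.minimum(i0 + 1, src.n_rows - 1)
    j1 = np.minimum(j0 + 1, src.n_cols - 1)

    vals = grid.values
    msk = grid.mask.astype(float)
    corners = ((i0, j0), (i0, j1), (i1, j0), (i1, j1))
    weights = ((1 - dy) * (1 - dx), (1 - dy) * dx, dy * (1 - dx), dy * dx)

    wsum = np.zeros(target.shape)
    vacc = np.zeros(target.shape)
    for (ii, jj), w in zip(corners, weights):
        wv = w * msk[ii, jj]
        vacc += wv * vals[ii, jj]
        wsum += wv
    any_valid = wsum > 1e-12
    out_mask = inside & any_valid
    out = np.zeros(target.shape)
    out[out_mask] = vacc[out_mask] / wsum[out_mask]
    return RasterGrid(target, out, out_mask)


def normalize01(grid: RasterGrid) -> RasterGrid:
    """Min-max rescale of unmasked cells onto [0, 1]; mask preserved."""
    if not grid.mask.any():
        raise DegenerateInputError("cannot normalise a fully masked grid")
    v = grid.values[grid.mask]
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateInputError(f"constant grid (value {lo}) cannot be rescaled onto [0, 1]")
    out = np.zeros_like(grid.values)
    out[grid.mask] = (grid.values[grid.mask] - lo) / (hi - lo)
    return RasterGrid(grid.spec, out, grid.mask.copy())


def require_same_spec(a: GridSpec, b: GridSpec, what: str = "layers") -> None:
    if a != b:
        raise SchemaError(f"{what} are on different grids: {a} vs {b}")
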