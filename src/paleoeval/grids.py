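"""Gridded suitability surfaces: I/O, point snapping, value extraction.

Conventions, stated once and used everywhere:

* coordinates are WGS84 decimal degrees (longitude, latitude);
* grids are north-up with square cells, row 0 at the northern edge;
* registration is cell-center: the value of cell (row, col) is taken to
  hold at its center;
* suitability is in [0, 1]; nodata cells are *invalid* and carry NaN.

Rasters are read and written as single-band ESRI ASCII grids (``.asc``), a
plain-text format with a six-line header (ncols, nrows, xllcorner,
yllcorner, cellsize, NODATA_value) followed by rows north to south.

Point-to-cell distances are great-circle (haversine), appropriate at the
continental extents these analyses run at.  A point whose own cell is
invalid (a coastal site falling off-grid, typically) is *snapped* to the
valid cell whose center is nearest, within a capped search radius.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import numpy as np

from .errors import AlignmentError, EmptyInputError, NoValidCellError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between (lon1, lat1) and (lon2, lat2).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


@dataclass(frozen=True)
class GridTransform:
    """North-up geotransform: western edge, northern edge, square cell size
    in degrees, and grid dimensions."""

    x_origin: float  # longitude of the western edge
    y_origin: float  # latitude of the northern edge
    cell_size: float  # degrees, square cells
    nrows: int
    ncols: int

    def __post_init__(self):
        if self.cell_size <= 0 or self.nrows < 1 or self.ncols < 1:
            raise ValueError("degenerate geotransform")

    def cell_center(self, row, col):
        """(lon, lat) of the center of cell (row, col); array-friendly."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin - (row + 0.5) * self.cell_size
        return lon, lat

    def index_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing a point, or None if outside."""
        col = math.floor((lon - self.x_origin) / self.cell_size)
        row = math.floor((self.y_origin - lat) / self.cell_size)
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def cell_diagonal_km(self) -> float:
        """Haversine length of one cell diagonal at the grid's central
        latitude (used for the default snapping radius)."""
        lat_mid = self.y_origin - 0.5 * self.nrows * self.cell_size
        return float(
            haversine_km(
                0.0, lat_mid, self.cell_size, lat_mid + self.cell_size
            )
        )


@dataclass
class SuitabilityGrid:
    """One slice's suitability surface: values (NaN where invalid), a
    validity mask, and the shared geotransform."""

    values: np.ndarray
    transform: GridTransform
    mask: np.ndarray  # True where valid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.shape != (self.transform.nrows, self.transform.ncols):
            raise ValueError("values shape does not match geotransform")
        valid = self.values[self.mask]
        if valid.size and (np.nanmin(valid) < 0 or np.nanmax(valid) > 1):
            raise ValueError("valid suitability values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def valid_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, lons, lats) of all valid cell centers, row-major."""
        rows, cols = np.nonzero(self.mask)
        lons, lats = self.transform.cell_center(rows, cols)
        return rows, cols, lons, lats


@dataclass
class SuitabilityStack:
    """Per-slice suitability grids sharing one geotransform."""

    grids: dict[str, SuitabilityGrid]

    def __post_init__(self):
        labels = list(self.grids)
        if not labels:
            raise EmptyInputError("empty suitability stack")
        ref = self.grids[labels[0]].transform
        for label in labels[1:]:
            if self.grids[label].transform != ref:
                raise AlignmentError(
                    f"slice {label!r} is not aligned with slice {labels[0]!r}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.grids)

    @property
    def transform(self) -> GridTransform:
        return next(iter(self.grids.values())).transform

    def __getitem__(self, label: str) -> SuitabilityGrid:
        return self.grids[label]


def read_ascii_grid(path) -> tuple[SuitabilityGrid, int]:
    """Read one ESRI ASCII grid; returns the grid and the count of cells
    clipped into [0, 1]."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=float)

    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    mask = data != nodata

    transform = GridTransform(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        nrows=nrows,
        ncols=ncols,
    )
    values = np.where(mask, data, np.nan)
    clipped = int((mask & ((data < 0) | (data > 1))).sum())
    if clipped:
        logger.warning("%s: clipped %d cell(s) into [0, 1]", path, clipped)
    values = np.clip(values, 0.0, 1.0)
    return SuitabilityGrid(values=values, transform=transform, mask=mask), clipped


def write_ascii_grid(grid: SuitabilityGrid, path, nodata: float = -9999.0) -> None:
    """Write a suitability grid as an ESRI ASCII raster."""
    t = grid.transform
    out = np.where(grid.mask, grid.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {t.ncols}\n")
        fh.write(f"nrows {t.nrows}\n")
        fh.write(f"xllcorner {t.x_origin!r}\n")
        fh.write(f"yllcorner {t.y_origin - t.nrows * t.cell_size!r}\n")
        fh.write(f"cellsize {t.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, out, fmt="%.10g")


def read_suitability_stack(paths: dict[str, str]) -> tuple[SuitabilityStack, dict[str, int]]:
    """Read one ASCII grid per slice label.

    Returns the stack plus a per-slice count of values clipped into [0, 1].
    Raises :class:`AlignmentError` naming the first slice whose geotransform
    differs from the others.
    """
    grids: dict[str, SuitabilityGrid] = {}
    clip_report: dict[str, int] = {}
    ref_label = None
    for label, path in paths.items():
        grid, clipped = read_ascii_grid(path)
        clip_report[label] = clipped
        if ref_label is None:
            ref_label = label
        elif grid.transform != grids[ref_label].transform:
            raise AlignmentError(
                f"raster for slice {label!r} ({path}) is not aligned with "
                f"slice {ref_label!r}"
            )
        grids[label] = grid
    return SuitabilityStack(grids=grids), clip_report


@dataclass(frozen=True)
class SnapResult:
    """Outcome of snapping one point to a valid cell."""

    longitude: float
    latitude: float
    row: int
    col: int
    moved: bool
    distance_km: float


def snap_to_valid(
    lon: float,
    lat: float,
    grid: SuitabilityGrid,
    max_radius_km: float | None = None,
) -> SnapResult | None:
    """Snap a point to the nearest valid cell center.

    A point already on a valid cell is returned unchanged (``moved=False``).
    Otherwise the valid cell whose center is nearest by great-circle
    distance is chosen, ties broken by lowest (row, col); if that distance
    exceeds ``max_radius_km`` the point is unsnappable and None is returned.
    The default radius is twice the cell diagonal — generous enough for
    coastal off-grid points, tight enough not to teleport records.
    """
    if grid.n_valid == 0:
        raise NoValidCellError("grid has no valid cells to snap to")
    if max_radius_km is None:
        max_radius_km = 2.0 * grid.transform.cell_diagonal_km()
    if max_radius_km <= 0:
        raise ValueError("max_radius_km must be positive")

    idx = grid.transform.index_of(lon, lat)
    if idx is not None and grid.mask[idx]:
        return SnapResult(lon, lat, idx[0], idx[1], moved=False, distance_km=0.0)

    rows, cols, lons, lats = grid.valid_centers()
    dists = haversine_km(lon, lat, lons, lats)
    dmin = dists.min()
    if dmin > max_radius_km:
        return None
    # ties (within float round-off of the haversine) break on lowest
    # (row, col); valid_centers is row-major so the first near-minimal
    # index is that cell
    k = int(np.argmax(dists <= dmin * (1.0 + 1e-9) + 1e-12))
    slon, slat = grid.transform.cell_center(int(rows[k]), int(cols[k]))
    return SnapResult(
        float(slon),
        float(slat),
        int(rows[k]),
        int(cols[k]),
        moved=True,
        distance_km=float(dmin),
    )


def extract_suitability(grid: SuitabilityGrid, lons, lats) -> np.ndarray:
    """Suitability of the cell containing each point.

    Points on invalid cells or outside the grid yield NaN (with a logged
    warning); callers are expected to snap first.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.shape != lats.shape:
        raise ValueError("lons and lats must have the same length")
    out = np.full(lons.shape, np.nan)
    n_missing = 0
    for i, (lon, lat) in enumerate(zip(lons, lats)):
        idx = grid.transform.index_of(float(lon), float(lat))
        if idx is not None and grid.mask[idx]:
            out[i] = grid.values[idx]
        else:
            n_missing += 1
    if n_missing:
        logger.warning(
            "%d point(s) fell on invalid or out-of-grid cells; returned NaN",
            n_missing,
        )
    return out
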