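"""Spherical-grid bookkeeping: cell areas, point-count density maps, and
percentile coarsening.

All grids are regular lon/lat grids described by a :class:`GridSpec`.
Cell areas are exact spherical band areas, so latitude weighting is
handled without any small-angle approximation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

EARTH_RADIUS_KM = 6371.0


class OutOfBoundsError(ValueError):
    """Raised when event points fall outside the grid bounds."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"events outside grid bounds at indices {self.indices}")


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid.

    Parameters
    ----------
    resolution : float
        Cell size in degrees (square cells).
    bounds : tuple of float
        ``(lon_min, lon_max, lat_min, lat_max)`` in degrees.
    earth_radius : float
        Sphere radius in km used for cell areas.
    """

    resolution: float
    bounds: tuple[float, float, float, float]
    earth_radius: float = EARTH_RADIUS_KM

    def __post_init__(self):
        lon0, lon1, lat0, lat1 = self.bounds
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (lon0 < lon1 and lat0 < lat1):
            raise ValueError("bounds must be ordered (lon_min < lon_max, lat_min < lat_max)")
        if not (-90.0 <= lat0 < lat1 <= 90.0):
            raise ValueError("latitudes must lie in [-90, 90]")

    @property
    def n_lon(self) -> int:
        lon0, lon1, _, _ = self.bounds
        return int(round((lon1 - lon0) / self.resolution))

    @property
    def n_lat(self) -> int:
        _, _, lat0, lat1 = self.bounds
        return int(round((lat1 - lat0) / self.resolution))

    @property
    def lon_edges(self) -> np.ndarray:
        lon0, lon1, _, _ = self.bounds
        return np.linspace(lon0, lon1, self.n_lon + 1)

    @property
    def lat_edges(self) -> np.ndarray:
        _, _, lat0, lat1 = self.bounds
        return np.linspace(lat0, lat1, self.n_lat + 1)

    @property
    def lon_centers(self) -> np.ndarray:
        e = self.lon_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def lat_centers(self) -> np.ndarray:
        e = self.lat_edges
        return 0.5 * (e[:-1] + e[1:])


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Exact spherical cell areas in km², shape ``(n_lat, n_lon)``.

    Each cell spanning longitudes ``[λ1, λ2]`` and latitudes ``[φ1, φ2]``
    has area ``R²·(λ2−λ1)·(sin φ2 − sin φ1)``, independent of longitude.
    """
    lat_e = np.deg2rad(grid.lat_edges)
    dlam = np.deg2rad(grid.resolution)
    band = grid.earth_radius**2 * dlam * (np.sin(lat_e[1:]) - np.sin(lat_e[:-1]))
    return np.repeat(band[:, None], grid.n_lon, axis=1)


def point_cell_indices(grid: GridSpec, lons, lats) -> tuple[np.ndarray, np.ndarray]:
    """Map points to (row, col) cell indices with half-open membership.

    A point on a shared edge belongs to the cell to its east/north; a
    point at or beyond the upper bounds is out of range.

    Raises
    ------
    OutOfBoundsError
        listing the offending point indices.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    lon0, lon1, lat0, lat1 = grid.bounds
    cols = np.floor((lons - lon0) / grid.resolution).astype(int)
    rows = np.floor((lats - lat0) / grid.resolution).astype(int)
    bad = (lons < lon0) | (lons >= lon1) | (lats < lat0) | (lats >= lat1)
    if bad.any():
        raise OutOfBoundsError(np.flatnonzero(bad))
    return rows, cols


def grid_density_map(events, grid: GridSpec):
    """Count events per cell and convert to density per 10,000 km².

    Parameters
    ----------
    events : EventSet
        Windthrow points; all must lie within the grid bounds.
    grid : GridSpec

    Returns
    -------
    counts : ndarray of int, shape (n_lat, n_lon)
    density : ndarray of float
        ``counts / area × 10⁴`` (events per 10,000 km²).
    """
    rows, cols = point_cell_indices(grid, events.lons, events.lats)
    counts = np.zeros((grid.n_lat, grid.n_lon), dtype=int)
    np.add.at(counts, (rows, cols), 1)
    density = counts / cell_areas(grid) * 1.0e4
    return counts, density


def aggregate_percentile(field, grid: GridSpec, q: float = 90.0) -> np.ndarray:
    """Coarsen a fine CAPE field to ``grid`` by a per-cell percentile.

    For each coarse cell the q-th percentile (linear interpolation between
    order statistics) of the contained fine-cell values is returned.
    Coarse cells containing no valid fine cell are NaN.
    """
    if not 0.0 <= q <= 100.0:
        raise ValueError("q must be a percent in [0, 100]")
    rows, cols = point_cell_indices(
        grid,
        np.repeat(field.lons[None, :], field.values.shape[0], axis=0).ravel(),
        np.repeat(field.lats[:, None], field.values.shape[1], axis=1).ravel(),
    )
    vals = np.where(field.mask, field.values, np.nan).ravel()
    out = np.full((grid.n_lat, grid.n_lon), np.nan)
    flat = rows * grid.n_lon + cols
    order = np.argsort(flat, kind="stable")
    flat, vals = flat[order], vals[order]
    starts = np.searchsorted(flat, np.arange(grid.n_lat * grid.n_lon))
    ends = np.searchsorted(flat, np.arange(grid.n_lat * grid.n_lon), side="right")
    for k, (a, b) in enumerate(zip(starts, ends)):
        chunk = vals[a:b]
        chunk = chunk[np.isfinite(chunk)]
        if chunk.size:
            out[k // grid.n_lon, k % grid.n_lon] = np.percentile(chunk, q)
    return out
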