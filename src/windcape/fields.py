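"""Georeferenced CAPE rasters.

:class:`CapeField` is the package's in-memory raster container: a 2-D
array of CAPE values (J kg⁻¹) on a regular lon/lat grid with per-cell
spherical areas and an in-region mask. Missing cells are NaN.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grids import GridSpec, cell_areas


class GridMismatchError(ValueError):
    """Two fields expected on the same grid are not co-registered."""


@dataclasses.dataclass
class CapeField:
    """A raster of CAPE (J kg⁻¹) with grid metadata.

    Attributes
    ----------
    values : ndarray, shape (n_lat, n_lon)
        CAPE in J kg⁻¹; NaN marks missing cells.
    lats, lons : ndarray
        Cell-center coordinates in degrees.
    cell_areas : ndarray, shape (n_lat, n_lon)
        Cell areas in km².
    mask : ndarray of bool
        True for cells inside the study region.
    provenance : str
        Free-text label, e.g. ``"reanalysis-current"`` or ``"scaled-future"``.
    """

    values: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    cell_areas: np.ndarray
    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.cell_areas = np.asarray(self.cell_areas, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = (self.lats.size, self.lons.size)
        for name in ("values", "cell_areas", "mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if (self.cell_areas <= 0).any():
            raise ValueError("cell areas must be positive")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError("CAPE values must be non-negative or NaN")

    @classmethod
    def from_grid(cls, grid: GridSpec, values, mask=None, provenance: str = "") -> "CapeField":
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.ones_like(values, dtype=bool)
        return cls(
            values=values,
            lats=grid.lat_centers,
            lons=grid.lon_centers,
            cell_areas=cell_areas(grid),
            mask=mask,
            provenance=provenance,
        )

    @property
    def valid(self) -> np.ndarray:
        """In-region cells with a finite CAPE value."""
        return self.mask & np.isfinite(self.values)

    @property
    def region_area(self) -> float:
        """Total area (km²) of valid in-region cells."""
        return float(self.cell_areas[self.valid].sum())

    def like(self, values, provenance: str | None = None) -> "CapeField":
        """A new field on this grid with different values."""
        return CapeField(
            values=np.asarray(values, dtype=float),
            lats=self.lats,
            lons=self.lons,
            cell_areas=self.cell_areas,
            mask=self.mask,
            provenance=self.provenance if provenance is None else provenance,
        )

    def check_aligned(self, other: "CapeField") -> None:
        if (
            self.values.shape != other.values.shape
            or not np.allclose(self.lats, other.lats)
            or not np.allclose(self.lons, other.lons)
        ):
            raise GridMismatchError("fields are not on the same grid")
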