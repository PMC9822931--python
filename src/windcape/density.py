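"""Non-parametric look-up table linking CAPE to windthrow density.

The model is a step function fitted by equal-count binning: CAPE values
at the observed windthrow locations are sorted and split into groups of
(nearly) equal size, the interior bin edges are placed between adjacent
groups, and the outermost edges are extended to 0 and +∞ under the
assumption that windthrow density is similar for neighbouring CAPE
values. Each bin's density is its event count divided by the area of the
region whose CAPE falls in that bin, expressed per 10,000 km². Bootstrap
resampling of the events (bin edges held fixed) gives per-bin standard
deviations, and the maximal-contrast interior edge defines the
storm-favorable CAPE threshold.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .fields import CapeField


class OutOfRegionError(ValueError):
    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"events outside the field's masked extent at indices {self.indices}")


class UnderdeterminedModelError(ValueError):
    """Fewer events than bins."""


class UndefinedRatioError(ZeroDivisionError):
    """Density ratio undefined (zero events or area on one side)."""


class TieWarning(UserWarning):
    """Tied CAPE values prevented an exact equal-count split."""


class NoThresholdWarning(UserWarning):
    """Density profile is flat; no contrast-maximising edge exists."""


@dataclasses.dataclass
class EventSet:
    """Windthrow point records.

    ``lons``/``lats`` are event coordinates in degrees; ``sizes`` (m²)
    and ``years`` are optional per-event attributes.
    """

    lons: np.ndarray
    lats: np.ndarray
    sizes: np.ndarray | None = None
    years: np.ndarray | None = None

    def __post_init__(self):
        self.lons = np.atleast_1d(np.asarray(self.lons, dtype=float))
        self.lats = np.atleast_1d(np.asarray(self.lats, dtype=float))
        if self.lons.shape != self.lats.shape:
            raise ValueError("lons and lats must have the same length")

    @property
    def n(self) -> int:
        return self.lons.size


@dataclasses.dataclass
class DensityModel:
    """Fitted CAPE → windthrow-density step function.

    ``bin_edges`` has length ``n_bins + 1`` with first edge 0 and last
    +∞; bins are left-closed, right-open. Densities are events per
    10,000 km². ``threshold`` is the storm-favorable CAPE cutoff
    (J kg⁻¹), None until set.
    """

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    bin_areas: np.ndarray
    bin_density: np.ndarray
    bootstrap_sd: np.ndarray | None = None
    threshold: float | None = None

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        self.bin_areas = np.asarray(self.bin_areas, dtype=float)
        self.bin_density = np.asarray(self.bin_density, dtype=float)
        if (np.diff(self.bin_edges) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def n_events(self) -> int:
        return int(self.bin_counts.sum())


def sample_cape_at_points(field: CapeField, events: EventSet) -> np.ndarray:
    """CAPE of the grid cell containing each event (nearest cell center).

    Order is preserved. Events outside the field's valid masked extent
    raise :class:`OutOfRegionError` listing the offending indices.
    """
    iy = np.abs(events.lats[:, None] - field.lats[None, :]).argmin(axis=1)
    ix = np.abs(events.lons[:, None] - field.lons[None, :]).argmin(axis=1)
    res_lat = np.median(np.abs(np.diff(field.lats))) if field.lats.size > 1 else np.inf
    res_lon = np.median(np.abs(np.diff(field.lons))) if field.lons.size > 1 else np.inf
    inside = (
        (np.abs(events.lats - field.lats[iy]) <= 0.5 * res_lat + 1e-9)
        & (np.abs(events.lons - field.lons[ix]) <= 0.5 * res_lon + 1e-9)
        & field.valid[iy, ix]
    )
    if not inside.all():
        raise OutOfRegionError(np.flatnonzero(~inside))
    return field.values[iy, ix]


def _bin_index(edges: np.ndarray, cape) -> np.ndarray:
    """Left-closed right-open bin membership; final bin closed at +∞."""
    idx = np.searchsorted(edges, np.asarray(cape, dtype=float), side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def bin_region_areas(field: CapeField, edges: np.ndarray) -> np.ndarray:
    """Area (km²) of valid region cells whose CAPE falls in each bin."""
    valid = field.valid
    idx = _bin_index(edges, field.values[valid])
    areas = np.zeros(edges.size - 1)
    np.add.at(areas, idx, field.cell_areas[valid])
    return areas


def fit_density_model(event_capes, field: CapeField, n_bins: int = 6) -> DensityModel:
    """Fit the equal-count binned density model.

    Events are sorted by CAPE and split into ``n_bins`` groups whose
    sizes differ by at most one (larger groups first); interior edges
    are midpoints between adjacent groups' extreme values, and the outer
    edges are 0 and +∞. Ties straddling a group boundary can make the
    exact equal split impossible; the realised counts are then reported
    via :class:`TieWarning`.
    """
    capes = np.sort(np.asarray(event_capes, dtype=float))
    n = capes.size
    if n < n_bins:
        raise UnderdeterminedModelError(f"{n} events cannot fill {n_bins} bins")
    if (capes < 0).any() or not np.isfinite(capes).all():
        raise ValueError("event CAPE values must be finite and non-negative")

    base, rem = divmod(n, n_bins)
    sizes = np.array([base + 1] * rem + [base] * (n_bins - rem))
    splits = np.cumsum(sizes)[:-1]
    interior = 0.5 * (capes[splits - 1] + capes[splits])
    edges = np.concatenate([[0.0], interior, [np.inf]])
    if (np.diff(edges) <= 0).any():
        raise ValueError("degenerate bin edges: too many tied CAPE values")

    counts = np.bincount(_bin_index(edges, capes), minlength=n_bins)
    if counts.max() - counts.min() > 1:
        warnings.warn(
            f"tied CAPE values at a bin edge; realised counts {counts.tolist()}",
            TieWarning,
            stacklevel=2,
        )
    areas = bin_region_areas(field, edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(areas > 0, counts / areas * 1.0e4, np.nan)
    return DensityModel(edges, counts, areas, density)


def predict_density(model: DensityModel, cape) -> np.ndarray | float:
    """Step-function lookup: density of the bin containing ``cape``.

    Defined on [0, ∞); CAPE beyond the largest observed value returns
    the last bin's density (the conservative upper extension).
    """
    arr = np.asarray(cape, dtype=float)
    if (arr < 0).any():
        raise ValueError("CAPE must be non-negative")
    out = model.bin_density[_bin_index(model.bin_edges, arr)]
    return float(out) if np.isscalar(cape) or arr.ndim == 0 else out


def bootstrap_density_sd(
    event_capes, model: DensityModel, n_boot: int = 10_000, seed: int | None = None
) -> np.ndarray:
    """Per-bin bootstrap SD of windthrow density, bin edges held fixed.

    Resamples the n events with replacement ``n_boot`` times and
    recounts against the fitted edges. Because edges are fixed, the
    replicate bin counts are exactly multinomial(n, p̂) draws, which is
    how they are generated (vectorised). Reproducible given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    capes = np.asarray(event_capes, dtype=float)
    n = capes.size
    p_hat = np.bincount(_bin_index(model.bin_edges, capes), minlength=model.n_bins) / n
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p_hat, size=n_boot)
    densities = counts / model.bin_areas * 1.0e4
    sd = densities.std(axis=0, ddof=1)
    model.bootstrap_sd = sd
    return sd


def favorable_threshold(model: DensityModel) -> float:
    """Storm-favorable CAPE cutoff: the maximal-contrast interior edge.

    Each interior edge splits the bins into a low and a high side; the
    edge maximising (events above / area above) ÷ (events below / area
    below) is returned and stored on the model. A flat density profile
    triggers :class:`NoThresholdWarning` and returns the lowest interior
    edge.
    """
    k = model.n_bins
    ratios = np.empty(k - 1)
    for i in range(1, k):
        lo = model.bin_counts[:i].sum() / model.bin_areas[:i].sum()
        hi = model.bin_counts[i:].sum() / model.bin_areas[i:].sum()
        ratios[i - 1] = np.inf if lo == 0 else hi / lo
    if np.allclose(ratios, ratios[0]):
        if np.isclose(ratios[0], 1.0):
            warnings.warn("flat density profile; no contrast-maximising edge",
                          NoThresholdWarning, stacklevel=2)
        best = 0
    else:
        best = int(np.argmax(ratios))
    model.threshold = float(model.bin_edges[best + 1])
    return model.threshold


def density_ratio(model: DensityModel, threshold: float) -> float:
    """Fold ratio of windthrow density above vs below ``threshold``.

    Events and areas are aggregated from the fitted bins split at the
    threshold: (events above / area above) ÷ (events below / area
    below). A threshold strictly inside a finite bin splits that bin's
    count and area proportionally (uniform-within-bin assumption); a
    threshold inside the unbounded last bin is not supported.
    """
    edges = model.bin_edges
    if not edges[0] < threshold < edges[-1]:
        raise UndefinedRatioError("threshold outside the model's CAPE domain")
    counts = model.bin_counts.astype(float)
    areas = model.bin_areas.astype(float)
    j = int(np.searchsorted(edges, threshold, side="left")) - 1
    below_c, below_a = counts[: j + 1].sum(), areas[: j + 1].sum()
    above_c, above_a = counts[j + 1 :].sum(), areas[j + 1 :].sum()
    if not np.isclose(threshold, edges[j + 1]):
        lo, hi = edges[j], edges[j + 1]
        if not np.isfinite(hi):
            raise UndefinedRatioError("threshold inside the unbounded last bin")
        frac = (threshold - lo) / (hi - lo)  # fraction of bin j below the threshold
        below_c -= counts[j] * (1.0 - frac)
        below_a -= areas[j] * (1.0 - frac)
        above_c += counts[j] * (1.0 - frac)
        above_a += areas[j] * (1.0 - frac)
    if below_c == 0 or below_a == 0 or above_a == 0:
        raise UndefinedRatioError("zero events or area on one side of the threshold")
    return float((above_c / above_a) / (below_c / below_a))
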