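"""Delta-change scaling of ESM futures and windthrow projections.

Because reanalysis and ESM CAPE products are computed with different
parcel algorithms, their absolute values are not comparable. Each ESM's
fractional change

    delta = (CAPE_future − CAPE_current) / CAPE_current

is therefore applied grid-wise to the observational baseline,

    CAPE_scaled_future = (1 + delta) · CAPE_baseline_current ,

and projections are read off the scaled field: the change in area with
CAPE above the storm-favorable threshold, and the change in the expected
windthrow total Σ_cells density(CAPE) · area / 10⁴ under the fitted
density model. Ensemble means and sample standard deviations summarise
the model spread.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .density import DensityModel, predict_density
from .fields import CapeField


class UndefinedIncreaseError(ZeroDivisionError):
    """Percentage increase undefined (zero current area or event total)."""


class EmptyFieldError(ValueError):
    """Field has no valid in-region cells."""


class NegativeCapeError(ValueError):
    """A fractional delta below −1 would produce negative CAPE."""


class EmptyEnsembleError(ValueError):
    """No projection results to summarise."""


@dataclasses.dataclass
class ProjectionResult:
    """Per-ESM projection on the scaled baseline."""

    model_name: str
    delta_field: np.ndarray
    scaled_future: CapeField
    favorable_area_current: float
    favorable_area_future: float
    area_increase_pct: float
    density_increase_pct: float


@dataclasses.dataclass
class EnsembleSummary:
    per_model: list[ProjectionResult]
    mean_area_increase: float
    sd_area_increase: float
    mean_density_increase: float
    sd_density_increase: float


def delta_cape(current_cmip: CapeField, future_cmip: CapeField, floor: float = 1.0) -> np.ndarray:
    """Fractional CAPE change (future − current)/current, per cell.

    Cells whose current CAPE is below ``floor`` (J kg⁻¹) are NaN rather
    than divided — the delta is meaningless against a near-zero
    baseline.
    """
    current_cmip.check_aligned(future_cmip)
    cur, fut = current_cmip.values, future_cmip.values
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(cur >= floor, (fut - cur) / cur, np.nan)
    return delta


def scale_future_cape(delta: np.ndarray, era5_current: CapeField) -> CapeField:
    """Scaled future field (1 + delta)·baseline, labelled scaled-future."""
    delta = np.asarray(delta, dtype=float)
    if delta.shape != era5_current.values.shape:
        raise ValueError("delta field shape does not match the baseline grid")
    if np.nanmin(delta, initial=0.0) < -1.0:
        raise NegativeCapeError("delta < -1 would give negative CAPE")
    return era5_current.like((1.0 + delta) * era5_current.values, provenance="scaled-future")


def favorable_area(field: CapeField, threshold: float) -> float:
    """Area (km²) of in-region cells with CAPE strictly above threshold."""
    valid = field.valid
    if not valid.any():
        raise EmptyFieldError("field has no valid in-region cells")
    return float(field.cell_areas[valid & (field.values > threshold)].sum())


def favorable_area_increase(current: CapeField, future: CapeField, threshold: float) -> float:
    """Percent increase in storm-favorable area, 100·(A_fut − A_cur)/A_cur."""
    current.check_aligned(future)
    a_cur = favorable_area(current, threshold)
    if a_cur == 0.0:
        raise UndefinedIncreaseError("no current favorable area")
    return 100.0 * (favorable_area(future, threshold) - a_cur) / a_cur


def expected_event_total(model: DensityModel, field: CapeField) -> float:
    """Expected windthrow count Σ density(CAPE)·area/10⁴ over the region."""
    valid = field.valid
    dens = predict_density(model, field.values[valid])
    return float((dens * field.cell_areas[valid]).sum() / 1.0e4)


def project_density_increase(model: DensityModel, current: CapeField, future: CapeField) -> float:
    """Percent increase in the expected windthrow total under ``model``.

    Both totals are computed the same way — from the model's prediction
    on the respective field — so the increase isolates the CAPE shift.
    """
    current.check_aligned(future)
    n_cur = expected_event_total(model, current)
    if n_cur == 0.0:
        raise UndefinedIncreaseError("expected current windthrow total is zero")
    return 100.0 * (expected_event_total(model, future) - n_cur) / n_cur


def project_model(
    name: str,
    current_cmip: CapeField,
    future_cmip: CapeField,
    baseline: CapeField,
    model: DensityModel,
    threshold: float,
    floor: float = 1.0,
) -> ProjectionResult:
    """Full per-ESM projection: delta, scaling, area and density change."""
    delta = delta_cape(current_cmip, future_cmip, floor=floor)
    scaled = scale_future_cape(np.nan_to_num(delta, nan=0.0), baseline)
    return ProjectionResult(
        model_name=name,
        delta_field=delta,
        scaled_future=scaled,
        favorable_area_current=favorable_area(baseline, threshold),
        favorable_area_future=favorable_area(scaled, threshold),
        area_increase_pct=favorable_area_increase(baseline, scaled, threshold),
        density_increase_pct=project_density_increase(model, baseline, scaled),
    )


def ensemble_summary(results: list[ProjectionResult]) -> EnsembleSummary:
    """Ensemble mean and sample SD (ddof=1) of the percentage increases.

    Percentages are carried at full precision; rounding to integers is a
    report-time concern only.
    """
    if not results:
        raise EmptyEnsembleError("no projection results")
    area = np.array([r.area_increase_pct for r in results])
    dens = np.array([r.density_increase_pct for r in results])
    sd_area = float(area.std(ddof=1)) if area.size > 1 else np.nan
    sd_dens = float(dens.std(ddof=1)) if dens.size > 1 else np.nan
    return EnsembleSummary(
        per_model=list(results),
        mean_area_increase=float(area.mean()),
        sd_area_increase=sd_area,
        mean_density_increase=float(dens.mean()),
        sd_density_increase=sd_dens,
    )
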