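"""Readers and writers for the pipeline's on-disk formats.

Rasters travel as CF-style NetCDF (lat/lon coordinates, explicit fill
value); events as CSV ``lon,lat[,size_m2,year]`` or GeoJSON points;
fitted density models and projection summaries as JSON; region polygons
as GeoJSON. Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .density import DensityModel, EventSet
from .fields import CapeField
from .projection import EnsembleSummary, ProjectionResult

FILL_VALUE = -9999.0


# ---------------------------------------------------------------- rasters

def write_cape_field(field: CapeField, path) -> None:
    ds = xr.Dataset(
        {
            "cape": (("lat", "lon"), field.values),
            "cell_area": (("lat", "lon"), field.cell_areas),
            "region_mask": (("lat", "lon"), field.mask.astype(np.int8)),
        },
        coords={"lat": field.lats, "lon": field.lons},
        attrs={"provenance": field.provenance},
    )
    ds["cape"].attrs["units"] = "J kg-1"
    ds["cell_area"].attrs["units"] = "km2"
    ds.to_netcdf(path, engine="scipy", encoding={"cape": {"_FillValue": FILL_VALUE}})


def read_cape_field(path) -> CapeField:
    with xr.open_dataset(path, engine="scipy") as ds:
        return CapeField(
            values=ds["cape"].values,
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            cell_areas=ds["cell_area"].values,
            mask=ds["region_mask"].values.astype(bool),
            provenance=str(ds.attrs.get("provenance", "")),
        )


def write_hourly_stack(fields: list[tuple[object, CapeField]], path) -> None:
    """Write timestamped hourly fields as one NetCDF with a time axis."""
    times, stack = zip(*fields)
    first = stack[0]
    ds = xr.Dataset(
        {
            "cape": (("time", "lat", "lon"), np.stack([f.values for f in stack])),
            "cell_area": (("lat", "lon"), first.cell_areas),
            "region_mask": (("lat", "lon"), first.mask.astype(np.int8)),
        },
        coords={"time": list(times), "lat": first.lats, "lon": first.lons},
    )
    ds.to_netcdf(path, engine="scipy", encoding={"cape": {"_FillValue": FILL_VALUE}})


def read_hourly_stack(path) -> list[tuple[object, CapeField]]:
    with xr.open_dataset(path, engine="scipy") as ds:
        times = pd.to_datetime(ds["time"].values)
        area = ds["cell_area"].values
        mask = ds["region_mask"].values.astype(bool)
        return [
            (
                ts,
                CapeField(ds["cape"].values[i], ds["lat"].values, ds["lon"].values, area, mask),
            )
            for i, ts in enumerate(times)
        ]


# ----------------------------------------------------------------- events

def write_events_csv(events: EventSet, path) -> None:
    data = {"lon": events.lons, "lat": events.lats}
    if events.sizes is not None:
        data["size_m2"] = events.sizes
    if events.years is not None:
        data["year"] = events.years
    pd.DataFrame(data).to_csv(path, index=False)


def read_events_csv(path) -> EventSet:
    df = pd.read_csv(path)
    return EventSet(
        lons=df["lon"].to_numpy(),
        lats=df["lat"].to_numpy(),
        sizes=df["size_m2"].to_numpy() if "size_m2" in df else None,
        years=df["year"].to_numpy() if "year" in df else None,
    )


def write_events_geojson(events: EventSet, path) -> None:
    features = []
    for i in range(events.n):
        props = {}
        if events.sizes is not None:
            props["size_m2"] = float(events.sizes[i])
        if events.years is not None:
            props["year"] = int(events.years[i])
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(events.lons[i]), float(events.lats[i])],
                },
                "properties": props,
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_events_geojson(path) -> EventSet:
    gj = json.loads(Path(path).read_text())
    lons, lats, sizes, years = [], [], [], []
    for feat in gj["features"]:
        lon, lat = feat["geometry"]["coordinates"][:2]
        lons.append(lon)
        lats.append(lat)
        props = feat.get("properties") or {}
        sizes.append(props.get("size_m2", np.nan))
        years.append(props.get("year", np.nan))
    sizes_arr = np.asarray(sizes, dtype=float)
    years_arr = np.asarray(years, dtype=float)
    return EventSet(
        lons=np.asarray(lons, dtype=float),
        lats=np.asarray(lats, dtype=float),
        sizes=None if np.isnan(sizes_arr).all() else sizes_arr,
        years=None if np.isnan(years_arr).all() else years_arr,
    )


def read_region_polygon(path):
    """First polygon geometry from a GeoJSON file, as a shapely Polygon."""
    from shapely.geometry import shape

    gj = json.loads(Path(path).read_text())
    geoms = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    for feat in geoms:
        geom = feat.get("geometry", feat)
        if geom["type"] in ("Polygon", "MultiPolygon"):
            return shape(geom)
    raise ValueError("no polygon geometry found")


def apply_region_mask(field: CapeField, polygon) -> CapeField:
    """Restrict a field's mask to cells whose centers fall in ``polygon``."""
    from shapely import contains_xy

    lon2, lat2 = np.meshgrid(field.lons, field.lats)
    inside = contains_xy(polygon, lon2, lat2)
    out = field.like(field.values)
    out.mask = field.mask & inside
    return out


# ------------------------------------------------------------ model JSON

def density_model_to_json(model: DensityModel, path) -> None:
    edges = [None if not np.isfinite(e) else float(e) for e in model.bin_edges]
    payload = {
        "bin_edges": edges,
        "bin_counts": model.bin_counts.tolist(),
        "bin_areas": model.bin_areas.tolist(),
        "bin_density": model.bin_density.tolist(),
        "bootstrap_sd": None if model.bootstrap_sd is None else model.bootstrap_sd.tolist(),
        "threshold": model.threshold,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def density_model_from_json(path) -> DensityModel:
    d = json.loads(Path(path).read_text())
    edges = np.array([np.inf if e is None else e for e in d["bin_edges"]], dtype=float)
    model = DensityModel(
        bin_edges=edges,
        bin_counts=np.asarray(d["bin_counts"]),
        bin_areas=np.asarray(d["bin_areas"]),
        bin_density=np.asarray(d["bin_density"]),
        threshold=d.get("threshold"),
    )
    if d.get("bootstrap_sd") is not None:
        model.bootstrap_sd = np.asarray(d["bootstrap_sd"], dtype=float)
    return model


# --------------------------------------------------------------- reports

def ensemble_to_json(summary: EnsembleSummary, path) -> None:
    payload = {
        "per_model": [
            {
                "model": r.model_name,
                "area_increase_pct": r.area_increase_pct,
                "density_increase_pct": r.density_increase_pct,
                "favorable_area_current_km2": r.favorable_area_current,
                "favorable_area_future_km2": r.favorable_area_future,
            }
            for r in summary.per_model
        ],
        "mean_area_increase_pct": summary.mean_area_increase,
        "sd_area_increase_pct": summary.sd_area_increase,
        "mean_density_increase_pct": summary.mean_density_increase,
        "sd_density_increase_pct": summary.sd_density_increase,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def ensemble_report_csv(summary: EnsembleSummary, path) -> pd.DataFrame:
    """Table-style per-model report with integer rounding (report-time only)."""
    rows = [
        {
            "model": r.model_name,
            "area_increase_pct": int(round(r.area_increase_pct)),
            "density_increase_pct": int(round(r.density_increase_pct)),
        }
        for r in summary.per_model
    ]
    rows.append(
        {
            "model": "ensemble_mean",
            "area_increase_pct": int(round(summary.mean_area_increase)),
            "density_increase_pct": int(round(summary.mean_density_increase)),
        }
    )
    rows.append(
        {
            "model": "one_standard_deviation",
            "area_increase_pct": int(round(summary.sd_area_increase)),
            "density_increase_pct": int(round(summary.sd_density_increase)),
        }
    )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def projection_result_to_json(result: ProjectionResult, path) -> None:
    payload = {
        "model": result.model_name,
        "area_increase_pct": result.area_increase_pct,
        "density_increase_pct": result.density_increase_pct,
        "favorable_area_current_km2": result.favorable_area_current,
        "favorable_area_future_km2": result.favorable_area_future,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
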