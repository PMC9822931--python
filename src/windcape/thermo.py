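"""Nondilute near-surface-parcel CAPE.

The convective available potential energy of a near-surface parcel is
computed as a discrete buoyancy sum over fixed pressure levels:

    CAPE = Σᵢ dp · H(bᵢ) · bᵢ ,   bᵢ = 1/ρᵢ − 1/ρ_{e,i}

where ρᵢ is the parcel density after adiabatic ascent to level i, ρ_{e,i}
the environmental density at that level, H the Heaviside step function
(H(0) = 0 here: zero buoyancy contributes nothing), and dp the level
spacing. With dp in Pa and b in m³ kg⁻¹ the sum is in J kg⁻¹.

The parcel ascends dry-adiabatically from the surface to its lifting
condensation level (LCL) and pseudo-adiabatically above it (condensate
removed on formation; no entrainment). Densities use the ideal-gas law
with virtual temperature; condensate loading is ignored, consistent with
pseudo-adiabatic removal. Saturation vapour pressure follows Bolton's
empirical formula by default.

Levels below ground (pressure greater than the surface pressure) are
skipped rather than extrapolated, as are levels outside the range of the
supplied environmental profile.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np

# Thermodynamic constants (SI)
RD = 287.04  # gas constant of dry air, J kg⁻¹ K⁻¹
CPD = 1005.7  # isobaric heat capacity of dry air, J kg⁻¹ K⁻¹
LV = 2.501e6  # latent heat of vaporisation, J kg⁻¹ (held constant)
EPS = 0.622  # Rd/Rv
KAPPA = RD / CPD


class InvalidInputError(ValueError):
    """Non-finite or physically impossible profile inputs."""


class InsufficientProfileError(ValueError):
    """Fewer than two usable pressure levels for the buoyancy sum."""


class EmptySelectionError(ValueError):
    """A temporal selection matched no fields."""


def saturation_vapor_pressure(temperature_k, formula: str = "bolton"):
    """Saturation vapour pressure over liquid water, Pa.

    ``"bolton"`` — Bolton's empirical fit (accurate −35…35 °C);
    ``"tetens"`` — classic Tetens formula, kept for sensitivity checks.
    """
    tc = np.asarray(temperature_k, dtype=float) - 273.15
    if formula == "bolton":
        return 611.2 * np.exp(17.67 * tc / (tc + 243.5))
    if formula == "tetens":
        return 610.78 * np.exp(17.27 * tc / (tc + 237.3))
    raise ValueError(f"unknown saturation formula {formula!r}")


def saturation_mixing_ratio(pressure_pa, temperature_k, formula: str = "bolton"):
    """Saturation water-vapour mixing ratio, kg kg⁻¹."""
    es = saturation_vapor_pressure(temperature_k, formula)
    es = np.minimum(es, 0.9 * np.asarray(pressure_pa, dtype=float))
    return EPS * es / (pressure_pa - es)


def specific_humidity_to_mixing_ratio(q):
    return np.asarray(q, dtype=float) / (1.0 - np.asarray(q, dtype=float))


def virtual_temperature(temperature_k, mixing_ratio):
    """Virtual temperature Tv = T·(1 + r/ε)/(1 + r)."""
    r = np.asarray(mixing_ratio, dtype=float)
    return np.asarray(temperature_k, dtype=float) * (1.0 + r / EPS) / (1.0 + r)


def air_density(pressure_pa, temperature_k, mixing_ratio=0.0):
    """Moist-air density from the ideal-gas law with virtual temperature."""
    return np.asarray(pressure_pa, dtype=float) / (
        RD * virtual_temperature(temperature_k, mixing_ratio)
    )


@dataclasses.dataclass(frozen=True)
class CapeConfig:
    """Discretisation and scheme choices for the CAPE sum.

    ``dp`` is the level spacing in Pa (default 10 kPa) and ``levels`` the
    target pressures, defaulting to 100 kPa down to 10 kPa in 10 kPa
    increments. ``max_step`` bounds the internal pseudo-adiabatic
    integration step (Pa).
    """

    dp: float = 1.0e4
    levels: tuple[float, ...] = tuple(np.arange(100000.0, 9999.0, -10000.0))
    saturation_formula: str = "bolton"
    zero_buoyancy_positive: bool = False  # H(0): False → contributes zero
    max_step: float = 100.0

    def __post_init__(self):
        if self.dp <= 0:
            raise ValueError("dp must be positive")
        lv = np.asarray(self.levels, dtype=float)
        if lv.size < 2 or (np.diff(lv) >= 0).any():
            raise ValueError("levels must be strictly decreasing pressures")

    @classmethod
    def with_dp(cls, dp: float, p_top: float = 1.0e4, p_bottom: float = 1.0e5, **kw) -> "CapeConfig":
        """Levels from ``p_bottom`` down to ``p_top`` with spacing ``dp``."""
        levels = tuple(np.arange(p_bottom, p_top - 0.5 * dp, -dp))
        return cls(dp=dp, levels=levels, **kw)


@dataclasses.dataclass
class AtmosphericProfile:
    """Environmental state plus the near-surface parcel source.

    Pressures in Pa (strictly decreasing from the surface), temperatures
    in K, humidities as specific humidity in kg kg⁻¹. ``env_humidity`` is
    optional: without it the environment is treated as dry air for the
    density calculation.
    """

    pressure_levels: np.ndarray
    env_temperature: np.ndarray
    surface_pressure: float
    surface_temperature: float
    surface_humidity: float
    env_humidity: np.ndarray | None = None

    def __post_init__(self):
        self.pressure_levels = np.asarray(self.pressure_levels, dtype=float)
        self.env_temperature = np.asarray(self.env_temperature, dtype=float)
        if self.env_humidity is not None:
            self.env_humidity = np.asarray(self.env_humidity, dtype=float)
        self._validate()

    def _validate(self):
        p, t = self.pressure_levels, self.env_temperature
        scalars = (self.surface_pressure, self.surface_temperature, self.surface_humidity)
        if not (np.isfinite(p).all() and np.isfinite(t).all() and np.isfinite(scalars).all()):
            raise InvalidInputError("profile contains non-finite values")
        if p.ndim != 1 or p.shape != t.shape:
            raise InvalidInputError("pressure and temperature levels must be 1-D and congruent")
        if (np.diff(p) >= 0).any():
            raise InvalidInputError("pressure_levels must be strictly decreasing")
        if (t <= 0).any() or self.surface_temperature <= 0:
            raise InvalidInputError("temperatures must be positive")
        for q in ([self.surface_humidity] if self.env_humidity is None
                  else [self.surface_humidity, *np.atleast_1d(self.env_humidity)]):
            if not 0.0 <= q < 0.1:
                raise InvalidInputError("specific humidities must lie in [0, 0.1)")


@dataclasses.dataclass
class ParcelState:
    """Thermodynamic state of the lifted parcel at one pressure level."""

    pressure: float
    temperature: float
    vapor_mixing: float
    density: float
    buoyancy_term: float  # 1/ρ_parcel − 1/ρ_env, m³ kg⁻¹
    below_ground: bool = False


def lifting_condensation_level(
    surface_pressure: float,
    surface_temperature: float,
    surface_humidity: float,
    formula: str = "bolton",
) -> tuple[float, float]:
    """LCL pressure (Pa) and temperature (K) of the surface parcel.

    Uses Bolton's LCL-temperature formula with the dry adiabat for the
    pressure. A dry parcel (q = 0) never condenses; (0, 0) is returned so
    every finite pressure lies below the LCL.
    """
    if surface_humidity <= 0.0:
        return 0.0, 0.0
    r = specific_humidity_to_mixing_ratio(surface_humidity)
    e = surface_pressure * r / (EPS + r)  # vapour pressure, Pa
    t_lcl = 2840.0 / (3.5 * np.log(surface_temperature) - np.log(e / 100.0) - 4.805) + 55.0
    if t_lcl >= surface_temperature:  # already saturated at the surface
        return surface_pressure, surface_temperature
    p_lcl = surface_pressure * (t_lcl / surface_temperature) ** (1.0 / KAPPA)
    return float(p_lcl), float(t_lcl)


def _pseudoadiabatic_lapse(pressure, temperature, formula):
    """dT/dp along the pseudo-adiabat (condensate removed), K Pa⁻¹."""
    rs = saturation_mixing_ratio(pressure, temperature, formula)
    num = RD * temperature + LV * rs
    den = pressure * (CPD + LV**2 * rs * EPS / (RD * temperature**2))
    return num / den


def parcel_profile(
    profile: AtmosphericProfile,
    pressures: Sequence[float],
    config: CapeConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Parcel temperature and vapour mixing ratio at given pressures.

    ``pressures`` must be sorted in descending order and not exceed the
    surface pressure. Below the LCL the dry-adiabat closed form is used;
    above it the pseudo-adiabatic ODE is integrated with fixed-step RK4
    (step ≤ ``config.max_step``).
    """
    config = config or CapeConfig()
    ps, ts = profile.surface_pressure, profile.surface_temperature
    r0 = float(specific_humidity_to_mixing_ratio(profile.surface_humidity))
    p_lcl, t_lcl = lifting_condensation_level(
        ps, ts, profile.surface_humidity, config.saturation_formula
    )

    pressures = np.asarray(pressures, dtype=float)
    temps = np.empty_like(pressures)
    mixing = np.empty_like(pressures)

    dry = pressures >= p_lcl
    temps[dry] = ts * (pressures[dry] / ps) ** KAPPA
    mixing[dry] = r0

    moist_targets = pressures[~dry]
    if moist_targets.size:
        t, p = t_lcl, p_lcl
        out = []
        for p_target in moist_targets:  # descending pressures
            n_steps = max(1, int(np.ceil((p - p_target) / config.max_step)))
            h = (p_target - p) / n_steps  # negative
            for _ in range(n_steps):
                k1 = _pseudoadiabatic_lapse(p, t, config.saturation_formula)
                k2 = _pseudoadiabatic_lapse(p + 0.5 * h, t + 0.5 * h * k1, config.saturation_formula)
                k3 = _pseudoadiabatic_lapse(p + 0.5 * h, t + 0.5 * h * k2, config.saturation_formula)
                k4 = _pseudoadiabatic_lapse(p + h, t + h * k3, config.saturation_formula)
                t += h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                p += h
            out.append(t)
        temps[~dry] = out
        mixing[~dry] = saturation_mixing_ratio(
            moist_targets, np.asarray(out), config.saturation_formula
        )
    return temps, mixing


def environment_density(profile: AtmosphericProfile, pressures) -> np.ndarray:
    """Environmental density interpolated to ``pressures``.

    Temperature (and specific humidity, when provided) is interpolated
    linearly in log pressure; density follows from the ideal-gas law with
    virtual temperature. Pressures outside the profile's range are NaN.
    """
    pressures = np.asarray(pressures, dtype=float)
    x = -np.log(profile.pressure_levels)  # increasing
    xt = -np.log(pressures)
    t_env = np.interp(xt, x, profile.env_temperature, left=np.nan, right=np.nan)
    if profile.env_humidity is not None:
        q_env = np.interp(xt, x, profile.env_humidity, left=np.nan, right=np.nan)
        r_env = specific_humidity_to_mixing_ratio(q_env)
    else:
        r_env = np.zeros_like(t_env)
    return air_density(pressures, t_env, r_env)


def lift_parcel(
    profile: AtmosphericProfile,
    level_pressure: float,
    config: CapeConfig | None = None,
) -> ParcelState:
    """Lift the surface parcel adiabatically to ``level_pressure``.

    Returns the parcel's state including the buoyancy term
    b = 1/ρ_parcel − 1/ρ_env. A level below ground (pressure larger than
    the surface pressure) is flagged ``below_ground`` with NaN buoyancy.
    """
    config = config or CapeConfig()
    if not np.isfinite(level_pressure) or level_pressure <= 0:
        raise InvalidInputError("level_pressure must be finite and positive")
    if level_pressure > profile.surface_pressure:
        return ParcelState(level_pressure, np.nan, np.nan, np.nan, np.nan, below_ground=True)
    temps, mixing = parcel_profile(profile, [level_pressure], config)
    rho = float(air_density(level_pressure, temps[0], mixing[0]))
    rho_e = float(environment_density(profile, [level_pressure])[0])
    b = 1.0 / rho - 1.0 / rho_e if np.isfinite(rho_e) else np.nan
    return ParcelState(float(level_pressure), float(temps[0]), float(mixing[0]), rho, b)


def compute_cape(profile: AtmosphericProfile, config: CapeConfig | None = None) -> float:
    """CAPE (J kg⁻¹) of the near-surface parcel over the configured levels.

    Levels below ground or outside the environmental profile's pressure
    range are excluded from the sum; fewer than two usable levels raises
    :class:`InsufficientProfileError`. Zero and negative buoyancy
    contribute nothing, so the result is non-negative.
    """
    config = config or CapeConfig()
    levels = np.asarray(config.levels, dtype=float)
    usable = levels <= profile.surface_pressure
    rho_e = environment_density(profile, levels)
    usable &= np.isfinite(rho_e)
    if usable.sum() < 2:
        raise InsufficientProfileError(
            f"only {int(usable.sum())} usable level(s) for the buoyancy sum"
        )
    p_use = levels[usable]
    temps, mixing = parcel_profile(profile, p_use, config)
    rho = air_density(p_use, temps, mixing)
    b = 1.0 / rho - 1.0 / rho_e[usable]
    positive = b >= 0.0 if config.zero_buoyancy_positive else b > 0.0
    return float(config.dp * b[positive].sum())


def afternoon_mean_cape(
    hourly_fields: Iterable[tuple["object", "object"]],
    hours_utc: frozenset[int] | set[int] = frozenset(range(17, 24)),
    period: tuple[int, int] | None = None,
):
    """Mean-afternoon CAPE climatology from timestamped hourly fields.

    Parameters
    ----------
    hourly_fields : iterable of (timestamp, CapeField)
        Timestamps must expose ``.hour`` and ``.year`` (datetime-like).
    hours_utc : set of int
        UTC hours to average, default 17:00–23:00 (13:00–19:00 Amazon
        local time).
    period : (first_year, last_year), optional
        Inclusive year range; ``None`` keeps all years.

    Returns
    -------
    CapeField
        Per-cell arithmetic mean over exactly the selected hours; cells
        missing in every selected field stay NaN.
    """
    selected = [
        f
        for ts, f in hourly_fields
        if ts.hour in hours_utc and (period is None or period[0] <= ts.year <= period[1])
    ]
    if not selected:
        raise EmptySelectionError("no fields match the requested hours/period")
    stack = np.stack([f.values for f in selected])
    with np.errstate(invalid="ignore"):
        mean = np.where(np.isfinite(stack).any(axis=0), np.nanmean(stack, axis=0), np.nan)
    return selected[0].like(mean, provenance="mean-afternoon")


def daily_cape_from_esm(ds, config: CapeConfig | None = None):
    """Daily CAPE fields from ESM output (tas, huss, ps, ta on plev).

    ``ds`` is an xarray Dataset with variables ``tas`` (K), ``huss``
    (kg kg⁻¹), ``ps`` (Pa) on dims (time, lat, lon) and ``ta`` (K) on
    (time, plev, lat, lon) with ``plev`` in Pa. Returns a DataArray of
    CAPE (time, lat, lon). Grids/calendars must be shared.
    """
    import xarray as xr

    from .fields import GridMismatchError

    config = config or CapeConfig()
    for v in ("tas", "huss", "ps", "ta"):
        if v not in ds:
            raise GridMismatchError(f"missing variable {v!r}")
    base = ds["tas"].shape
    if ds["huss"].shape != base or ds["ps"].shape != base or ds["ta"].shape[0] != base[0] \
            or ds["ta"].shape[2:] != base[1:]:
        raise GridMismatchError("tas/huss/ps/ta are not co-registered")
    plev = np.asarray(ds["plev"].values, dtype=float)
    order = np.argsort(plev)[::-1]
    nt, ny, nx = base
    out = np.empty(base)
    for it in range(nt):
        for iy in range(ny):
            for ix in range(nx):
                prof = AtmosphericProfile(
                    pressure_levels=plev[order],
                    env_temperature=ds["ta"].values[it, order, iy, ix],
                    surface_pressure=float(ds["ps"].values[it, iy, ix]),
                    surface_temperature=float(ds["tas"].values[it, iy, ix]),
                    surface_humidity=float(ds["huss"].values[it, iy, ix]),
                )
                out[it, iy, ix] = compute_cape(prof, config)
    return xr.DataArray(
        out,
        dims=("time", "lat", "lon"),
        coords={"time": ds["time"], "lat": ds["lat"], "lon": ds["lon"]},
        name="cape",
        attrs={"units": "J kg-1", "long_name": "near-surface parcel CAPE"},
    )
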