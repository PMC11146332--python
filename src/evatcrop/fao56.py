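"""FAO-56 Penman–Monteith daily reference evapotranspiration.

Implements the combination equation for the hypothetical grass reference
surface together with the standard auxiliary relations of Allen et al.
(1998): saturation vapour pressure and its slope, the psychrometric
constant from site elevation, and the daily radiation budget from solar
geometry. ET0 computed here serves as the supervised target for the
quasi-fuzzy neural estimator.

All functions are deterministic, accept scalars or numpy arrays, and use
these units throughout: temperature °C, pressure kPa, wind speed m s⁻¹ at
2 m, radiation MJ m⁻² d⁻¹, ET0 mm d⁻¹.

Note on the combination equation: its radiation term uses the *net*
radiation Rn at the crop surface (shortwave absorbed minus longwave
emitted), computed by :func:`radiation_budget` — not the extraterrestrial
radiation Ra, which only enters as the ceiling of the clear-sky budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .weather import SiteMeta, WeatherRecord, WeatherSeries

#: solar constant, MJ m⁻² min⁻¹
SOLAR_CONSTANT = 0.0820
#: Stefan–Boltzmann constant, MJ K⁻⁴ m⁻² d⁻¹
STEFAN_BOLTZMANN = 4.903e-9
#: grass reference albedo
ALBEDO = 0.23
#: clamp range for the relative shortwave ratio sr/Rso inside net longwave
CLOUDINESS_CLAMP = (0.05, 1.0)


def saturation_vapour_pressure(t):
    """Saturation vapour pressure e°(T) in kPa at air temperature ``t`` °C."""
    t = np.asarray(t, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def svp_slope(t):
    """Slope Δ of the saturation vapour-pressure curve, kPa °C⁻¹."""
    t = np.asarray(t, dtype=float)
    return 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2


def vapour_pressure_terms(tmin, tmax, rh_mean):
    """Saturation (es) and actual (ea) vapour pressure, kPa.

    es is the mean of e° at the daily extremes; ea scales es by the mean
    relative humidity, so ``ea <= es`` always.
    """
    es = (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin)) / 2.0
    ea = np.asarray(rh_mean, dtype=float) / 100.0 * es
    return es, ea


def atmospheric_pressure(elevation):
    """Atmospheric pressure in kPa from elevation in m (standard atmosphere)."""
    z = np.asarray(elevation, dtype=float)
    return 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26


def psychrometric_constant(elevation):
    """Psychrometric constant γ in kPa °C⁻¹; decreases with elevation."""
    return 0.000665 * atmospheric_pressure(elevation)


def extraterrestrial_radiation(doy, latitude):
    """Daily extraterrestrial radiation Ra, MJ m⁻² d⁻¹.

    ``doy`` is the 1-based day of year; ``latitude`` in decimal degrees
    (positive north).
    """
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(np.asarray(latitude, dtype=float))
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi / 365.0 * doy)
    delta = 0.409 * np.sin(2.0 * np.pi / 365.0 * doy - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    return (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )


def clear_sky_radiation(doy, latitude, elevation):
    """Clear-sky ceiling Rso = (0.75 + 2e-5 z) Ra, MJ m⁻² d⁻¹."""
    return (0.75 + 2e-5 * np.asarray(elevation, dtype=float)) * \
        extraterrestrial_radiation(doy, latitude)


def sunset_hour_angle(doy, latitude):
    """Sunset hour angle ωs in radians (π/2 at the equator)."""
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(np.asarray(latitude, dtype=float))
    delta = 0.409 * np.sin(2.0 * np.pi / 365.0 * doy - 1.39)
    return np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))


@dataclass(frozen=True)
class RadiationBudget:
    """Daily radiation components, MJ m⁻² d⁻¹ (fields may be arrays)."""

    ra_extra: np.ndarray   # extraterrestrial radiation
    rso: np.ndarray        # clear-sky ceiling
    rns: np.ndarray        # net shortwave
    rnl: np.ndarray        # net longwave (positive = surface loss)
    rn: np.ndarray         # net radiation, rns - rnl


def radiation_budget(sr, doy, latitude, elevation, tmin, tmax, ea,
                     sr_tolerance: float = 0.05) -> RadiationBudget:
    """Daily net radiation budget from measured shortwave radiation.

    Net shortwave reflects the grass albedo, ``Rns = (1 - 0.23) sr``. Net
    longwave follows the Stefan–Boltzmann form with humidity and cloudiness
    corrections; the relative shortwave ratio ``sr/Rso`` is clamped to
    ``CLOUDINESS_CLAMP`` so overcast or degenerate days cannot blow up the
    cloudiness factor. ``sr`` exceeding ``Rso`` by more than ``sr_tolerance``
    (relative) indicates inconsistent inputs and triggers a warning.
    """
    import warnings

    sr = np.asarray(sr, dtype=float)
    ra = extraterrestrial_radiation(doy, latitude)
    rso = (0.75 + 2e-5 * np.asarray(elevation, dtype=float)) * ra
    if np.any(sr > rso * (1.0 + sr_tolerance)):
        warnings.warn("solar radiation exceeds the clear-sky ceiling Rso; "
                      "check units or site metadata", stacklevel=2)
    rns = (1.0 - ALBEDO) * sr
    tmink = np.asarray(tmin, dtype=float) + 273.16
    tmaxk = np.asarray(tmax, dtype=float) + 273.16
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.clip(np.where(rso > 0, sr / np.where(rso > 0, rso, 1.0), 0.0),
                        *CLOUDINESS_CLAMP)
    rnl = (
        STEFAN_BOLTZMANN * (tmaxk ** 4 + tmink ** 4) / 2.0
        * (0.34 - 0.14 * np.sqrt(np.asarray(ea, dtype=float)))
        * (1.35 * ratio - 0.35)
    )
    return RadiationBudget(ra_extra=ra, rso=rso, rns=rns, rnl=rnl, rn=rns - rnl)


def _et0_arrays(tmin, tmax, ws, rh, sr, doy, latitude, elevation,
                floor_at_zero: bool = False):
    """Vectorised ET0 core shared by the record and series entry points."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    t = (tmin + tmax) / 2.0
    es, ea = vapour_pressure_terms(tmin, tmax, rh)
    delta = svp_slope(t)
    gamma = psychrometric_constant(elevation)
    budget = radiation_budget(sr, doy, latitude, elevation, tmin, tmax, ea)
    g = 0.0  # daily soil heat flux is negligible
    u2 = np.asarray(ws, dtype=float)
    num = 0.408 * delta * (budget.rn - g) + gamma * 900.0 / (t + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    et0 = num / den
    if floor_at_zero:
        et0 = np.maximum(et0, 0.0)
    return et0


def reference_et0(record: "WeatherRecord", site: "SiteMeta",
                  floor_at_zero: bool = False) -> float:
    """ET0 in mm d⁻¹ for a single fully observed day.

    Requires all five variables on the record; raises ``KeyError`` naming
    any missing one. Negative values (possible on strongly negative net
    radiation days) are returned as computed unless ``floor_at_zero``.
    """
    vals = {v: record.value(v) for v in ("tmin", "tmax", "ws", "rh", "sr")}
    doy = record.date.dayofyear
    return float(_et0_arrays(vals["tmin"], vals["tmax"], vals["ws"], vals["rh"],
                             vals["sr"], doy, site.latitude, site.elevation,
                             floor_at_zero))


def et0_series(series: "WeatherSeries", floor_at_zero: bool = False) -> np.ndarray:
    """ET0 for every record of a series carrying all five variables."""
    for v in ("tmin", "tmax", "ws", "rh", "sr"):
        if v not in series.variables:
            raise KeyError(f"variable {v!r} required for ET0 is absent")
    f = series.frame
    doy = f.index.dayofyear.to_numpy().astype(float)
    return _et0_arrays(
        f["tmin"].to_numpy(), f["tmax"].to_numpy(), f["ws"].to_numpy(),
        f["rh"].to_numpy(), f["sr"].to_numpy(), doy,
        series.site.latitude, series.site.elevation, floor_at_zero,
    )
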