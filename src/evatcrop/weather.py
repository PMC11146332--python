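"""Daily weather series: I/O, summary statistics, chronological splitting,
and a synthetic generator for the sub-humid plains climate the estimator
targets.

A :class:`WeatherSeries` wraps a :class:`pandas.DataFrame` indexed by calendar
date with float columns drawn from ``("tmin", "tmax", "ws", "rh", "sr")``:

========  =====================================  ==================
column    meaning                                units
========  =====================================  ==================
tmin      daily minimum air temperature          °C
tmax      daily maximum air temperature          °C
ws        wind speed at 2 m height (optional)    m s⁻¹
rh        daily mean relative humidity (opt.)    %
sr        incoming solar radiation (optional)    MJ m⁻² d⁻¹
========  =====================================  ==================

The temperature pair is always required; the three remaining variables are
optional, which is what allows downstream models to run on reduced input
combinations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from . import fao56

logger = logging.getLogger(__name__)

#: canonical variable order, shared with the fuzzy layer
VARIABLES: tuple[str, ...] = ("tmin", "tmax", "ws", "rh", "sr")

#: CSV column names of the on-disk dialect, keyed by internal variable name
CSV_COLUMNS: dict[str, str] = {
    "tmin": "tmin_c",
    "tmax": "tmax_c",
    "ws": "ws_ms",
    "rh": "rh_pct",
    "sr": "sr_mj_m2_d",
}
_CSV_TO_VAR = {v: k for k, v in CSV_COLUMNS.items()}


@dataclass(frozen=True)
class SiteMeta:
    """Location metadata needed by the radiation geometry.

    Parameters
    ----------
    name : str
        Free-text site label.
    latitude : float
        Decimal degrees, positive north. Must lie in [-90, 90].
    elevation : float
        Metres above sea level. Must be >= -430 (the lowest land surface).
    """

    name: str
    latitude: float
    elevation: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.elevation < -430.0:
            raise ValueError(f"elevation {self.elevation} below -430 m")


@dataclass(frozen=True)
class WeatherRecord:
    """A single day's observations; optional variables are ``None`` when absent."""

    date: pd.Timestamp
    tmin: float
    tmax: float
    ws: float | None = None
    rh: float | None = None
    sr: float | None = None

    def __post_init__(self) -> None:
        _validate_values(self.tmin, self.tmax, self.ws, self.rh, self.sr)

    def value(self, variable: str) -> float:
        v = getattr(self, variable)
        if v is None:
            raise KeyError(f"variable {variable!r} absent from record {self.date.date()}")
        return v


def _validate_values(tmin, tmax, ws, rh, sr) -> None:
    """Raise ValueError naming the violated record invariant, if any."""
    if not (np.isfinite(tmin) and np.isfinite(tmax)):
        raise ValueError("non-finite temperature")
    if tmin > tmax:
        raise ValueError(f"tmin {tmin} > tmax {tmax}")
    if rh is not None and not (0.0 <= rh <= 100.0):
        raise ValueError(f"rh {rh} outside [0, 100]")
    if ws is not None and ws < 0.0:
        raise ValueError(f"ws {ws} negative")
    if sr is not None and sr < 0.0:
        raise ValueError(f"sr {sr} negative")


@dataclass
class WeatherSeries:
    """An ordered daily weather table for one site.

    ``frame`` is indexed by a strictly increasing ``DatetimeIndex`` named
    ``date`` and holds only the columns that are actually available.
    """

    frame: pd.DataFrame
    site: SiteMeta

    def __post_init__(self) -> None:
        f = self.frame
        if "date" in f.columns:
            f = f.set_index("date")
        f.index = pd.DatetimeIndex(f.index, name="date")
        missing = {"tmin", "tmax"} - set(f.columns)
        if missing:
            raise ValueError(f"required columns absent: {sorted(missing)}")
        order = [v for v in VARIABLES if v in f.columns]
        f = f[order].astype(float).sort_index()
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise ValueError(f"duplicate date {dup.date()}")
        self.frame = f

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return iter(self.records())

    @property
    def variables(self) -> tuple[str, ...]:
        """Available variables, in canonical order."""
        return tuple(self.frame.columns)

    def records(self) -> list[WeatherRecord]:
        out = []
        for date, row in self.frame.iterrows():
            kw = {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
            out.append(WeatherRecord(date=date, **kw))
        return out

    def values(self, variable: str) -> np.ndarray:
        if variable not in self.frame.columns:
            raise KeyError(f"variable {variable!r} absent from series")
        return self.frame[variable].to_numpy()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_weather_csv(path, site: SiteMeta) -> WeatherSeries:
    """Read the daily weather CSV dialect into a :class:`WeatherSeries`.

    Rows violating the record invariants (unparseable date, ``tmin > tmax``,
    relative humidity outside [0, 100], negative wind or radiation) are
    rejected with a logged diagnostic naming the offending row and rule; the
    remaining rows form the series. Optional columns that are absent from the
    header stay absent — they are never filled with zeros.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    if "date" not in raw.columns or not {"tmin_c", "tmax_c"} <= set(raw.columns):
        raise ValueError(f"{path}: header must declare at least date,tmin_c,tmax_c")
    cols = [c for c in CSV_COLUMNS.values() if c in raw.columns]

    kept: list[dict] = []
    n_rejected = 0
    for i, row in raw.iterrows():
        rowno = i + 2  # 1-based, counting the header line
        try:
            date = pd.Timestamp(str(row["date"]))
        except (ValueError, TypeError):
            logger.warning("%s row %d: malformed date %r — row rejected", path, rowno, row["date"])
            n_rejected += 1
            continue
        rec = {"date": date}
        for c in cols:
            cell = row[c]
            rec[_CSV_TO_VAR[c]] = np.nan if pd.isna(cell) or cell == "" else float(cell)
        try:
            _validate_values(
                rec.get("tmin", np.nan), rec.get("tmax", np.nan),
                *(None if pd.isna(rec.get(v, np.nan)) else rec[v] for v in ("ws", "rh", "sr")),
            )
        except ValueError as e:
            logger.warning("%s row %d: %s — row rejected", path, rowno, e)
            n_rejected += 1
            continue
        kept.append(rec)

    if n_rejected:
        logger.info("%s: rejected %d of %d rows", path, n_rejected, len(raw))
    if not kept:
        raise ValueError(f"{path}: no valid rows")
    frame = pd.DataFrame(kept).set_index("date")
    # drop optional columns that carry no data at all
    frame = frame.dropna(axis="columns", how="all")
    return WeatherSeries(frame=frame, site=site)


def write_weather_csv(series: WeatherSeries, path) -> None:
    """Write a series in the CSV dialect (only the available columns)."""
    out = series.frame.rename(columns=CSV_COLUMNS).copy()
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Splitting and summaries
# ---------------------------------------------------------------------------

def chronological_split(series: WeatherSeries, train_fraction: float = 0.7
                        ) -> tuple[WeatherSeries, WeatherSeries]:
    """Split into a leading training part and trailing test part, no shuffling.

    The first ``floor(n * train_fraction)`` records form the training series.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(series)
    if n == 0:
        raise ValueError("cannot split an empty series")
    k = math.floor(n * train_fraction)
    return (
        WeatherSeries(frame=series.frame.iloc[:k].copy(), site=series.site),
        WeatherSeries(frame=series.frame.iloc[k:].copy(), site=series.site),
    )


@dataclass(frozen=True)
class SummaryStats:
    """Per-variable distribution summary.

    ``cv`` is sd/mean and ``sk`` the adjusted Fisher–Pearson sample skewness;
    either is NaN when undefined (zero mean, zero variance).
    """

    variable: str
    min: float
    max: float
    sd: float
    cv: float
    sk: float


def summary_statistics(series: WeatherSeries) -> list[SummaryStats]:
    """Min, max, standard deviation, coefficient of variation and skewness
    for every available variable.

    Sd is the population standard deviation (ddof=0). Requires at least three
    present values per variable; variables with fewer are skipped.
    """
    out = []
    for var in series.variables:
        x = series.frame[var].dropna().to_numpy()
        if x.size < 3:
            continue
        sd = float(np.std(x))
        mean = float(np.mean(x))
        cv = sd / mean if mean != 0.0 else float("nan")
        sk = float(stats.skew(x, bias=False)) if sd > 0.0 else float("nan")
        out.append(SummaryStats(var, float(x.min()), float(x.max()), sd, cv, sk))
    return out


# ---------------------------------------------------------------------------
# Synthetic weather
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Climate parameters of the synthetic daily weather generator.

    Defaults emulate the humid/sub-humid plains of northern West Bengal:
    warm monsoonal summers (annual Tmax peak near early August), a wide
    winter diurnal range, humidity that rises in the wet season, light and
    positively skewed winds (~1.2 m s⁻¹ mean), and radiation expressed as a
    clearness fraction of the clear-sky ceiling, higher in the dry season.
    """

    tmax_mean: float = 28.5          # °C, annual mean of daily maximum
    tmax_amplitude: float = 3.5      # °C, annual cycle half-range
    tmax_peak_doy: float = 215.0     # day of year of warmest Tmax
    tmax_noise_sd: float = 1.5       # °C, day-to-day Gaussian noise (clipped ±3.5 sd)
    drange_mean: float = 9.0         # °C, mean diurnal range
    drange_amplitude: float = 3.5    # °C, winter-peaking cycle half-range
    drange_peak_doy: float = 15.0    # day of year of widest range (dry season)
    drange_noise_sd: float = 1.0     # °C
    drange_min: float = 1.5          # °C, floor keeping tmin < tmax
    rh_mean: float = 73.0            # %, annual mean relative humidity
    rh_amplitude: float = 12.0       # %, wet-season peak half-range
    rh_peak_doy: float = 215.0       # day of year of peak humidity (monsoon)
    rh_noise_sd: float = 5.0         # %
    rh_bounds: tuple[float, float] = (20.0, 100.0)
    ws_weibull_shape: float = 1.7    # k < 3.6 guarantees positive skewness
    ws_weibull_scale: float = 1.34   # m s⁻¹; mean = scale * Γ(1 + 1/k) ≈ 1.2
    clearness_mean: float = 0.62     # dimensionless sr / Rso
    clearness_amplitude: float = 0.13
    clearness_peak_doy: float = 15.0  # clearest skies in the dry season
    clearness_noise_sd: float = 0.08
    clearness_bounds: tuple[float, float] = (0.25, 1.0)


def _annual_cycle(doy: np.ndarray, mean: float, amplitude: float, peak_doy: float
                  ) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def generate_synthetic_weather(
    n_days: int,
    site: SiteMeta,
    seed: int,
    params: GeneratorParams | None = None,
    start: str = "2000-01-01",
) -> WeatherSeries:
    """Generate a seeded synthetic daily weather series.

    The series carries all five variables: sinusoidal annual cycles with
    clipped Gaussian noise for temperatures and humidity, Weibull-distributed
    wind speed (hence positively skewed for any usable sample size), and
    solar radiation as a seasonal clearness fraction of the site's clear-sky
    radiation ceiling, so ``0 < sr <= Rso`` by construction. Identical
    ``seed``/``params`` give an identical series.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start=start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)

    def clipped_normal(sd: float, size: int) -> np.ndarray:
        return np.clip(rng.normal(0.0, sd, size), -3.5 * sd, 3.5 * sd)

    tmax = _annual_cycle(doy, p.tmax_mean, p.tmax_amplitude, p.tmax_peak_doy)
    tmax = tmax + clipped_normal(p.tmax_noise_sd, n_days)
    drange = _annual_cycle(doy, p.drange_mean, p.drange_amplitude, p.drange_peak_doy)
    drange = np.maximum(drange + clipped_normal(p.drange_noise_sd, n_days), p.drange_min)
    tmin = tmax - drange

    rh = _annual_cycle(doy, p.rh_mean, p.rh_amplitude, p.rh_peak_doy)
    rh = np.clip(rh + clipped_normal(p.rh_noise_sd, n_days), *p.rh_bounds)

    ws = p.ws_weibull_scale * rng.weibull(p.ws_weibull_shape, n_days)

    clearness = _annual_cycle(doy, p.clearness_mean, p.clearness_amplitude,
                              p.clearness_peak_doy)
    clearness = np.clip(clearness + clipped_normal(p.clearness_noise_sd, n_days),
                        *p.clearness_bounds)
    rso = fao56.clear_sky_radiation(doy, site.latitude, site.elevation)
    sr = clearness * rso

    frame = pd.DataFrame(
        {"tmin": tmin, "tmax": tmax, "ws": ws, "rh": rh, "sr": sr}, index=dates
    )
    frame.index.name = "date"
    return WeatherSeries(frame=frame, site=site)
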