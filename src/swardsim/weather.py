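"""Daily weather series: file input, validation, synthesis, and PAR.

The simulator is driven by one meteorological record per calendar day:
minimum and maximum air temperature (°C), global solar radiation
(MJ m⁻² d⁻¹) and precipitation (mm d⁻¹), optionally extended with mean
vapour pressure (kPa) and 2-m wind speed (m s⁻¹) for Penman–Monteith
evapotranspiration.  Series are read from delimited text with an explicit
column mapping, or generated by a stochastic weather generator that
emulates a temperate maritime (UK-like) climate: a sinusoidal annual
temperature cycle with autocorrelated bounded noise, solar radiation as a
clear-sky ceiling scaled by cloudiness, and rainfall from a two-state
wet/dry Markov occurrence chain with gamma-distributed wet-day amounts.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, fields
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ContinuityError, DomainError, FormatError

__all__ = [
    "WeatherRecord",
    "WeatherSeries",
    "SyntheticClimate",
    "read_weather_table",
    "write_weather_table",
    "synthesize_weather",
    "par_from_radiation",
    "extraterrestrial_radiation",
]

#: Default fraction of global solar radiation that is photosynthetically
#: active.  0.5 is the standard value in light-use-efficiency grass models.
PAR_FRACTION = 0.5

#: Solar constant, MJ m⁻² min⁻¹ (FAO-56).
_GSC = 0.0820


@dataclass(frozen=True)
class WeatherRecord:
    """One day of meteorological drivers.

    Attributes
    ----------
    date : datetime.date
    tmin, tmax : float
        Daily minimum / maximum air temperature, °C.
    radiation : float
        Global solar radiation, MJ m⁻² d⁻¹.
    rain : float
        Precipitation, mm d⁻¹.
    vapour_pressure : float or None
        Mean actual vapour pressure, kPa (optional).
    wind : float or None
        Wind speed at 2 m, m s⁻¹ (optional).
    """

    date: dt.date
    tmin: float
    tmax: float
    radiation: float
    rain: float
    vapour_pressure: float | None = None
    wind: float | None = None

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise DomainError(
                f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.radiation < 0:
            raise DomainError(f"{self.date}: negative radiation {self.radiation}")
        if self.rain < 0:
            raise DomainError(f"{self.date}: negative rain {self.rain}")

    @property
    def tavg(self) -> float:
        """Daily mean air temperature, (tmin + tmax) / 2, °C."""
        return 0.5 * (self.tmin + self.tmax)

    @property
    def par(self) -> float:
        """Photosynthetically active radiation at the default PAR fraction."""
        return par_from_radiation(self.radiation)


class WeatherSeries:
    """An ordered, gap-free sequence of daily weather records.

    Dates must increase strictly by one day.  Optional fields (vapour
    pressure, wind) must be present on every record or on none.
    """

    def __init__(
        self,
        records: Iterable[WeatherRecord],
        site_label: str = "",
        year: int | None = None,
    ):
        self.records: list[WeatherRecord] = list(records)
        if not self.records:
            raise ContinuityError("weather series is empty")
        for prev, cur in zip(self.records, self.records[1:]):
            delta = (cur.date - prev.date).days
            if delta != 1:
                raise ContinuityError(
                    f"date gap between {prev.date} and {cur.date} "
                    f"({delta} days; expected 1)"
                )
        has_vp = [r.vapour_pressure is not None for r in self.records]
        has_wind = [r.wind is not None for r in self.records]
        if any(has_vp) and not all(has_vp):
            raise FormatError("vapour_pressure present on some records but not all")
        if any(has_wind) and not all(has_wind):
            raise FormatError("wind present on some records but not all")
        self.site_label = site_label
        self.year = year if year is not None else self.records[0].date.year

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[WeatherRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> WeatherRecord:
        return self.records[i]

    @property
    def start(self) -> dt.date:
        return self.records[0].date

    @property
    def end(self) -> dt.date:
        return self.records[-1].date

    @property
    def has_penman_inputs(self) -> bool:
        """True when vapour pressure and wind are available on all days."""
        r = self.records[0]
        return r.vapour_pressure is not None and r.wind is not None

    def covers(self, start: dt.date, end: dt.date) -> bool:
        return self.start <= start and self.end >= end

    def window(self, start: dt.date, end: dt.date) -> "WeatherSeries":
        """Sub-series covering [start, end] inclusive."""
        if not self.covers(start, end):
            raise ContinuityError(
                f"weather covers {self.start}..{self.end}, "
                f"cannot supply {start}..{end}"
            )
        i0 = (start - self.start).days
        i1 = (end - self.start).days + 1
        return WeatherSeries(self.records[i0:i1], self.site_label, self.year)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with one row per day, optional columns dropped if absent."""
        cols = {f.name: [getattr(r, f.name) for r in self.records]
                for f in fields(WeatherRecord)}
        df = pd.DataFrame(cols)
        for opt in ("vapour_pressure", "wind"):
            if df[opt].isna().all():
                df = df.drop(columns=opt)
        return df


# ---------------------------------------------------------------------------
# Reading and writing delimited tables
# ---------------------------------------------------------------------------

#: Required columns of the canonical weather dialect.
REQUIRED_FIELDS = ("date", "tmin", "tmax", "radiation", "rain")
OPTIONAL_FIELDS = ("vapour_pressure", "wind")


def read_weather_table(
    path,
    dialect: Mapping[str, str] | None = None,
    site_label: str = "",
) -> WeatherSeries:
    """Read a delimited daily weather table into a validated series.

    Parameters
    ----------
    path : str or pathlib.Path
        Comma- or tab-delimited text file with a header row and one row
        per day.
    dialect : mapping, optional
        Maps canonical field names (``date``, ``tmin``, ``tmax``,
        ``radiation``, ``rain``, and optionally ``vapour_pressure``,
        ``wind``) to the column headers used in the file.  Defaults to the
        identity mapping.  Extra file columns are ignored; there is no
        header guessing.

    Raises
    ------
    FormatError
        A required mapped column is absent or fails to parse.
    ContinuityError
        Dates are out of order or have gaps.
    DomainError
        A row violates a physical invariant (tmax < tmin, negative rain
        or radiation); the message names the offending date.
    """
    dialect = dict(dialect or {})
    colmap = {f: dialect.get(f, f) for f in REQUIRED_FIELDS + OPTIONAL_FIELDS}
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for canon in REQUIRED_FIELDS:
        if colmap[canon] not in df.columns:
            raise FormatError(
                f"required column {canon!r} (mapped to {colmap[canon]!r}) "
                f"not found in {path}"
            )
    present_optional = [f for f in OPTIONAL_FIELDS if colmap[f] in df.columns]

    try:
        dates = pd.to_datetime(df[colmap["date"]], format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        raise FormatError(f"column {colmap['date']!r} does not parse as ISO dates: {exc}")

    def _num(canon: str) -> np.ndarray:
        col = pd.to_numeric(df[colmap[canon]], errors="coerce")
        if col.isna().any():
            bad = dates[col.isna()].iloc[0]
            raise FormatError(f"column {canon!r} not numeric at {bad}")
        return col.to_numpy(dtype=float)

    values = {f: _num(f) for f in REQUIRED_FIELDS[1:]}
    optvals = {f: _num(f) for f in present_optional}

    records = []
    for i, d in enumerate(dates):
        records.append(
            WeatherRecord(
                date=d,
                tmin=values["tmin"][i],
                tmax=values["tmax"][i],
                radiation=values["radiation"][i],
                rain=values["rain"][i],
                vapour_pressure=optvals.get("vapour_pressure", [None] * len(df))[i]
                if "vapour_pressure" in optvals else None,
                wind=optvals["wind"][i] if "wind" in optvals else None,
            )
        )
    return WeatherSeries(records, site_label=site_label)


def write_weather_table(series: WeatherSeries, path, sep: str = ",") -> None:
    """Write a series to delimited text; inverse of :func:`read_weather_table`.

    Floats are written with 17 significant digits so the round trip is
    value-exact.
    """
    series.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# PAR and extraterrestrial radiation
# ---------------------------------------------------------------------------


def par_from_radiation(radiation: float, fraction: float = PAR_FRACTION) -> float:
    """Photosynthetically active radiation as a fixed fraction of global.

    Raises :class:`DomainError` for negative radiation.
    """
    if radiation < 0:
        raise DomainError(f"negative radiation {radiation}")
    return fraction * radiation


def extraterrestrial_radiation(doy: int, latitude: float) -> float:
    """Daily extraterrestrial radiation Ra, MJ m⁻² d⁻¹ (FAO-56 eq. 21).

    Used as the clear-sky ceiling of the weather generator and for net
    long-wave estimates in the Priestley–Taylor fallback.
    """
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (24.0 * 60.0 / math.pi) * _GSC * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )
    return max(0.0, ra)


# ---------------------------------------------------------------------------
# Synthetic temperate-maritime weather
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticClimate:
    """Parameters of the stochastic weather generator.

    Defaults describe a temperate maritime lowland climate of the kind
    perennial ryegrass swards are grown in across the UK: annual-mean air
    temperature near 9.5 °C swinging ±6.5 °C over the year (warmest around
    late July), ~690 mm annual rainfall spread over ~44% of days, and
    global radiation between ~15% and ~75% of the clear-sky ceiling
    depending on cloudiness.
    """

    tmean: float = 9.5            #: annual mean air temperature, °C
    tamp: float = 6.5             #: seasonal semi-amplitude, °C
    warmest_doy: int = 200        #: day of year of the temperature maximum
    temp_noise_sd: float = 1.5    #: s.d. of daily temperature anomalies, °C
    temp_noise_rho: float = 0.6   #: lag-1 autocorrelation of anomalies
    temp_noise_bound: float = 8.0 #: hard clip on anomalies, °C
    diurnal_range: float = 7.5    #: tmax − tmin, °C
    p_wet_given_dry: float = 0.30 #: Markov transition P(wet | dry)
    p_wet_given_wet: float = 0.62 #: Markov transition P(wet | wet)
    rain_shape: float = 0.85      #: gamma shape of wet-day amounts
    rain_mean: float = 4.3        #: mean wet-day amount, mm
    tau_dry: tuple[float, float] = (0.50, 0.75)  #: transmissivity range, dry days
    tau_wet: tuple[float, float] = (0.15, 0.40)  #: transmissivity range, wet days

    def __post_init__(self):
        for name in ("temp_noise_sd", "diurnal_range", "rain_shape", "rain_mean"):
            if getattr(self, name) < 0:
                raise DomainError(f"climate parameter {name} must be >= 0")
        for name in ("p_wet_given_dry", "p_wet_given_wet"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"climate parameter {name}={p} outside [0, 1]")


def synthesize_weather(
    year: int,
    latitude: float = 52.0,
    seed: int = 0,
    climate: SyntheticClimate | None = None,
    site_label: str = "synthetic",
) -> WeatherSeries:
    """Generate one calendar year of synthetic daily weather.

    The daily mean temperature follows a sinusoid set by ``climate``
    (mean, amplitude, phase) plus bounded AR(1) noise; tmin/tmax are the
    mean ∓/± half the diurnal range.  Radiation is the clear-sky ceiling
    (0.75 × extraterrestrial) scaled by a cloudiness-dependent
    transmissivity, lower on wet days.  Rain occurrence follows a
    two-state Markov chain; wet-day amounts are gamma distributed.
    Output is bit-reproducible for a fixed seed.

    Parameters
    ----------
    year : int
        Calendar year; leap years produce 366 records (1 Jan – 31 Dec).
    latitude : float
        Site latitude in degrees, restricted to the temperate band [40, 65].
    seed : int
        Seed for :class:`numpy.random.Generator`.
    climate : SyntheticClimate, optional
        Generator parameters; defaults to the UK-like climate.
    """
    if not 40.0 <= latitude <= 65.0:
        raise DomainError(f"latitude {latitude} outside supported band [40, 65]")
    c = climate or SyntheticClimate()
    rng = np.random.default_rng(seed)

    start = dt.date(year, 1, 1)
    ndays = (dt.date(year, 12, 31) - start).days + 1
    doy = np.arange(1, ndays + 1)

    # seasonal temperature cycle + bounded AR(1) anomalies
    tclim = c.tmean + c.tamp * np.cos(2.0 * np.pi * (doy - c.warmest_doy) / 365.25)
    innov_sd = c.temp_noise_sd * math.sqrt(max(1e-12, 1.0 - c.temp_noise_rho ** 2))
    innov = rng.normal(0.0, 1.0, ndays) * innov_sd
    anom = np.empty(ndays)
    prev = 0.0
    for i in range(ndays):
        prev = c.temp_noise_rho * prev + innov[i]
        anom[i] = prev
    anom = np.clip(anom, -c.temp_noise_bound, c.temp_noise_bound)
    tavg = tclim + anom
    tmin = tavg - 0.5 * c.diurnal_range
    tmax = tavg + 0.5 * c.diurnal_range

    # two-state rainfall occurrence chain, gamma amounts
    u = rng.random(ndays)
    wet = np.zeros(ndays, dtype=bool)
    wet_prev = False
    for i in range(ndays):
        p = c.p_wet_given_wet if wet_prev else c.p_wet_given_dry
        wet[i] = u[i] < p
        wet_prev = wet[i]
    amounts = np.zeros(ndays)
    nwet = int(wet.sum())
    if nwet and c.rain_mean > 0 and c.rain_shape > 0:
        scale = c.rain_mean / c.rain_shape
        amounts[wet] = rng.gamma(c.rain_shape, scale, nwet)

    # radiation: clear-sky ceiling scaled by cloudiness
    ra = np.array([extraterrestrial_radiation(int(d), latitude) for d in doy])
    rso = 0.75 * ra
    tau = np.where(
        wet,
        rng.uniform(c.tau_wet[0], c.tau_wet[1], ndays),
        rng.uniform(c.tau_dry[0], c.tau_dry[1], ndays),
    )
    radiation = rso * tau / 0.75  # tau expressed as fraction of Ra

    records = [
        WeatherRecord(
            date=start + dt.timedelta(days=int(i)),
            tmin=float(tmin[i]),
            tmax=float(tmax[i]),
            radiation=float(radiation[i]),
            rain=float(amounts[i]),
        )
        for i in range(ndays)
    ]
    return WeatherSeries(records, site_label=site_label, year=year)
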