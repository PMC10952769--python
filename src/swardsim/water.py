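"""Soil water balance, reference evapotranspiration and drought stress.

A single-layer "tipping bucket" of depth equal to the rooting depth holds
plant-available water between the wilting point and field capacity.
Reference evapotranspiration (ET₀) uses FAO-56 Penman–Monteith when the
weather series carries vapour pressure and wind, and a Priestley–Taylor
(α = 1.26) radiation–temperature method otherwise.  ET₀ is partitioned
into soil evaporation, exp(−k·LAI) of ET₀, and a transpiration demand,
fInt(LAI)·ET₀; actual transpiration is demand times the drought factor
wf, which ramps linearly from 0 at a critical fraction of plant-available
water down to the wilting point.  With the irrigation switch on, the
profile is refilled to field capacity whenever stress would otherwise
occur, so wf stays at 1 (ideal irrigation — no scheduling).  Excess water
above field capacity leaves the same day as drainage (runoff is merged
into drainage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .canopy import fraction_intercepted
from .errors import ConfigError, DomainError
from .weather import WeatherRecord, extraterrestrial_radiation

__all__ = [
    "SoilWaterParameters",
    "WaterState",
    "reference_evapotranspiration",
    "transpiration_reduction",
    "step_water_balance",
]

_ALBEDO = 0.23            # grass reference surface
_SIGMA = 4.903e-9         # Stefan–Boltzmann, MJ K⁻⁴ m⁻² d⁻¹
_GAMMA = 0.0665           # psychrometric constant at sea level, kPa °C⁻¹
_LAMBDA = 2.45            # latent heat of vaporization, MJ kg⁻¹
_PT_ALPHA = 1.26          # Priestley–Taylor coefficient


@dataclass(frozen=True)
class SoilWaterParameters:
    """Soil hydraulic constants of the root-zone bucket.

    ``rooting_depth`` is the primary user-facing soil lever: deeper soils
    hold more plant-available water and buffer dry spells longer.
    """

    field_capacity: float = 0.35   #: volumetric water content at field capacity
    wilting_point: float = 0.12    #: volumetric water content at wilting point
    rooting_depth: float = 600.0   #: mm
    crit_fraction: float = 0.5     #: fraction of PAW below which wf < 1
    init_fraction: float = 1.0     #: initial fill of plant-available water

    def __post_init__(self):
        if not 0.0 < self.wilting_point < self.field_capacity < 1.0:
            raise ConfigError(
                "need 0 < wilting_point < field_capacity < 1, got "
                f"wp={self.wilting_point}, fc={self.field_capacity}"
            )
        if self.rooting_depth <= 0:
            raise ConfigError("rooting_depth must be > 0")
        if not 0.0 < self.crit_fraction <= 1.0:
            raise ConfigError("crit_fraction must lie in (0, 1]")
        if not 0.0 <= self.init_fraction <= 1.0:
            raise ConfigError("init_fraction must lie in [0, 1]")

    @property
    def sw_max(self) -> float:
        """Soil water at field capacity, mm."""
        return self.field_capacity * self.rooting_depth

    @property
    def sw_min(self) -> float:
        """Soil water at wilting point, mm."""
        return self.wilting_point * self.rooting_depth

    def initial_soil_water(self) -> float:
        return self.sw_min + self.init_fraction * (self.sw_max - self.sw_min)


@dataclass
class WaterState:
    soil_water: float              #: mm in root zone
    cum_transpiration: float = 0.0
    cum_evaporation: float = 0.0
    cum_drainage: float = 0.0
    cum_irrigation: float = 0.0
    cum_rain: float = 0.0


# ---------------------------------------------------------------------------
# Reference evapotranspiration
# ---------------------------------------------------------------------------


def _sat_vp(t: float) -> float:
    """Saturation vapour pressure, kPa (FAO-56 eq. 11)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def _vp_slope(t: float) -> float:
    """Slope of the saturation vapour-pressure curve, kPa °C⁻¹."""
    return 4098.0 * _sat_vp(t) / (t + 237.3) ** 2


def _net_radiation(rec: WeatherRecord, latitude: float, ea: float) -> float:
    """Net radiation at the grass surface, MJ m⁻² d⁻¹ (FAO-56)."""
    rns = (1.0 - _ALBEDO) * rec.radiation
    ra = extraterrestrial_radiation(rec.date.timetuple().tm_yday, latitude)
    rso = 0.75 * ra
    rel = min(1.0, rec.radiation / rso) if rso > 0 else 0.3
    tmax_k4 = (rec.tmax + 273.16) ** 4
    tmin_k4 = (rec.tmin + 273.16) ** 4
    rnl = (
        _SIGMA * 0.5 * (tmax_k4 + tmin_k4)
        * (0.34 - 0.14 * math.sqrt(max(0.0, ea)))
        * (1.35 * rel - 0.35)
    )
    return rns - max(0.0, rnl)


def reference_evapotranspiration(rec: WeatherRecord, latitude: float) -> float:
    """Daily grass reference ET₀, mm d⁻¹, never negative.

    FAO-56 Penman–Monteith when the record carries vapour pressure and
    wind; otherwise Priestley–Taylor with α = 1.26 on the same net
    radiation, estimating the actual vapour pressure as saturation at
    tmin (standard humid-climate proxy).  Pure function of its inputs.
    """
    t = rec.tavg
    delta = _vp_slope(t)
    if rec.vapour_pressure is not None and rec.wind is not None:
        ea = rec.vapour_pressure
        es = 0.5 * (_sat_vp(rec.tmin) + _sat_vp(rec.tmax))
        rn = _net_radiation(rec, latitude, ea)
        u2 = rec.wind
        num = 0.408 * delta * rn + _GAMMA * (900.0 / (t + 273.0)) * u2 * max(0.0, es - ea)
        den = delta + _GAMMA * (1.0 + 0.34 * u2)
        return max(0.0, num / den)
    ea = _sat_vp(rec.tmin)
    rn = _net_radiation(rec, latitude, ea)
    return max(0.0, _PT_ALPHA * delta / (delta + _GAMMA) * rn / _LAMBDA)


# ---------------------------------------------------------------------------
# Stress factor and daily balance
# ---------------------------------------------------------------------------


def transpiration_reduction(soil_water: float, p: SoilWaterParameters) -> float:
    """Drought stress factor wf ∈ [0, 1].

    The available fraction a = (SW − SWwp) / (SWfc − SWwp) is rescaled by
    the critical fraction: wf = clamp(a / crit_fraction, 0, 1).  1 at
    field capacity, 0 at the wilting point.
    """
    a = (soil_water - p.sw_min) / (p.sw_max - p.sw_min)
    return min(1.0, max(0.0, a / p.crit_fraction))


def step_water_balance(
    state: WaterState,
    rec: WeatherRecord,
    lai: float,
    et0: float,
    irrigated: int,
    p: SoilWaterParameters,
    k_ext: float = 0.6,
) -> tuple[WaterState, dict]:
    """Advance the bucket by one day; returns (new state, daily fluxes).

    Order: irrigation tops the profile up to field capacity when the flag
    is set and stress would otherwise occur; rain is added; soil
    evaporation (ET₀·exp(−k·LAI)) and actual transpiration
    (ET₀·fInt(LAI)·wf) are extracted, capped jointly so the profile never
    falls below wilting point; excess above field capacity drains the
    same day.  Closure Δsoil = in − E − T − drainage holds exactly.

    The flux dict carries ``evaporation``, ``transpiration``, ``wf``,
    ``irrigation``, ``drainage`` for the daily output table.
    """
    if irrigated not in (0, 1):
        raise ConfigError(f"irrigated flag must be 0 or 1, got {irrigated!r}")
    if et0 < 0:
        raise DomainError(f"negative ET0 {et0}")

    sw = state.soil_water
    irrigation = 0.0
    if irrigated == 1 and transpiration_reduction(sw, p) < 1.0:
        irrigation = p.sw_max - sw
        sw = p.sw_max

    wf = transpiration_reduction(sw, p)
    sw += rec.rain

    evap_demand = et0 * math.exp(-k_ext * lai)
    transp = et0 * fraction_intercepted(lai, k_ext) * wf
    extract = evap_demand + transp
    avail = max(0.0, sw - p.sw_min)
    if extract > avail > 0.0:
        scale = avail / extract
        evap_demand *= scale
        transp *= scale
    elif avail == 0.0:
        evap_demand = transp = 0.0
    sw -= evap_demand + transp

    drainage = max(0.0, sw - p.sw_max)
    sw -= drainage

    new = replace(
        state,
        soil_water=sw,
        cum_transpiration=state.cum_transpiration + transp,
        cum_evaporation=state.cum_evaporation + evap_demand,
        cum_drainage=state.cum_drainage + drainage,
        cum_irrigation=state.cum_irrigation + irrigation,
        cum_rain=state.cum_rain + rec.rain,
    )
    fluxes = {
        "evaporation": evap_demand,
        "transpiration": transp,
        "irrigation": irrigation,
        "drainage": drainage,
        "wf": wf,
    }
    return new, fluxes
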