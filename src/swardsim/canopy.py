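"""Daily canopy growth: light capture, source/sink limitation, reserves.

The growth engine follows the light-use-efficiency (LUE) family of grass
models.  Each day the canopy fixes an amount of dry matter limited either
by its *source* — intercepted photosynthetically active radiation times a
light-use efficiency modified by temperature, CO₂ and the more limiting
of water and nitrogen stress — or by its *sink* — the capacity of the
tiller population to expand leaf area, driven by thermal time.  Surplus
assimilate is buffered in a carbohydrate reserve pool (stubble and crown
storage) that is drawn down to support regrowth after cutting; reserve
storage is capped and remobilization is rate-limited.  Leaf death is
driven by self-shading above a critical leaf area index and by drought.
Tiller numbers rise by site filling while light is available low in the
canopy and fall under self-shading.

All pool sizes are kg DM ha⁻¹; LAI is m² leaf per m² ground; rates are
per day.  Integration is forward Euler with a fixed one-day step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ConfigError, DomainError

__all__ = [
    "CanopyParameters",
    "CanopyState",
    "fraction_intercepted",
    "temperature_factor",
    "co2_factor",
    "source_limited_growth",
    "sink_limited_growth",
    "allocate_with_reserves",
    "leaf_death_rate",
    "update_tillers",
    "apply_canopy_fluxes",
]

#: Default temperature-response anchors (°C, factor): no growth at or below
#: the 3 °C base temperature, optimal from 10 to 25 °C, shut down at 35 °C.
DEFAULT_TEMP_TABLE = ((3.0, 0.0), (10.0, 1.0), (25.0, 1.0), (35.0, 0.0))


@dataclass(frozen=True)
class CanopyParameters:
    """Grass canopy constants (perennial ryegrass parameterization).

    Defaults follow the published LINGRA-family values for *Lolium
    perenne*; every one is configurable and the engine logs the values
    used for a run.
    """

    k_ext: float = 0.6             #: PAR extinction coefficient
    lue_ref: float = 3.0           #: light-use efficiency, g DM MJ⁻¹ PAR
    sla: float = 0.0025            #: specific leaf area, ha leaf kg⁻¹ DM
    t_base: float = 3.0            #: base temperature for thermal time, °C
    lai_crit: float = 4.0          #: critical LAI for self-shading
    rdr_max: float = 0.05          #: max relative leaf death rate, d⁻¹
    phyllochron: float = 110.0     #: °Cd per leaf appearance
    site_filling: float = 0.693    #: new tillers per tiller per phyllochron
    tiller_death_max: float = 0.01 #: max relative tiller death rate, d⁻¹
    leaf_width: float = 0.003      #: m
    ler_slope: float = 0.00083     #: leaf elongation, m °Cd⁻¹ tiller⁻¹
    co2_ref: float = 360.0         #: reference CO₂, ppm
    co2_beta: float = 0.8          #: log-response coefficient
    frac_root: float = 0.30        #: fraction of growth allocated below ground
    reserves_max_frac: float = 0.20  #: reserve cap as fraction of shoot DM
    remob_rate: float = 80.0       #: max reserve withdrawal, kg DM ha⁻¹ d⁻¹
    temp_factor_table: tuple[tuple[float, float], ...] = DEFAULT_TEMP_TABLE

    def __post_init__(self):
        for name in ("k_ext", "lue_ref", "sla", "rdr_max", "phyllochron",
                     "site_filling", "tiller_death_max", "leaf_width",
                     "ler_slope", "co2_ref", "remob_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"canopy parameter {name} must be >= 0")
        for name in ("frac_root", "reserves_max_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"canopy parameter {name}={v} outside [0, 1]")
        xs = [x for x, _ in self.temp_factor_table]
        ys = [y for _, y in self.temp_factor_table]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigError("temp_factor_table abscissae must strictly increase")
        if any(not 0.0 <= y <= 1.0 for y in ys):
            raise ConfigError("temp_factor_table values must lie in [0, 1]")


@dataclass
class CanopyState:
    """Crop state pools at the end of a day."""

    lai: float = 0.0               #: leaf area index
    tillers: float = 0.0           #: tiller density, m⁻²
    w_leaf_green: float = 0.0      #: green leaf, kg DM ha⁻¹
    w_leaf_dead: float = 0.0       #: standing dead leaf, kg DM ha⁻¹
    w_stem: float = 0.0            #: stem, kg DM ha⁻¹
    w_seed: float = 0.0            #: seed head, kg DM ha⁻¹
    w_root: float = 0.0            #: root, kg DM ha⁻¹
    reserves: float = 0.0          #: carbohydrate reserves, kg DM ha⁻¹
    tt_since_cut: float = 0.0      #: thermal time since last harvest, °Cd

    @property
    def w_shoot_live(self) -> float:
        """Live shoot mass (green leaf + stem), the N-bearing pools."""
        return self.w_leaf_green + self.w_stem

    @property
    def w_aboveground(self) -> float:
        """Standing above-ground DM including dead leaf and seed."""
        return self.w_leaf_green + self.w_leaf_dead + self.w_stem + self.w_seed

    def total_dm(self) -> float:
        return self.w_aboveground + self.w_root + self.reserves


# ---------------------------------------------------------------------------
# Source side
# ---------------------------------------------------------------------------


def fraction_intercepted(lai: float, k_ext: float = 0.6) -> float:
    """Beer's-law fraction of incoming PAR intercepted by the canopy."""
    if lai < 0:
        raise DomainError(f"negative LAI {lai}")
    return 1.0 - math.exp(-k_ext * lai)


def temperature_factor(tavg: float, params: CanopyParameters) -> float:
    """Growth reduction factor for temperature, piecewise linear in [0, 1].

    Interpolates ``temp_factor_table`` and clamps outside the anchors;
    zero at or below the base temperature by construction of the default
    table.
    """
    table = params.temp_factor_table
    if tavg <= table[0][0]:
        return table[0][1]
    if tavg >= table[-1][0]:
        return table[-1][1]
    for (x0, y0), (x1, y1) in zip(table, table[1:]):
        if x0 <= tavg <= x1:
            f = y0 + (y1 - y0) * (tavg - x0) / (x1 - x0)
            return min(1.0, max(0.0, f))
    raise AssertionError("unreachable")  # pragma: no cover


def co2_factor(co2: float, params: CanopyParameters) -> float:
    """Logarithmic CO₂ response of light-use efficiency.

    1 + β·ln(CO₂/CO₂ref), floored at zero; equals 1 at the reference
    concentration and rises monotonically.
    """
    if co2 <= 0:
        raise DomainError(f"non-positive CO2 {co2}")
    return max(0.0, 1.0 + params.co2_beta * math.log(co2 / params.co2_ref))


def source_limited_growth(
    par: float,
    lai: float,
    tf: float,
    cf: float,
    wf: float,
    nf: float,
    params: CanopyParameters,
) -> float:
    """Radiation-limited growth rate, kg DM ha⁻¹ d⁻¹.

    10 · PAR · fInt(LAI) · LUE · tf · cf · min(wf, nf); the factor 10
    converts g m⁻² to kg ha⁻¹.  Water and nitrogen stress act through
    their minimum (Liebig coupling), not their product.
    """
    if par < 0:
        raise DomainError(f"negative PAR {par}")
    fint = fraction_intercepted(lai, params.k_ext)
    return 10.0 * par * fint * params.lue_ref * tf * cf * min(wf, nf)


# ---------------------------------------------------------------------------
# Sink side
# ---------------------------------------------------------------------------


def sink_limited_growth(state: CanopyState, dtt: float, params: CanopyParameters) -> float:
    """Growth the tiller population can structurally accommodate, kg DM ha⁻¹ d⁻¹.

    Potential leaf-area expansion is tiller density × leaf elongation rate
    × thermal time × leaf width (m² leaf per m² ground per day); dividing
    by the specific leaf area converts the expansion to a dry-matter
    demand.  Zero on cold days (dtt = 0) and for a tiller-less sward.
    """
    if dtt < 0:
        raise DomainError(f"negative thermal time increment {dtt}")
    dlai = state.tillers * params.ler_slope * dtt * params.leaf_width
    if params.sla <= 0:
        return math.inf
    return dlai / params.sla


def allocate_with_reserves(
    source: float,
    sink: float,
    reserves: float,
    params: CanopyParameters,
    shoot_dm: float,
) -> tuple[float, float, float]:
    """Arbitrate between source and sink via the reserve pool.

    Returns ``(growth, new_reserves, discarded)``.

    * source ≥ sink: growth = sink; the surplus tops up reserves until the
      cap ``reserves_max_frac × shoot_dm`` binds; assimilate beyond the
      cap is discarded as unrealized (photosynthetic down-regulation).
    * source < sink: the deficit is withdrawn from reserves, at most
      ``remob_rate`` per day; growth = source + withdrawal (≤ sink).

    Mass balance: growth + Δreserves + discarded = source exactly.
    """
    if min(source, sink, reserves) < 0:
        raise DomainError("source, sink and reserves must be >= 0")
    cap = params.reserves_max_frac * shoot_dm
    if source >= sink:
        growth = sink
        surplus = source - sink
        room = max(0.0, cap - reserves)
        stored = min(surplus, room)
        return growth, reserves + stored, surplus - stored
    withdrawal = min(sink - source, reserves, params.remob_rate)
    return source + withdrawal, reserves - withdrawal, 0.0


# ---------------------------------------------------------------------------
# Turnover
# ---------------------------------------------------------------------------


def leaf_death_rate(lai: float, wf: float, params: CanopyParameters) -> float:
    """Relative green-leaf death rate, d⁻¹: max of shading and drought terms.

    Shading ramps linearly from zero at the critical LAI to ``rdr_max``
    at twice the critical LAI; drought contributes ``rdr_max·(1 − wf)``.
    """
    shade = params.rdr_max * _clamp01((lai - params.lai_crit) / params.lai_crit)
    drought = params.rdr_max * (1.0 - wf)
    return max(shade, drought)


def update_tillers(state: CanopyState, dtt: float, params: CanopyParameters) -> float:
    """New tiller density after one day of appearance and death.

    Site filling adds tillers while light reaches the sward base
    (LAI < critical); self-shading kills tillers at up to
    ``tiller_death_max`` per day once LAI exceeds the critical value.
    """
    if dtt < 0:
        raise DomainError(f"negative thermal time increment {dtt}")
    shading = _clamp01((state.lai - params.lai_crit) / params.lai_crit)
    appearance = 0.0
    if state.lai < params.lai_crit:
        appearance = state.tillers * params.site_filling * dtt / params.phyllochron
    death = state.tillers * params.tiller_death_max * shading
    return max(0.0, state.tillers + appearance - death)


def apply_canopy_fluxes(
    state: CanopyState,
    growth: float,
    fractions,  # management.PartitionFractions
    rdr: float,
    dtt: float,
    params: CanopyParameters,
) -> CanopyState:
    """Advance the canopy pools by one day of growth and senescence.

    Shoot growth ``growth·(1 − frac_root)`` is split between green leaf,
    stem and seed by the partition fractions; roots receive the rest.
    Senescence moves ``rdr·w_leaf_green`` from green to standing dead and
    removes the same relative amount of LAI; new leaf adds LAI at the
    specific leaf area.  Thermal time since the last cut accumulates.
    """
    s = fractions.f_leaf + fractions.f_stem + fractions.f_seed
    if abs(s - 1.0) > 1e-9:
        raise ConfigError(f"partition fractions sum to {s}, expected 1")
    if growth < 0 or rdr < 0 or dtt < 0:
        raise DomainError("growth, rdr and dtt must be >= 0")

    shoot_growth = growth * (1.0 - params.frac_root)
    d_leaf = shoot_growth * fractions.f_leaf
    d_stem = shoot_growth * fractions.f_stem
    d_seed = shoot_growth * fractions.f_seed
    dead_transfer = rdr * state.w_leaf_green

    return replace(
        state,
        w_leaf_green=state.w_leaf_green + d_leaf - dead_transfer,
        w_leaf_dead=state.w_leaf_dead + dead_transfer,
        w_stem=state.w_stem + d_stem,
        w_seed=state.w_seed + d_seed,
        w_root=state.w_root + growth * params.frac_root,
        lai=max(0.0, state.lai * (1.0 - rdr) + d_leaf * params.sla),
        tt_since_cut=state.tt_since_cut + dtt,
    )


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))
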