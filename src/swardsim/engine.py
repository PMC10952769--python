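"""Simulation engine: configuration, the daily loop, scans and outputs.

The engine wires the weather, canopy, water, nitrogen and management
modules into a fixed daily order of operations:

1.  apply the scenario temperature offset to the day's record;
2.  fertilizer applications due today enter the mineral pool at the
    fixed recovery fraction;
3.  mineralization moves N from the organic to the mineral pool;
4.  reference ET and the drought stress factor are computed;
5.  crop N demand, uptake and the N stress factor;
6.  source- and sink-limited growth and reserve arbitration;
7.  partitioning of growth, leaf death, LAI and tiller updates;
8.  the soil water balance advances;
9.  the harvest trigger is checked and a cut executed if due;
10. the daily record is emitted.

Mass balances for dry matter, water and nitrogen are accumulated through
the run and reported as closure residuals in the result, so every
simulation doubles as its own conservation check.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import canopy as cn
from . import management as mg
from . import nitrogen as ni
from . import water as wt
from . import weather as wx
from .errors import ConfigError, ContinuityError, NumericalError

__all__ = [
    "RunConfig",
    "SimulationState",
    "DailyRecord",
    "SimulationResult",
    "load_config",
    "step_day",
    "run_simulation",
    "scan_harvest_interval",
    "scan_n_rate",
    "summarize_annual",
]

log = logging.getLogger("swardsim")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything one simulation needs: site, soil, grass, management, window.

    Mirrors a control sheet split into "site and grass factors" and
    "management choices".  ``temperature_offset`` and ``co2`` are
    scenario levers applied uniformly over the run.
    """

    # site and grass factors
    latitude: float = 52.0
    co2: float = 400.0
    temperature_offset: float = 0.0
    canopy: cn.CanopyParameters = field(default_factory=cn.CanopyParameters)
    soil: wt.SoilWaterParameters = field(default_factory=wt.SoilWaterParameters)
    nitrogen: ni.NitrogenParameters = field(default_factory=ni.NitrogenParameters)
    partition_table: mg.PartitionTable = mg.DEFAULT_PARTITION_TABLE

    # management choices
    harvest: mg.HarvestRule = field(default_factory=mg.HarvestRule)
    fertilizer: tuple[tuple[dt.date, float], ...] = ()
    irrigated: int = 0

    # weather source: a file with a column mapping, or the synthetic generator
    weather_file: str | None = None
    weather_columns: Mapping[str, str] | None = None
    synthetic_climate: wx.SyntheticClimate = field(default_factory=wx.SyntheticClimate)

    # run window and bookkeeping
    year: int = 2021
    start: dt.date | None = None
    end: dt.date | None = None
    seed: int = 0
    output_dir: str | None = None

    # initial crop state
    init_lai: float = 0.5
    init_tillers: float = 4000.0
    init_reserves: float = 200.0

    def __post_init__(self):
        if self.co2 <= 0:
            raise ConfigError(f"co2 must be > 0, got {self.co2}")
        if self.irrigated not in (0, 1):
            raise ConfigError(f"irrigated must be 0 or 1, got {self.irrigated!r}")
        for d, amount in self.fertilizer:
            if amount < 0:
                raise ConfigError(f"negative fertilizer amount {amount} on {d}")

    @property
    def window(self) -> tuple[dt.date, dt.date]:
        start = self.start or dt.date(self.year, 1, 1)
        end = self.end or dt.date(self.year, 12, 31)
        if start > end:
            raise ConfigError(f"start {start} after end {end}")
        return start, end

    def build_weather(self) -> wx.WeatherSeries:
        if self.weather_file is not None:
            return wx.read_weather_table(self.weather_file, self.weather_columns)
        return wx.synthesize_weather(
            self.year, self.latitude, seed=self.seed, climate=self.synthetic_climate
        )

    def initial_state(self) -> "SimulationState":
        sla = self.canopy.sla
        w_green = self.init_lai / sla if sla > 0 else 0.0
        canopy_state = cn.CanopyState(
            lai=self.init_lai,
            tillers=self.init_tillers,
            w_leaf_green=w_green,
            reserves=self.init_reserves,
        )
        nstate = ni.NitrogenState(
            n_mineral=self.nitrogen.n_min_init,
            n_org_remaining=self.nitrogen.n_org_mineralisable,
            n_crop=self.nitrogen.ncrit_max / 100.0 * w_green,
        )
        wstate = wt.WaterState(soil_water=self.soil.initial_soil_water())
        return SimulationState(canopy=canopy_state, nitrogen=nstate, water=wstate)


def _parse_date(v) -> dt.date:
    if isinstance(v, dt.date):
        return v
    try:
        return dt.date.fromisoformat(str(v))
    except ValueError as exc:
        raise ConfigError(f"cannot parse date {v!r}: {exc}")


def _config_from_dict(d: Mapping[str, Any]) -> RunConfig:
    """Build a RunConfig from the nested config-file dictionary."""
    site = dict(d.get("site", {}))
    grass = dict(d.get("grass", {}))
    soil = dict(d.get("soil", {}))
    nitro = dict(d.get("nitrogen", {}))
    manage = dict(d.get("management", {}))
    weather_cfg = dict(d.get("weather", {}))
    run = dict(d.get("run", {}))

    if "temp_factor_table" in grass:
        grass["temp_factor_table"] = tuple(
            tuple(float(x) for x in row) for row in grass["temp_factor_table"]
        )
    partition = d.get("partition_table")
    partition_table = (
        tuple(tuple(float(x) for x in row) for row in partition)
        if partition
        else mg.DEFAULT_PARTITION_TABLE
    )

    harvest_cfg = dict(manage.get("harvest", {}))
    for key in ("window_start", "window_end"):
        if harvest_cfg.get(key) is not None:
            harvest_cfg[key] = _parse_date(harvest_cfg[key])
    if "dates" in harvest_cfg:
        harvest_cfg["dates"] = tuple(_parse_date(x) for x in harvest_cfg["dates"])
    fertilizer = tuple(
        (_parse_date(ev["date"]), float(ev["amount"]))
        for ev in manage.get("fertilizer", [])
    )

    synth = dict(weather_cfg.get("synthetic", {}))
    year = int(synth.pop("year", run.get("year", 2021)))
    climate = wx.SyntheticClimate(**synth) if synth else wx.SyntheticClimate()

    kwargs: dict[str, Any] = dict(
        latitude=float(site.get("latitude", 52.0)),
        co2=float(site.get("co2", 400.0)),
        temperature_offset=float(site.get("temperature_offset", 0.0)),
        canopy=cn.CanopyParameters(**grass),
        soil=wt.SoilWaterParameters(**soil),
        nitrogen=ni.NitrogenParameters(**nitro),
        partition_table=partition_table,
        harvest=mg.HarvestRule(**harvest_cfg),
        fertilizer=fertilizer,
        irrigated=int(manage.get("irrigated", 0)),
        weather_file=weather_cfg.get("file"),
        weather_columns=weather_cfg.get("columns"),
        synthetic_climate=climate,
        year=year,
        seed=int(run.get("seed", 0)),
        output_dir=run.get("output_dir"),
    )
    if run.get("start"):
        kwargs["start"] = _parse_date(run["start"])
    if run.get("end"):
        kwargs["end"] = _parse_date(run["end"])
    initial = dict(d.get("initial", {}))
    for key in ("init_lai", "init_tillers", "init_reserves"):
        short = key.removeprefix("init_")
        if short in initial:
            kwargs[key] = float(initial[short])
    return RunConfig(**kwargs)


def apply_overrides(d: dict, overrides: Sequence[str]) -> dict:
    """Apply ``section.key=value`` command-line overrides to a config dict."""
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form section.key=value")
        dotted, raw = item.split("=", 1)
        keys = dotted.split(".")
        node = d
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ConfigError(f"override {item!r} descends through a non-section")
        node[keys[-1]] = yaml.safe_load(raw)
    return d


def load_config(path=None, overrides: Sequence[str] = ()) -> RunConfig:
    """Load a YAML run configuration, apply overrides, fill defaults.

    With no path, the built-in defaults (synthetic UK weather, 28-day
    cutting, rainfed, no fertilizer) are used.
    """
    d: dict = {}
    if path is not None:
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
    if overrides:
        d = apply_overrides(d, overrides)
    return _config_from_dict(d)


# ---------------------------------------------------------------------------
# State bundle and records
# ---------------------------------------------------------------------------


@dataclass
class SimulationState:
    """All crop and soil pools at the end of a day, plus run accumulators."""

    canopy: cn.CanopyState
    nitrogen: ni.NitrogenState
    water: wt.WaterState
    cum_source: float = 0.0
    cum_growth: float = 0.0
    cum_discarded: float = 0.0
    last_cut_date: dt.date | None = None


@dataclass(frozen=True)
class DailyRecord:
    """One output row per simulated day."""

    date: dt.date
    tavg: float
    par: float
    et0: float
    lai: float
    tillers: float
    w_leaf_green: float
    w_leaf_dead: float
    w_stem: float
    w_seed: float
    w_root: float
    reserves: float
    soil_water: float
    n_mineral: float
    n_crop: float
    growth: float
    source: float
    sink: float
    wf: float
    nf: float
    tf: float
    evaporation: float
    transpiration: float
    irrigation: float
    drainage: float
    harvested: float


@dataclass
class SimulationResult:
    """Daily table, harvest events, annual summary and closure residuals."""

    daily: pd.DataFrame
    harvests: list[mg.HarvestEvent]
    summary: dict[str, float]
    balance: dict[str, float]
    config: RunConfig
    log_lines: list[str] = field(default_factory=list)

    def harvest_frame(self) -> pd.DataFrame:
        cols = [
            "date", "interval_days", "removed_green_leaf", "removed_stem",
            "removed_dead_leaf", "removed_seed", "removed_n",
        ]
        if not self.harvests:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([asdict(h) for h in self.harvests])[cols]


# ---------------------------------------------------------------------------
# The daily step
# ---------------------------------------------------------------------------


def _days_since_cut(
    state: SimulationState, date: dt.date, config: RunConfig, rule: mg.HarvestRule
) -> int:
    """Days since the previous cut, or since the window/season start.

    The first cut of the season measures its interval from the start of
    the cutting window (date-list mode: from the simulation start).
    """
    if state.last_cut_date is not None:
        return (date - state.last_cut_date).days
    if rule.mode == "date_list" or rule.window_start is None:
        return (date - config.window[0]).days
    return (date - rule.window_start).days


def step_day(
    state: SimulationState,
    rec: wx.WeatherRecord,
    config: RunConfig,
    rule: mg.HarvestRule | None = None,
) -> tuple[SimulationState, DailyRecord, mg.HarvestEvent | None]:
    """Advance all pools by one day in the fixed order of operations."""
    rule = rule or config.harvest
    p_can, p_soil, p_n = config.canopy, config.soil, config.nitrogen

    # (1) scenario temperature offset
    if config.temperature_offset:
        rec = replace(
            rec,
            tmin=rec.tmin + config.temperature_offset,
            tmax=rec.tmax + config.temperature_offset,
        )
    tavg = rec.tavg

    # (2) fertilizer due today enters the mineral pool at fixed recovery
    nstate = state.nitrogen
    for d, amount in config.fertilizer:
        if d == rec.date and amount > 0:
            nstate = replace(
                nstate,
                n_mineral=nstate.n_mineral + ni.fertilizer_to_mineral(amount, p_n),
                cum_fertilizer_applied=nstate.cum_fertilizer_applied + amount,
            )

    # (4, computed early: mineralization needs soil moisture) drought factor
    wf = (
        1.0
        if config.irrigated == 1
        else wt.transpiration_reduction(state.water.soil_water, p_soil)
    )
    et0 = wt.reference_evapotranspiration(rec, config.latitude)

    # (3) mineralization
    mineralized = ni.mineralization_rate(nstate.n_org_remaining, tavg, wf, p_n)
    nstate = replace(
        nstate,
        n_mineral=nstate.n_mineral + mineralized,
        n_org_remaining=nstate.n_org_remaining - mineralized,
        cum_mineralized=nstate.cum_mineralized + mineralized,
    )

    # (5) N demand, uptake, stress
    w_shoot = state.canopy.w_shoot_live
    demand = ni.n_demand(nstate, w_shoot, p_n)
    uptake = ni.n_uptake(demand, nstate.n_mineral, p_n)
    nstate = replace(
        nstate,
        n_mineral=nstate.n_mineral - uptake,
        n_crop=nstate.n_crop + uptake,
        cum_uptake=nstate.cum_uptake + uptake,
    )
    nf = ni.n_stress_factor(nstate.n_crop, w_shoot, p_n)

    # (6) source/sink growth and reserves
    par = wx.par_from_radiation(rec.radiation)
    tf = cn.temperature_factor(tavg, p_can)
    cf = cn.co2_factor(config.co2, p_can)
    dtt = max(0.0, tavg - p_can.t_base)
    source = cn.source_limited_growth(par, state.canopy.lai, tf, cf, wf, nf, p_can)
    sink = cn.sink_limited_growth(state.canopy, dtt, p_can)
    growth, new_reserves, discarded = cn.allocate_with_reserves(
        source, sink, state.canopy.reserves, p_can, state.canopy.w_aboveground
    )

    # (7) partitioning, pool updates, leaf death, tillering
    fractions = mg.partition_fractions(state.canopy.tt_since_cut, config.partition_table)
    rdr = cn.leaf_death_rate(state.canopy.lai, wf, p_can)
    canopy_state = replace(state.canopy, reserves=new_reserves)
    canopy_state = cn.apply_canopy_fluxes(canopy_state, growth, fractions, rdr, dtt, p_can)
    canopy_state = replace(canopy_state, tillers=cn.update_tillers(canopy_state, dtt, p_can))

    # (8) soil water balance (canopy of the day intercepts rain/light)
    wstate, fluxes = wt.step_water_balance(
        state.water, rec, state.canopy.lai, et0, config.irrigated, p_soil, p_can.k_ext
    )

    # (9) harvest trigger and execution
    event: mg.HarvestEvent | None = None
    new_last_cut = state.last_cut_date
    days_since = _days_since_cut(state, rec.date, config, rule)
    if mg.check_harvest_trigger(rule, rec.date, canopy_state.w_shoot_live, days_since):
        canopy_state, nstate, event = mg.execute_harvest(
            canopy_state, nstate, rec.date, max(1, days_since), rule.residual_weight
        )
        new_last_cut = rec.date

    # (10) emit the daily record
    record = DailyRecord(
        date=rec.date,
        tavg=tavg,
        par=par,
        et0=et0,
        lai=canopy_state.lai,
        tillers=canopy_state.tillers,
        w_leaf_green=canopy_state.w_leaf_green,
        w_leaf_dead=canopy_state.w_leaf_dead,
        w_stem=canopy_state.w_stem,
        w_seed=canopy_state.w_seed,
        w_root=canopy_state.w_root,
        reserves=canopy_state.reserves,
        soil_water=wstate.soil_water,
        n_mineral=nstate.n_mineral,
        n_crop=nstate.n_crop,
        growth=growth,
        source=source,
        sink=sink if math.isfinite(sink) else float("inf"),
        wf=wf,
        nf=nf,
        tf=tf,
        evaporation=fluxes["evaporation"],
        transpiration=fluxes["transpiration"],
        irrigation=fluxes["irrigation"],
        drainage=fluxes["drainage"],
        harvested=event.removed_total if event else 0.0,
    )
    for name in ("lai", "w_leaf_green", "soil_water", "n_mineral", "growth"):
        if not math.isfinite(getattr(record, name)):
            raise NumericalError(f"non-finite {name} on {rec.date}")

    new_state = SimulationState(
        canopy=canopy_state,
        nitrogen=nstate,
        water=wstate,
        cum_source=state.cum_source + source,
        cum_growth=state.cum_growth + growth,
        cum_discarded=state.cum_discarded + discarded,
        last_cut_date=new_last_cut,
    )
    return new_state, record, event


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


def run_simulation(
    config: RunConfig,
    weather: wx.WeatherSeries | None = None,
) -> SimulationResult:
    """Run one simulation over the configured window.

    ``weather`` may be passed to reuse a series across scenario runs;
    otherwise it is read or synthesized per the configuration.  The run
    log records every parameter value in effect (defaults included) and
    the closure residuals; the same config and seed give byte-identical
    outputs.
    """
    start, end = config.window
    series = weather if weather is not None else config.build_weather()
    if not series.covers(start, end):
        raise ContinuityError(
            f"weather covers {series.start}..{series.end}, "
            f"run window is {start}..{end}"
        )
    series = series.window(start, end)

    rule = mg.build_schedule(config.harvest, start.year)
    log_lines = _run_log_header(config, rule, series)

    state = config.initial_state()
    init = state
    init_pools = _pool_vector(init)

    records: list[DailyRecord] = []
    events: list[mg.HarvestEvent] = []
    for rec in series:
        state, record, event = step_day(state, rec, config, rule)
        records.append(record)
        if event is not None:
            events.append(event)

    daily = pd.DataFrame([asdict(r) for r in records])
    balance = _closures(init, init_pools, state, events, config)
    summary = _summaries(daily, events, state)
    for key, val in balance.items():
        log_lines.append(f"closure {key}: {val:.3e}")
    for key, val in summary.items():
        log_lines.append(f"summary {key}: {val:.4f}")

    result = SimulationResult(
        daily=daily,
        harvests=events,
        summary=summary,
        balance=balance,
        config=config,
        log_lines=log_lines,
    )
    if config.output_dir:
        _write_outputs(result, Path(config.output_dir))
    for line in log_lines:
        log.info(line)
    return result


def _pool_vector(state: SimulationState) -> dict[str, float]:
    c = state.canopy
    return {
        "dm": c.w_leaf_green + c.w_leaf_dead + c.w_stem + c.w_seed + c.w_root,
        "reserves": c.reserves,
        "soil_water": state.water.soil_water,
        "n_mineral": state.nitrogen.n_mineral,
        "n_org": state.nitrogen.n_org_remaining,
        "n_crop": state.nitrogen.n_crop,
    }


def _closures(
    init: SimulationState,
    init_pools: dict[str, float],
    state: SimulationState,
    events: list[mg.HarvestEvent],
    config: RunConfig,
) -> dict[str, float]:
    """Conservation residuals; all should vanish to round-off."""
    end = _pool_vector(state)
    removed_dm = sum(e.removed_total for e in events)
    removed_n = sum(e.removed_n for e in events)
    w = state.water
    n = state.nitrogen
    return {
        # growth in = pool change + harvest export
        "dry_matter": state.cum_growth - (end["dm"] - init_pools["dm"]) - removed_dm,
        # assimilation = growth + reserve change + discarded surplus
        "reserves": state.cum_source
        - state.cum_discarded
        - state.cum_growth
        - (end["reserves"] - init_pools["reserves"]),
        "water": (w.cum_rain + w.cum_irrigation)
        - (w.cum_evaporation + w.cum_transpiration + w.cum_drainage)
        - (end["soil_water"] - init_pools["soil_water"]),
        "n_mineral": (
            init_pools["n_mineral"]
            + n.cum_mineralized
            + config.nitrogen.n_recovery * n.cum_fertilizer_applied
        )
        - n.cum_uptake
        - end["n_mineral"],
        "n_crop": n.cum_uptake - (end["n_crop"] - init_pools["n_crop"]) - removed_n,
        "n_organic": init_pools["n_org"] - n.cum_mineralized - end["n_org"],
    }


def _summaries(
    daily: pd.DataFrame,
    events: list[mg.HarvestEvent],
    state: SimulationState | None = None,
) -> dict[str, float]:
    out = {
        "yield_green_leaf": sum(e.removed_green_leaf for e in events),
        "yield_stem": sum(e.removed_stem for e in events),
        "yield_dead_leaf": sum(e.removed_dead_leaf for e in events),
        "yield_seed": sum(e.removed_seed for e in events),
        "yield_total": sum(e.removed_total for e in events),
        "n_removed": sum(e.removed_n for e in events),
        "transpiration": float(daily["transpiration"].sum()),
        "evaporation": float(daily["evaporation"].sum()),
        "n_cuts": float(len(events)),
    }
    if state is not None:
        out["n_uptake"] = state.nitrogen.cum_uptake
    return out


def summarize_annual(result: SimulationResult) -> dict[str, float]:
    """Recompute the annual summary from the result's own tables.

    Component yields come from the harvest events; water and N totals
    from the daily table.  Matches ``result.summary`` exactly on the
    shared keys — used as a consistency hook.
    """
    return _summaries(result.daily, result.harvests)


def _run_log_header(
    config: RunConfig, rule: mg.HarvestRule, series: wx.WeatherSeries
) -> list[str]:
    lines = [
        f"run window {config.window[0]}..{config.window[1]}, "
        f"weather '{series.site_label}' ({len(series)} days)",
        f"site: latitude={config.latitude} co2={config.co2} "
        f"temperature_offset={config.temperature_offset}",
        f"et method: {'penman-monteith' if series.has_penman_inputs else 'priestley-taylor (no vapour pressure/wind in weather)'}",
        f"grass: {asdict(config.canopy)}",
        f"soil: {asdict(config.soil)}",
        f"nitrogen: {asdict(config.nitrogen)}",
        f"partition_table: {tuple(config.partition_table)}",
        f"harvest: {asdict(rule)}",
        f"fertilizer: {[(str(d), a) for d, a in config.fertilizer]}",
        f"irrigated: {config.irrigated}",
        f"initial: lai={config.init_lai} tillers={config.init_tillers} "
        f"reserves={config.init_reserves}",
        f"seed: {config.seed}",
    ]
    return lines


def _write_outputs(result: SimulationResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.daily.to_csv(outdir / "daily.csv", index=False)
    result.harvest_frame().to_csv(outdir / "harvests.csv", index=False)
    with open(outdir / "summary.txt", "w") as fh:
        for k, v in result.summary.items():
            fh.write(f"{k}\t{v:.6f}\n")
        for k, v in result.balance.items():
            fh.write(f"closure_{k}\t{v:.6e}\n")
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("\n".join(result.log_lines) + "\n")


# ---------------------------------------------------------------------------
# Scenario scans
# ---------------------------------------------------------------------------


def scan_harvest_interval(
    config: RunConfig,
    intervals: Sequence[int],
    weather: wx.WeatherSeries | None = None,
) -> pd.DataFrame:
    """Annual component yields as a function of the cutting interval.

    Runs one simulation per interval with everything else fixed (same
    weather, management and parameters) and returns a tidy table with one
    row per interval.  Duplicate intervals are dropped with a warning.
    """
    if any(i < 1 for i in intervals):
        raise ConfigError("harvest intervals must be >= 1 day")
    unique = sorted(set(int(i) for i in intervals))
    if len(unique) != len(intervals):
        warnings.warn("duplicate harvest intervals removed", stacklevel=2)
    series = weather if weather is not None else config.build_weather()
    rows = []
    for interval in unique:
        rule = replace(
            config.harvest,
            mode="fixed_interval",
            interval_days=interval,
        )
        cfg = replace(config, harvest=rule, output_dir=None)
        res = run_simulation(cfg, weather=series)
        rows.append(
            {
                "interval_days": interval,
                "yield_green_leaf": res.summary["yield_green_leaf"],
                "yield_stem": res.summary["yield_stem"],
                "yield_dead_leaf": res.summary["yield_dead_leaf"],
                "yield_seed": res.summary["yield_seed"],
                "yield_total": res.summary["yield_total"],
                "n_cuts": res.summary["n_cuts"],
            }
        )
    return pd.DataFrame(rows)


#: Default fertilizer split used by the N-rate scan when the base
#: configuration has no applications: a typical three-way split over the
#: growing season.
DEFAULT_N_SPLIT_DATES = ((3, 15), (5, 15), (7, 15))


def scan_n_rate(
    config: RunConfig,
    rates: Sequence[float],
    weather: wx.WeatherSeries | None = None,
) -> pd.DataFrame:
    """Annual yields and N use as a function of total fertilizer N rate.

    Each total rate is split across the configured application dates pro
    rata (keeping their relative sizes); with no applications configured,
    an equal three-way split on Mar 15 / May 15 / Jul 15 is used.
    """
    if any(r < 0 for r in rates):
        raise ConfigError("fertilizer rates must be >= 0")
    series = weather if weather is not None else config.build_weather()
    year = config.window[0].year
    base = config.fertilizer
    if not base:
        base = tuple((dt.date(year, m, d), 1.0) for m, d in DEFAULT_N_SPLIT_DATES)
    base_total = sum(a for _, a in base)
    rows = []
    for rate in rates:
        events = tuple((d, rate * a / base_total) for d, a in base)
        cfg = replace(config, fertilizer=events, output_dir=None)
        res = run_simulation(cfg, weather=series)
        rows.append(
            {
                "n_rate": float(rate),
                "yield_green_leaf": res.summary["yield_green_leaf"],
                "yield_total": res.summary["yield_total"],
                "n_removed": res.summary["n_removed"],
                "n_uptake": res.summary["n_uptake"],
            }
        )
    return pd.DataFrame(rows)
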