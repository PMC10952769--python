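"""Cutting management: shoot partitioning, harvest triggers, cut execution.

The management layer decides how new shoot growth is partitioned between
green leaf, stem and seed head — fractions interpolated over thermal
time accumulated since the last harvest, so a sward left to grow shifts
progressively from leaf to reproductive material — and when and how the
sward is cut.  Three trigger modes are offered: an explicit date list, a
standing-weight threshold (e.g. cut whenever the live shoot reaches
1500 kg DM ha⁻¹), and a fixed interval in days (e.g. every 20, 40 or 60
days within a cutting window).  A cut removes live shoot down to a
residual standing weight; stems are removed at the same proportion as
green leaf, and dead leaf is picked up as by-catch at a
fraction of the removed live material that depends on the harvest
interval: zero below 21 days, 0.0035·(HI − 21) between 21 and 70 days,
and a plateau of 0.1715 beyond 70 days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Sequence

from .canopy import CanopyState
from .errors import ConfigError, DomainError
from .nitrogen import NitrogenState

__all__ = [
    "PartitionFractions",
    "PartitionTable",
    "DEFAULT_PARTITION_TABLE",
    "HarvestRule",
    "HarvestEvent",
    "partition_fractions",
    "dead_leaf_harvest_fraction",
    "check_harvest_trigger",
    "execute_harvest",
    "build_schedule",
]

#: Dead-leaf by-catch constants: no dead leaf is picked up for harvest
#: intervals shorter than 21 days; the fraction rises at 0.0035 per day of
#: interval and plateaus at 0.1715 for intervals above 70 days.
DEAD_LEAF_HI_MIN = 21.0
DEAD_LEAF_HI_MAX = 70.0
DEAD_LEAF_SLOPE = 0.0035
DEAD_LEAF_PLATEAU = 0.1715


@dataclass(frozen=True)
class PartitionFractions:
    """Shares of daily shoot growth going to leaf, stem and seed."""

    f_leaf: float
    f_stem: float
    f_seed: float

    def __post_init__(self):
        for name in ("f_leaf", "f_stem", "f_seed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        s = self.f_leaf + self.f_stem + self.f_seed
        if abs(s - 1.0) > 1e-9:
            raise ConfigError(f"partition fractions sum to {s}, expected 1")


#: (thermal time °Cd, f_leaf, f_stem, f_seed) anchor rows; linearly
#: interpolated, last row held beyond the final anchor.  Young regrowth is
#: almost all leaf; as regrowth matures, stem extension takes over the
#: marginal allocation and, beyond ~800 °Cd uncut, new shoot growth is
#: nearly all stem and inflorescence — the behaviour of a sward running to
#: head.  Calibrated so that sweeping the cutting interval reproduces the
#: classic defoliation response: green-leaf yield peaks at an intermediate
#: interval while total harvestable dry matter approaches a plateau.
DEFAULT_PARTITION_TABLE: tuple[tuple[float, float, float, float], ...] = (
    (0.0, 0.92, 0.08, 0.00),
    (150.0, 0.62, 0.38, 0.00),
    (300.0, 0.30, 0.58, 0.12),
    (520.0, 0.14, 0.66, 0.20),
    (800.0, 0.08, 0.70, 0.22),
)

PartitionTable = Sequence[tuple[float, float, float, float]]


def _validate_partition_table(table: PartitionTable) -> None:
    if len(table) < 1:
        raise ConfigError("partition table must have at least one row")
    tts = [row[0] for row in table]
    if any(b <= a for a, b in zip(tts, tts[1:])):
        raise ConfigError("partition table thermal times must strictly increase")
    for row in table:
        if len(row) != 4:
            raise ConfigError(f"partition table row {row!r} must have 4 entries")
        if abs(sum(row[1:]) - 1.0) > 1e-9:
            raise ConfigError(f"partition table row {row!r} fractions do not sum to 1")


def partition_fractions(
    tt_since_cut: float,
    table: PartitionTable = DEFAULT_PARTITION_TABLE,
) -> PartitionFractions:
    """Interpolate the leaf/stem/seed split at a given thermal time.

    Piecewise linear between anchor rows; held constant beyond the last
    anchor.  Rows sum to 1 so the interpolant does too.
    """
    if tt_since_cut < 0:
        raise DomainError(f"negative thermal time {tt_since_cut}")
    _validate_partition_table(table)
    if tt_since_cut <= table[0][0]:
        _, fl, fs, fd = table[0]
        return PartitionFractions(fl, fs, fd)
    if tt_since_cut >= table[-1][0]:
        _, fl, fs, fd = table[-1]
        return PartitionFractions(fl, fs, fd)
    for r0, r1 in zip(table, table[1:]):
        if r0[0] <= tt_since_cut <= r1[0]:
            w = (tt_since_cut - r0[0]) / (r1[0] - r0[0])
            fl, fs, fd = (a + w * (b - a) for a, b in zip(r0[1:], r1[1:]))
            # renormalize away interpolation round-off
            s = fl + fs + fd
            return PartitionFractions(fl / s, fs / s, fd / s)
    raise AssertionError("unreachable")  # pragma: no cover


def dead_leaf_harvest_fraction(interval_days: float) -> float:
    """Dead leaf removed at a cut, as a fraction of removed live material.

    Zero below a harvest interval of 21 days, 0.0035·(HI − 21) between 21
    and 70 days, 0.1715 above 70 days; continuous at both breakpoints.
    """
    if interval_days <= 0:
        raise DomainError(f"non-positive harvest interval {interval_days}")
    if interval_days < DEAD_LEAF_HI_MIN:
        return 0.0
    if interval_days > DEAD_LEAF_HI_MAX:
        return DEAD_LEAF_PLATEAU
    return DEAD_LEAF_SLOPE * (interval_days - DEAD_LEAF_HI_MIN)


# ---------------------------------------------------------------------------
# Harvest rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarvestRule:
    """When to cut: explicit dates, a weight threshold, or a fixed interval.

    Exactly one mode is active.  ``residual_weight`` is the live-shoot
    (green leaf + stem) standing weight deliberately left after every cut
    (the cutting intensity, expressed as weight rather than LAI).  Modes
    2 and 3 operate inside [window_start, window_end].
    """

    mode: str = "fixed_interval"
    dates: tuple[dt.date, ...] = ()
    threshold: float = 1500.0          #: kg DM ha⁻¹ (weight mode)
    interval_days: int = 28            #: days (interval mode)
    window_start: dt.date | None = None
    window_end: dt.date | None = None
    residual_weight: float = 500.0     #: kg DM ha⁻¹ left standing
    final_cut: bool = True             #: clearing cut at window_end (modes 2–3)

    def __post_init__(self):
        if self.mode not in ("date_list", "weight_threshold", "fixed_interval"):
            raise ConfigError(f"unknown harvest mode {self.mode!r}")
        if self.residual_weight < 0:
            raise ConfigError("residual_weight must be >= 0")
        if self.mode == "weight_threshold" and self.threshold <= self.residual_weight:
            raise ConfigError(
                f"threshold ({self.threshold}) must exceed residual_weight "
                f"({self.residual_weight})"
            )
        if self.mode == "fixed_interval" and self.interval_days < 1:
            raise ConfigError("interval_days must be >= 1")
        if (
            self.window_start is not None
            and self.window_end is not None
            and self.window_start >= self.window_end
        ):
            raise ConfigError("window_start must precede window_end")


def build_schedule(rule: HarvestRule, year: int) -> HarvestRule:
    """Validate and normalize a harvest rule for one simulation year.

    Date lists are sorted and checked for duplicates and out-of-year
    entries; windowed modes get a default Apr 1 – Oct 31 cutting window
    when none is configured (a typical temperate silage season).
    """
    if rule.mode == "date_list":
        if not rule.dates:
            raise ConfigError("date_list mode requires a non-empty date list")
        if len(set(rule.dates)) != len(rule.dates):
            raise ConfigError("duplicate dates in harvest date list")
        for d in rule.dates:
            if d.year != year:
                raise ConfigError(f"harvest date {d} outside simulation year {year}")
        return replace(rule, dates=tuple(sorted(rule.dates)))
    ws = rule.window_start or dt.date(year, 4, 1)
    we = rule.window_end or dt.date(year, 10, 31)
    if ws >= we:
        raise ConfigError("window_start must precede window_end")
    return replace(rule, window_start=ws, window_end=we)


def check_harvest_trigger(
    rule: HarvestRule,
    date: dt.date,
    standing_harvestable: float,
    days_since_cut: int,
) -> bool:
    """Decide whether the sward is cut today (at most one cut per day).

    ``standing_harvestable`` is the live shoot (green leaf + stem)
    standing weight; dead leaf is excluded from the trigger and only
    enters as by-catch at the cut itself.

    Windowed modes take a clearing cut on the last day of the window
    when ``final_cut`` is set (standard cutting-trial practice, so the
    season's last regrowth is measured rather than left standing).
    """
    if rule.mode == "date_list":
        return date in rule.dates
    in_window = (
        rule.window_start is not None
        and rule.window_end is not None
        and rule.window_start <= date <= rule.window_end
    )
    if not in_window:
        return False
    if rule.final_cut and date == rule.window_end and days_since_cut > 0:
        return True
    if rule.mode == "weight_threshold":
        return standing_harvestable >= rule.threshold
    return days_since_cut == rule.interval_days


@dataclass(frozen=True)
class HarvestEvent:
    """Removals of one cut, by component, plus the interval that produced it."""

    date: dt.date
    interval_days: int
    removed_green_leaf: float
    removed_stem: float
    removed_dead_leaf: float
    removed_seed: float
    removed_n: float

    @property
    def removed_total(self) -> float:
        return (
            self.removed_green_leaf
            + self.removed_stem
            + self.removed_dead_leaf
            + self.removed_seed
        )


def execute_harvest(
    canopy: CanopyState,
    nstate: NitrogenState,
    date: dt.date,
    interval_days: int,
    residual_weight: float,
) -> tuple[CanopyState, NitrogenState, HarvestEvent]:
    """Cut the sward down to the residual standing weight.

    The live shoot (green leaf + stem — the same quantity the weight
    trigger watches) is cut to ``residual_weight``; the single removal
    proportion p = (live − residual)/live applies equally to green leaf,
    stem and seed head, so harvested herbage has the standing sward's
    live composition.  Dead leaf is removed as by-catch at
    ``dead_leaf_harvest_fraction(interval)`` of the removed live
    material, capped at the standing dead pool.  LAI is scaled by
    (1 − p), thermal time since cut resets to zero, and shoot N is
    exported pro rata (p · crop N).  A sward at or below the residual
    yields a recorded no-op event with zero removals.
    """
    if residual_weight < 0:
        raise ConfigError("residual_weight must be >= 0")
    live = canopy.w_leaf_green + canopy.w_stem
    p = 0.0
    if live > residual_weight and live > 0:
        p = (live - residual_weight) / live

    removed_green = p * canopy.w_leaf_green
    removed_stem = p * canopy.w_stem
    removed_seed = p * canopy.w_seed
    dead_frac = dead_leaf_harvest_fraction(max(1, interval_days))
    removed_dead = min(
        dead_frac * (removed_green + removed_stem), canopy.w_leaf_dead
    )
    removed_n = p * nstate.n_crop

    new_canopy = replace(
        canopy,
        w_leaf_green=canopy.w_leaf_green - removed_green,
        w_stem=canopy.w_stem - removed_stem,
        w_seed=canopy.w_seed - removed_seed,
        w_leaf_dead=canopy.w_leaf_dead - removed_dead,
        lai=canopy.lai * (1.0 - p),
        tt_since_cut=0.0,
    )
    new_nstate = replace(
        nstate,
        n_crop=nstate.n_crop - removed_n,
        cum_removed=nstate.cum_removed + removed_n,
    )
    event = HarvestEvent(
        date=date,
        interval_days=interval_days,
        removed_green_leaf=removed_green,
        removed_stem=removed_stem,
        removed_dead_leaf=removed_dead,
        removed_seed=removed_seed,
        removed_n=removed_n,
    )
    return new_canopy, new_nstate, event
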