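"""Soil mineral nitrogen, crop N demand and uptake, and N growth stress.

The nitrogen extension tracks a single soil mineral-N pool fed by
first-order mineralization of a finite mineralisable organic-N pool
(temperature dependence as a Q₁₀ response around 10 °C, slowed by soil
dryness) and by fertilizer applications of which a fixed recovery
fraction — 0.7 by default — becomes available; the remaining 30% is
treated as unavailable and never enters any pool (no leaching or other
loss pathways are represented).  Crop demand follows a critical
N-dilution curve: the critical shoot N concentration is constant up to
1 t DM ha⁻¹ of live shoot and declines as a power of shoot mass beyond
it.  Daily uptake is the least of demand, the mineral pool, and a
maximum uptake rate.  Growth stress is the nitrogen nutrition index
(actual over critical shoot N concentration) clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError, DomainError

__all__ = [
    "NitrogenParameters",
    "NitrogenState",
    "fertilizer_to_mineral",
    "mineralization_rate",
    "critical_n_concentration",
    "n_demand",
    "n_uptake",
    "n_stress_factor",
]


@dataclass(frozen=True)
class NitrogenParameters:
    """Soil and crop nitrogen constants.

    ``n_recovery`` is the fixed fraction of applied fertilizer N that
    reaches the plant-available mineral pool.  The dilution-curve
    constants (``ncrit_a``, ``ncrit_b``) follow the classical critical
    N-dilution curve for C3 grasses.
    """

    n_recovery: float = 0.7        #: fertilizer recovery fraction
    n_min_init: float = 20.0       #: initial soil mineral N, kg N ha⁻¹
    n_org_mineralisable: float = 120.0  #: mineralisable organic N, kg N ha⁻¹
    k_mineralization: float = 0.002     #: first-order rate at 10 °C, d⁻¹
    q10: float = 2.0               #: temperature sensitivity (ref 10 °C)
    ncrit_a: float = 4.8           #: critical N% at 1 t DM ha⁻¹ shoot
    ncrit_b: float = 0.32          #: dilution exponent
    ncrit_max: float = 4.8         #: ceiling N%
    max_uptake: float = 8.0        #: kg N ha⁻¹ d⁻¹

    def __post_init__(self):
        if not 0.0 <= self.n_recovery <= 1.0:
            raise ConfigError(f"n_recovery={self.n_recovery} outside [0, 1]")
        for name in ("n_min_init", "n_org_mineralisable", "k_mineralization",
                     "q10", "ncrit_a", "ncrit_b", "ncrit_max", "max_uptake"):
            if getattr(self, name) < 0:
                raise ConfigError(f"nitrogen parameter {name} must be >= 0")


@dataclass
class NitrogenState:
    n_mineral: float               #: plant-available soil mineral N, kg N ha⁻¹
    n_org_remaining: float         #: undecomposed mineralisable organic N
    n_crop: float = 0.0            #: N in live shoot (green leaf + stem)
    cum_uptake: float = 0.0
    cum_fertilizer_applied: float = 0.0
    cum_mineralized: float = 0.0
    cum_removed: float = 0.0       #: N exported in harvests


def fertilizer_to_mineral(applied: float, params: NitrogenParameters) -> float:
    """Mineral-N increment from a fertilizer application.

    A fixed proportion ``n_recovery`` (default 0.7) of the applied N
    enters the available pool; the remainder never appears anywhere.
    """
    if applied < 0:
        raise ConfigError(f"negative fertilizer application {applied}")
    return params.n_recovery * applied


def mineralization_rate(
    n_org_remaining: float,
    tavg: float,
    wf: float,
    params: NitrogenParameters,
) -> float:
    """Daily N mineralization from the organic pool, kg N ha⁻¹ d⁻¹.

    First-order in the remaining pool with a Q₁₀ temperature response
    referenced to 10 °C; soil moisture slows it via max(wf, 0.2) so
    mineralization never stops completely.  Never exceeds the pool.
    """
    if n_org_remaining < 0:
        raise DomainError("negative organic N pool")
    wf_soil = max(wf, 0.2)
    rate = (
        params.k_mineralization
        * n_org_remaining
        * params.q10 ** ((tavg - 10.0) / 10.0)
        * wf_soil
    )
    return min(rate, n_org_remaining)


def critical_n_concentration(w_shoot: float, params: NitrogenParameters) -> float:
    """Critical shoot N concentration (%) from the dilution curve.

    Constant at ``ncrit_max`` up to 1 t DM ha⁻¹ live shoot, then
    ``ncrit_a · (W/1000)^(−ncrit_b)`` capped at the ceiling; monotone
    non-increasing in shoot mass.
    """
    if w_shoot < 0:
        raise DomainError("negative shoot mass")
    if w_shoot <= 1000.0:
        return params.ncrit_max
    return min(params.ncrit_max, params.ncrit_a * (w_shoot / 1000.0) ** (-params.ncrit_b))


def n_demand(state: NitrogenState, w_shoot: float, params: NitrogenParameters) -> float:
    """Shoot N deficit relative to the critical curve, kg N ha⁻¹ d⁻¹ (≥ 0)."""
    target = critical_n_concentration(w_shoot, params) / 100.0 * w_shoot
    return max(0.0, target - state.n_crop)


def n_uptake(demand: float, n_mineral: float, params: NitrogenParameters) -> float:
    """Daily crop N uptake: min(demand, mineral pool, max uptake rate)."""
    if demand < 0 or n_mineral < 0:
        raise DomainError("demand and mineral pool must be >= 0")
    return min(demand, n_mineral, params.max_uptake)


def n_stress_factor(n_crop: float, w_shoot: float, params: NitrogenParameters) -> float:
    """Nitrogen nutrition index clamped to [0, 1]; 1 for an empty sward.

    NNI = (actual shoot N%) / (critical shoot N%); growth scales linearly
    with NNI below the critical curve and is unaffected above it.
    """
    if n_crop < 0 or w_shoot < 0:
        raise DomainError("n_crop and shoot mass must be >= 0")
    if w_shoot == 0.0:
        return 1.0
    actual_pct = n_crop / w_shoot * 100.0
    crit_pct = critical_n_concentration(w_shoot, params)
    if crit_pct <= 0:
        return 1.0
    return min(1.0, max(0.0, actual_pct / crit_pct))
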