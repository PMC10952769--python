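# Methods

## Scope and model structure

swardsim simulates one sward of perennial ryegrass through a calendar
year on a daily timestep, with forward-Euler (explicit, 1-day step)
integration of all state pools.  The daily order of operations is fixed
and logged with every run:

1. the scenario temperature offset is applied to the day's weather;
2. fertilizer due today enters the soil mineral-N pool at the fixed
   recovery fraction;
3. mineralization transfers N from the organic to the mineral pool;
4. reference evapotranspiration and the drought factor are computed
   from the state at the start of the day;
5. crop N demand, uptake and the N stress factor;
6. source- and sink-limited growth and reserve arbitration;
7. growth partitioning, leaf senescence, LAI and tiller updates;
8. the soil water balance advances;
9. the harvest trigger is checked and a cut executed if due;
10. the daily record is emitted.

Because the step is explicit, quantities computed early in the day (the
stress factors, ET partition) see the previous day's canopy; this is the
usual convention in daily crop models and is part of the documented
contract rather than a tunable.

## Growth

Daily assimilation is light-use efficiency times intercepted PAR,

G_source = 10 · PAR · (1 − e^(−k·LAI)) · LUE · f(T) · f(CO₂) · min(f_W, f_N),

with PAR taken as a fixed 0.5 of global radiation.  Water and nitrogen
stress couple through their minimum (Liebig), not their product: the
model treats them as alternative bottlenecks on the same machinery.

The sink is the leaf area the tiller population can expand:
dLAI = tillers · LER · dTT · leaf width (dimensionless, m² leaf per m²
ground), converted to mass as dLAI / SLA.  When source exceeds sink the
surplus tops up a carbohydrate reserve pool capped at 20% of standing
above-ground DM; assimilate beyond the cap is discarded as unrealized
(down-regulation), which keeps the arbitration well defined.  When sink
exceeds source, reserves are remobilized at up to 80 kg DM ha⁻¹ d⁻¹.
Exact book-keeping identity, checked every run:
Σsource − Σdiscarded = Σgrowth + Δreserves.

Leaf death is rdr = max(shading, drought) with the shading term ramping
linearly from 0 at the critical LAI (4) to the maximum rate (0.05 d⁻¹)
at twice the critical LAI, and drought contributing rdr_max·(1 − f_W).
Dead leaf remains standing until harvested; the model does not decompose
standing dead within the year.

### Key canopy parameters

| parameter | default | units | role |
|---|---|---|---|
| LUE (reference) | 3.0 | g DM MJ⁻¹ PAR | slope of growth on intercepted light |
| k (extinction) | 0.6 | – | canopy light capture |
| SLA | 0.0025 | ha kg⁻¹ | converts leaf DM to LAI |
| T_base | 3.0 | °C | thermal-time base |
| temperature response | (3,0) (10,1) (25,1) (35,0) | °C → [0,1] | piecewise-linear LUE modifier |
| LAI_crit | 4.0 | – | onset of self-shading death and tiller loss |
| rdr_max | 0.05 | d⁻¹ | maximum relative leaf death rate |
| phyllochron | 110 | °Cd | leaf-appearance interval |
| site filling | 0.693 | tiller⁻¹ phyllochron⁻¹ | tillering while the base is lit |
| LER slope | 0.00083 | m °Cd⁻¹ tiller⁻¹ | sink-side elongation |
| root fraction | 0.30 | – | fixed below-ground allocation |
| CO₂ response | 1 + 0.8·ln(CO₂/360) | – | log response of LUE |

These are generic published values for ryegrass in this model family;
all are configurable and the run log echoes the values in effect.

## Partitioning and harvest

New shoot growth (70% of total) is split between green leaf, stem and
seed head by piecewise-linear interpolation over thermal time since the
last cut.  The default table,

| °Cd since cut | leaf | stem | seed |
|---|---|---|---|
| 0 | 0.92 | 0.08 | 0.00 |
| 150 | 0.62 | 0.38 | 0.00 |
| 300 | 0.30 | 0.58 | 0.12 |
| 520 | 0.14 | 0.66 | 0.20 |
| ≥800 | 0.08 | 0.70 | 0.22 |

describes a sward running to head: young regrowth is nearly all leaf,
and once stem extension starts the marginal allocation shifts rapidly to
stem and inflorescence.  The table was calibrated — it is the one
genuinely free function in the model — so that sweeping the cutting
interval reproduces the classic defoliation response: green-leaf yield
peaks at an intermediate interval (cut too often and regrowth cannot
recover; too rarely and leaves die standing), while total harvestable
DM rises to a plateau because stem, which does not senesce, replaces
leaf in the harvest.  A leafier table (e.g. 50% leaf beyond 900 °Cd)
shifts composition toward leaf but lets self-shading losses erode total
yield at long intervals.

A cut removes the live shoot (green leaf + stem, the same quantity the
weight trigger watches) down to the residual standing weight (default
500 kg DM ha⁻¹); the single proportion p = (live − residual)/live
applies equally to green leaf, stem and seed, so harvested herbage has
the standing sward's live composition.  Basing the residual on green
leaf alone was considered and rejected: it strands the entire
above-residual stem pool in proportion as swards get stemmy, producing
an artificial collapse of total yield at long cutting intervals.  Dead
leaf is by-catch: zero below a 21-day harvest interval, 0.0035·(HI−21)
for 21–70 days, 0.1715 above — continuous at both breakpoints — applied
to the removed live mass and capped at the standing dead pool.

Three triggers: an explicit date list; a standing-weight threshold
compared against live shoot (dead leaf excluded — it is picked up only
at a cut); a fixed interval counted from the previous cut (first cut:
from the window start).  Windowed modes default to an Apr 1 – Oct 31
cutting season and take a clearing cut on the window's last day
(`final_cut`, on by default), standard cutting-trial practice; without
it the comparison between intervals is confounded by how much regrowth
each schedule happens to strand at season's end.  A scheduled cut that
finds the sward at or below the residual is recorded as a zero-removal
event and still resets the thermal-time and interval counters (the
mower passed).

## Water

Single-layer tipping bucket of depth = rooting depth, bounded by wilting
point and field capacity; runoff is merged into drainage and any excess
above field capacity leaves the same day.  ET₀ is FAO-56
Penman–Monteith when the weather series carries vapour pressure and
wind, else Priestley–Taylor (α = 1.26) on the same net-radiation
estimate with actual vapour pressure proxied by saturation at tmin; the
choice is recorded in the run log.  ET₀ splits into soil evaporation
e^(−k·LAI)·ET₀ (no surface-dryness memory — a logged simplification)
and transpiration demand fInt·ET₀ scaled by f_W; joint extraction is
capped so the profile never falls below wilting point.  f_W ramps
linearly from 1 to 0 over the lower `crit_fraction` (default 0.5) of
plant-available water.  Irrigation (flag = 1) refills to field capacity
whenever f_W would otherwise drop below 1 — ideal irrigation, no
scheduling — so irrigated runs have f_W = 1 throughout.

## Nitrogen

The mineral pool receives 70% of each fertilizer application — the
fixed recovery fraction — with the other 30% treated as never entering
the system (no leaching, denitrification or volatilization is
represented), plus first-order mineralization of a finite organic pool:
k (0.002 d⁻¹ at 10 °C) × pool × Q₁₀^((T−10)/10) × max(f_W, 0.2).
Demand is the deficit of shoot N against the critical dilution curve
(4.8% up to 1 t DM ha⁻¹ live shoot, then 4.8·(W/1000)^−0.32); uptake is
the triple minimum of demand, pool and 8 kg N ha⁻¹ d⁻¹; the growth
factor f_N is the nitrogen nutrition index clamped to [0, 1], linear by
default.  Senescing leaves resorb their N into the live shoot (dead
leaf carries none), which is what closes the crop-N balance exactly:
Σuptake = Δcrop N + harvested N, with harvest exporting p × crop N.
Roots hold no tracked N.

## Synthetic weather

The generator emulates a temperate maritime lowland climate: daily mean
temperature = 9.5 + 6.5·cos(2π(doy − 200)/365.25) °C plus AR(1)
anomalies (σ = 1.5 °C, ρ = 0.6, clipped at ±8 °C); a fixed 7.5 °C
diurnal range; rainfall occurrence from a two-state Markov chain
(P(wet|dry) = 0.30, P(wet|wet) = 0.62 → ~44% wet days) with gamma
amounts (shape 0.85, mean 4.3 mm → ~690 mm yr⁻¹); radiation =
extraterrestrial × a transmissivity drawn uniformly from 0.50–0.75 on
dry days and 0.15–0.40 on wet days, capped at the 0.75 clear-sky
ceiling.  It reproduces seasonal cycles, realistic annual totals and
wet/dry persistence; it does not reproduce heat waves or multi-week
blocking droughts (temperature and rainfall are independent beyond the
radiation link), frontal structure, or inter-annual trends.  Properties
demonstrated on it therefore speak to ordinary year-to-year variation,
not to extreme-event response.

## Numerical and degenerate-input choices

- All pools are plain double precision; conservation residuals (dry
  matter, reserves, water, mineral/crop/organic N) are accumulated per
  run and reported; the test suite requires < 1e-6 kg ha⁻¹ (DM), 1e-6 mm
  (water) and 1e-9 kg ha⁻¹ (N).
- SLA = 0 is accepted and pins LAI at its initial value with an
  unbounded sink — the configuration used to verify the analytic
  light-limited ceiling 10·LUE·Σ(PAR·fInt) exactly.
- Empty swards: f_N = 1 for zero shoot (no stress on nothing); cuts on
  swards at/below the residual are zero-removal events; the temperature
  factor is clamped to its end anchors outside the table.
- Ties: a weight-threshold cut fires at exactly the threshold; the
  clearing cut fires even if a scheduled cut already occurred earlier in
  the window on the same day counter, but at most one cut happens per day.
- Non-finite state aborts the run naming the quantity and date.

## Typical problem sizes

One simulated year is 365 daily steps (~20 ms); the test-suite scans use
100 weather seeds × 8 cutting intervals, 100 irrigation pairs, and
5-seed fertilizer sweeps, chosen to estimate the stochastic properties
tightly while keeping the whole suite under a minute of compute.

## Known limitations

- **Potential yield is high.**  With the generic parameterization and
  no stress, annual growth reaches ~35–45 t DM ha⁻¹ and harvests
  20–25 t — roughly double intensively managed UK swards — because the
  temperature response is fully open from 10 °C and tillering is
  uncapped.  Qualitative responses (interval optimum, N response shape,
  irrigation contrast) are the model's purpose; absolute magnitudes
  should be calibrated per site before quantitative use.  One
  consequence: crop N demand at potential is ~600–800 kg N ha⁻¹ yr⁻¹,
  so a 400 kg fertilizer rate saturates the yield response only where
  background soil supply is substantial (the N-response demonstration
  uses an organic-rich lowland soil, 80 kg initial mineral N and 800 kg
  mineralisable organic N) or where water caps demand.
- No winter kill or frost damage; no grazing (continuous defoliation);
  no forage quality; single species; no multi-layer soil, capillary
  rise or snow; no N leaching or gaseous losses; no soil C dynamics.
- Standing dead neither decomposes nor shades (LAI counts green leaf
  only).
- Reserve dynamics are a single aggregated pool with a mass-fraction
  cap; no explicit stubble or crown morphology.
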