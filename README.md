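# swardsim

A daily-timestep simulator of perennial ryegrass (*Lolium perenne*)
dry-matter production under weather, soil water, soil nitrogen and
cutting management, for teaching and scenario exploration in grassland
agronomy: how do cutting frequency, fertilizer N rate, irrigation, soil
depth, CO₂ and warming change the yield and composition of harvested
herbage?

## The model

Growth follows the light-use-efficiency family of grass models.  Each
day the sward assimilates

```
G_source = 10 · PAR · (1 − e^(−k·LAI)) · LUE · f(T) · f(CO₂) · min(f_W, f_N)
```

kg DM ha⁻¹ d⁻¹ (PAR in MJ m⁻² d⁻¹; LUE = 3.0 g DM MJ⁻¹ at reference
conditions; k = 0.6), but realized growth is capped by the *sink* — the
leaf-area expansion the tiller population can support, tillers × leaf
elongation rate × thermal time × leaf width, converted to mass by the
specific leaf area.  Surplus assimilate is buffered in a capped
carbohydrate reserve pool and remobilized (≤ 80 kg ha⁻¹ d⁻¹) to fuel
regrowth after cutting.  Leaves senesce under self-shading (LAI above a
critical value of 4) and drought; tillers appear by site filling while
light reaches the sward base and die back under shading.

Around this core:

* **Water** — a single-layer root-zone bucket between wilting point and
  field capacity; FAO-56 Penman–Monteith reference ET when vapour
  pressure and wind are available, Priestley–Taylor otherwise; the
  drought factor f_W ramps linearly over the plant-available water; the
  irrigation switch (1/0) refills the profile whenever stress would
  otherwise occur.
* **Nitrogen** — a soil mineral-N pool fed by Q₁₀ first-order
  mineralization of a finite organic pool and by fertilizer, of which a
  fixed 70% is recovered; crop demand follows a critical N-dilution
  curve (4.8% up to 1 t DM ha⁻¹ shoot, declining as W^−0.32); daily
  uptake = min(demand, pool, 8 kg ha⁻¹); f_N is the nitrogen nutrition
  index clamped to [0, 1].
* **Management** — shoot growth is partitioned between leaf, stem and
  seed head as a function of thermal time since the last cut; harvests
  trigger on a date list, a standing-weight threshold (e.g.
  1500 kg DM ha⁻¹), or a fixed interval (e.g. every 20/40/60 days); a
  cut removes live shoot down to a residual (default 500 kg DM ha⁻¹),
  stems at the same proportion as green leaf, and dead leaf as by-catch
  at a fraction of the removed live material that is 0 below a 21-day
  harvest interval, 0.0035·(HI − 21) up to 70 days, then 0.1715.
* **Weather** — delimited-text daily tables (explicit column mapping),
  or a built-in stochastic generator for temperate maritime climate
  (sinusoidal temperature + bounded AR(1) noise, clear-sky radiation
  ceiling scaled by cloudiness, two-state Markov rainfall with gamma
  wet-day amounts).

Dry matter, water and nitrogen balances are closed exactly; every run
reports its closure residuals.  See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

Simulate one year of irrigated, well-fertilized grass on synthetic UK
weather, cut every 28 days:

```sh
swardsim run --seed 7 --quiet \
  -O management.irrigated=1 \
  -O nitrogen.n_min_init=150 \
  -O "management.fertilizer=[{date: 2021-03-15, amount: 100},
      {date: 2021-05-15, amount: 100}, {date: 2021-07-15, amount: 100}]"
```

prints the annual summary (kg DM ha⁻¹ unless noted):

```
yield_green_leaf    9025.53
yield_stem          6610.12
yield_dead_leaf      336.07
yield_seed           611.17
yield_total        16582.89
n_removed            419.84
transpiration        426.45
evaporation          179.55
n_cuts                 8.00
n_uptake             422.18
```

Eight cuts remove 16.6 t DM ha⁻¹ over the season, a bit over half of it
as green leaf; the sward transpires 426 mm and exports 420 kg N ha⁻¹
(high because irrigation plus 300 kg fertilizer N on a fertile soil
keeps the crop at its critical N concentration).  A cutting-interval
scan under non-limiting water and N shows the classic defoliation
trade-off — green leaf peaks at a ~2-week interval, while total
harvestable DM keeps creeping up to a plateau as stem and dead leaf
replace leaf in the harvest:

```sh
swardsim scan-interval --intervals 14,28,56 --seed 7 --quiet \
  -O management.irrigated=1 -O nitrogen.n_min_init=300 \
  -O nitrogen.max_uptake=30 \
  -O "management.fertilizer=[{date: 2021-03-15, amount: 200},
      {date: 2021-05-15, amount: 200}, {date: 2021-07-15, amount: 200}]"
```

| interval_days | yield_green_leaf | yield_stem | yield_dead_leaf | yield_total | n_cuts |
|---|---|---|---|---|---|
| 14 | 17313 | 5438 | 0 | 22771 | 16 |
| 28 | 13033 | 9889 | 505 | 24340 | 8 |
| 56 | 6893 | 13781 | 2198 | 25613 | 4 |

`swardsim scan-n` sweeps annual fertilizer rates the same way, and
`swardsim synth-weather` writes a synthetic weather table for
inspection or reuse.  Full runs (`swardsim run -o OUTDIR`) write the
daily state table, the per-cut harvest table, a key-value summary and a
run log listing every parameter value in effect.

Configuration lives in a YAML file mirroring a control sheet — a
"site and grass factors" block (`site:`, `grass:`, `soil:`,
`nitrogen:`) and a "management choices" block (`management:` with
`harvest:`, `fertilizer:`, `irrigated:`) — and any key can be
overridden on the command line with `-O section.key=value`.

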