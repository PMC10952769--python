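# Example run: irrigated silage system on synthetic UK weather.
# Any key can be overridden on the command line: -O section.key=value

site:
  latitude: 52.0
  co2: 400.0
  temperature_offset: 0.0

grass:
  lue_ref: 3.0          # g DM per MJ PAR at reference conditions
  k_ext: 0.6
  lai_crit: 4.0

soil:
  field_capacity: 0.35
  wilting_point: 0.12
  rooting_depth: 600    # mm; the main soil lever
  init_fraction: 1.0

nitrogen:
  n_min_init: 150       # kg N/ha mineral N at 1 January
  n_org_mineralisable: 120

management:
  irrigated: 1
  harvest:
    mode: fixed_interval      # or date_list / weight_threshold
    interval_days: 28
    window_start: 2021-04-01
    window_end: 2021-10-31
    residual_weight: 500      # kg DM/ha live shoot left standing
  fertilizer:
    - {date: 2021-03-15, amount: 100}
    - {date: 2021-05-15, amount: 100}
    - {date: 2021-07-15, amount: 100}

weather:
  synthetic: {year: 2021}     # or: file: weather.csv  + columns: {...}

run:
  seed: 7
  output_dir: scratch/example-run
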