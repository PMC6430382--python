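capacity_above_dam: 900.0
dam_passage_proportion: 0.6
estuary_coefficients:
  delta_length: 0.0329
  intercept: -2.003
  pdo_may: -1.12
  upwelling_may: 0.7
  upwelling_sept: 0.56
fraction_above_dam: 0.3
fry_survival_below_dam: 0.65
horizon_years: 100
initial_spawners: 650
lower_river_survival:
- 0.52
- 0.5
- 0.52
maturation_schedule:
- 0.3
- 0.6
- 1.0
n_runs: 1000
ocean_annual_survival: 0.8
pathway_proportions:
- 0.18
- 0.13
- 0.69
prespawn_coefficients:
  intercept: 4.935
  late_summer_temp: -0.45
  wild_fraction: 2.0
productivity: 215.0
quasi_extinction_threshold: 250
reservoir_survival: 0.55
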