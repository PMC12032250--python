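# Desk-scale transmission scenario: 200 humans, 2-year horizon, single
# release of 1000 drive-homozygous males 200 days in.
kind: epi
human_population: 200
target_eir: 35
horizon_days: 730
release_day: 200
release_size: 1000
replicates: 10
drive:
  homing_female: 0.99
  homing_male: 0.99
  uncut_fraction: 0.0
  functional_fraction: 0.001
fitness:
  daily_mort_mult_hom: 1.5
  bloodmeal_mort_hom: 0.5
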