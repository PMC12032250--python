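# Drive-only cage invasion: 500 adults, 20% starting drive allele frequency,
# measured transmission rates, calibrated homozygote costs.
kind: cage
generations: 21
founders:
  W/W: {female: 200, male: 200}
  D/D: {female: 50, male: 50}
drive:
  homing_female: 0.996
  homing_male: 0.971
  uncut_fraction: 0.0
  functional_fraction: 0.001
fitness:
  daily_mort_mult_hom: 1.5
  bloodmeal_mort_hom: 0.8
  mating_weight:
    homozygous_LOF: 0.2
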