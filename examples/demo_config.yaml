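# Small demo configuration: 4+4 participants, shortened SOM schedule.
# All analysis parameters shown with their defaults where commented.
n_per_group: [4, 4]
som_phases:
  - [20, 0.5, 0.05, 2.0, 1.0]
  - [40, 0.05, 0.01, 1.0, 0.0]
battery_seed: 1
cohort_seed: 2
som_seed: 3
# noise_sd_px: 38.0
# kernel_sd_px: 50.0
# alpha: 0.05
# bonferroni_m: 3
save_prototypes: true
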