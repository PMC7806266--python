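# G2/M re-replication induction: licensing-mutant variants re-initiate at
# registry rates (elevated on chrIII, highest at ARS317); the
# checkpoint-relieved variant scales every rate by rate_scale, modelling
# loss of the Rad53 brake on Sld3/Dbf4.  Includes a simulated RRIGA plating
# experiment on the split-marker strains.
scenario: g2-rerep
seed: 1
sim:
  fork_speed: 1.5
  n_cells: 500
  read_depth: 100.0
  bin_width: 1000
rerep:
  fork_extent_mean: 10.0   # kb, mean one-sided bubble extent
  induction_time: 240.0    # minutes of induction (metadata)
  variants:
    - {name: licensing-control, licensing_enabled: false, rate_scale: 1.0}
    - {name: licensing-mutant, licensing_enabled: true, rate_scale: 1.0}
    - {name: licensing-mutant checkpoint-relieved, licensing_enabled: true, rate_scale: 3.0}
pipeline:
  smooth_window: 15
  min_ref_count: 10.0
analysis:
  halfwidth: 5000
  gain_threshold: 0.2      # copy units above the 2n baseline
  min_bins: 5
  peak_origin: ARS317
rriga:
  enabled: true
  n_viable_per_ml: 1.0e7
  pre_induction_p_amp: 1.0e-6
  n_replicates: 3
  strains:
    - {name: licensing-mutant, p_amp: 0.001}
    - {name: licensing-mutant checkpoint-relieved, p_amp: 0.002}
  compare: [licensing-mutant, licensing-mutant checkpoint-relieved]
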