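# S-phase-release time course: origins fire in trep order; the checkpoint
# arms (G1/S transcription delay, probabilistic Sld3/Dbf4 firing block) are
# off by default, mimicking the fully checkpoint-refractory background.
scenario: g1-release
seed: 1
sim:
  fork_speed: 1.5      # kb/min
  n_cells: 500
  read_depth: 100.0    # expected reads per 1 kb bin per copy unit
  bin_width: 1000
checkpoint:
  transcription_delay: 0.0   # minutes; Swi6/SBF arm (0 = swi4-t expressed)
  firing_block_prob: 0.0     # Sld3/Dbf4 arm (0 = sld3-A dbf4-A)
  release_time: 60.0         # minutes until a blocked origin is released
  block_scope: all
# early-to-mid S for this registry (trep 15-45 min, no checkpoint delay);
# by ~40 min replication is nearly complete and baseline calibration of a
# 1n release profile is no longer meaningful
timepoints: [10.0, 20.0, 30.0]
pipeline:
  smooth_window: 15    # bins (15 kb)
  min_ref_count: 10.0
analysis:
  halfwidth: 5000      # bp window around each origin
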