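# Demo run: small synthetic medulla, fixed seed, default study parameters
# (38% pale mosaic, 5 um pitch, 40 um slab, DRA arc along the dorsal rim).
seed: 7
lattice:
  n_rows: 8
  n_cols: 8
  pitch_um: 5.0
  pale_prob: 0.38
  n_dra: 6
  thickness_um: 40.0
analysis:
  min_synapses: 3
  selectivity_threshold: 0.65
  percent_decimals: 1
  rounding: half-even
profiles:
  depth_sigma_um: 0.4
  radial_sigma_um: 0.6
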