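# Full pipeline on a synthetic array: simulate, call, assign, profile.
# Replace the `simulate:` block with `inputs: {probes: ..., genes: ...}`
# to analyze an existing probe table.
simulate:
  n_genes: 2000
  bound_fraction: 0.05
  effect_size: 2.0
  noise_sd: 0.5
caller:
  p_probe: 0.05
  p_center: 0.01
  p_flank: 0.1
  max_span: 1000
  n_permutations: 10
assign:
  max_distance: 10000
profile:
  bin_start: -5500
  bin_end: 2500
  bin_width: 250
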