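# Opposed-field proton-like reference run, uniform-cluster-yield strategy.
plan:
  particle: proton_like
  arrangement: opposed_fields
  phantom_side_cm: 20.0
  voxel_side_mm: 5.0
  n_target_voxels: 5
  target_shift_cm: 3.75
  peak_spacing_mm: 2.5
  pb_sigma_mm: 3.0
preset: proton_like
n_primaries: 4000
n_svs: 5000
seed: 1
strategy: uniform_yields
output_dir: nanoplan_out
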