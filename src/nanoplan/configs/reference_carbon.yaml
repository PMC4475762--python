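# Reference carbon-like plan: 20 cm water phantom, 5x5 mm voxel row target,
# 10 Gaussian pencil beams per field with 2.5 mm Bragg-peak spacing.
particle: carbon_like
arrangement: single_field
phantom_side_cm: 20.0
voxel_side_mm: 5.0
n_target_voxels: 5
target_shift_cm: 3.75
peak_spacing_mm: 2.5
pb_sigma_mm: 3.0
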