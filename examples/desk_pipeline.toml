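# Desk-scale multimodal pipeline configuration.
# Run with: mmxct all --config examples/desk_pipeline.toml --out out/

[phantom]
shape = [16, 16, 16]
voxel_size_mm = 0.075
cylinder_diameter_mm = 1.2
texture_voxels = 1.5
edge_taper_voxels = 2.0
diameter_range_nm = [46.0, 54.0]

[phantom.aligned_region]
center_frac = [0.5, 0.5, 0.65]
radius_frac = 0.22
target_anisotropy = 0.9
axis = [0.0, 0.0, 1.0]

[phantom.hotspot]
radius_frac = 0.18
fe_amp = 1.0
zn_amp = 1.0

[phantom.coupling]
"anisotropy-diameter" = 0.81
"anisotropy-fe" = 0.77
"anisotropy-zn" = 0.88
"diameter-fe" = 0.70
"diameter-zn" = 0.84
"fe-zn" = 0.89

[geometry]
n_y = 16
n_z = 16
step_mm = 0.075
tilt_pad = 5
# [tilt_deg, [rotation angles in deg]]
schedule = [
    [0.0,  [0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0, 120.0, 135.0, 150.0, 165.0]],
    [27.0, [0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0, 330.0]],
    [45.0, [0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0, 330.0]],
]
# q window start, stop (nm^-1), number of bins
q_edges = [0.25, 0.62, 40]
beam_energy_kev = 12.4
flux = 1e7

[pipeline]
seed = 0
saxs_noise = false
xrf_noise = false
xrf_absorption = true
tensor_iterations = 80
mask_fraction = 0.10
roi = [[5, 11], [5, 11], [6, 10]]
diameter_fit = true
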