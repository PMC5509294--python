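# Full-pipeline configuration for `petmvpa run-all --config ... --out-dir ...`
# Grid is a reduced-resolution template-like lattice (2 mm voxels) centred
# on the origin; clusters are the planted hypometabolic spheres.
grid:
  shape: [48, 56, 48]
  voxel_size_mm: 2.0
baseline: 100.0
fwhm_mm: 8.0
target_mean: 50.0
p_voxel: 0.005
k_min: 200
connectivity: 18
C: 1.0
seed: 1
effect_fraction: 0.3   # used by the default three-sphere pattern
train:
  n_disease: 100
  n_healthy: 44
  age_mean_disease: 46.5
  age_sd_disease: 12.0
  age_mean_healthy: 45.4
  age_sd_healthy: 16.0
test:
  n_disease: 19
  n_healthy: 20
  age_mean_disease: 42.5
  age_sd_disease: 15.0
  age_mean_healthy: 52.0
  age_sd_healthy: 15.0
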