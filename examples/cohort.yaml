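# Demo pipeline configuration: a small synthetic cohort with one planted
# structural cluster, one coherence cluster, and one connectivity edge.
cohort:
  n_male: 20
  n_female: 20
  grid_shape: [16, 16, 16]
  voxel_size_mm: 3.0
  n_regions: 6
  n_timepoints: 60
  tr_seconds: 2.0
  gmv_effect_clusters:
    - [[8, 8, 8], 3.0, 2.5]
  reho_effect_clusters:
    - [[5, 8, 8], 3.0, 0.6]
  fc_effect_edges:
    - [0, 1, 0.5]
  noise_sd: 1.0
  local_coherence_base: 0.2
  fc_base_corr: 0.2
  seed: 42

band_hz: [0.01, 0.08]
smoothing_fwhm_mm: 4.0
alpha_voxel: 0.05
fwe_method: max_t_permutation
n_perm_fwe: 200
alpha_edge_family: 0.05
trend_p: 0.001
cv_k: 4
grid_steps:
  gmv: 400
  reho: 400
  fc: 5
  combined: 800
n_perm_mvpa: 100
seed: 42
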