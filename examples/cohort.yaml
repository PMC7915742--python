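# Example pipeline configuration for `radrep run --config examples/cohort.yaml`.
# Any PipelineConfig field may be set; omitted fields keep their defaults.
cohort:
  groups:
    - label: wildtype
      n_subjects: 10
      volume_mean_ml: 21.0
      volume_sd_ml: 5.0
      volume_range_ml: [1.4, 33.0]
      texture_amplitude: 0.15
      texture_scale: 6.0
      tbr_contrast: 2.0
    - label: mutant
      n_subjects: 10
      volume_mean_ml: 12.0
      volume_sd_ml: 4.0
      volume_range_ml: [1.4, 33.0]
      texture_amplitude: 0.35
      texture_scale: 6.0
      tbr_contrast: 2.0
  shape: [64, 64, 64]
  spacing: [2.0, 2.0, 2.0]
  background_uptake: 1.0
  psf_fwhm: 4.0
  exposure: 500.0
  post_smoothing_fwhm: 0.0
  seed: 1

tbr_threshold: 1.6
background_diameter_mm: 30.0
tumor_diameters_mm: [10.0, 16.0, 20.0, 24.0, 30.0, 35.0, 40.0]
bin_width: 0.15
log_sigmas_mm: [1.0, 2.0, 3.0, 4.0, 5.0]
wavelet: coif1
icc_alpha: 0.05
n_clusters: 2
n_permutations: 1000
write_images: false
seed: 1
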