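# Default end-to-end run configuration.
#
# Physics follows the synchrotron protocol the pipeline emulates: 13 keV
# beam, 85 cm specimen-to-detector distance, 9 um pixels.  The phantom stage
# table encodes the monotone wall-thickening / texture-coarsening progression
# over the six stage classes; amplitudes are in refractive-decrement (delta)
# units, lengths in meters.  Every random stage has an explicit seed.

physics:
  energy_kev: 13.0
  propagation_distance: 0.85
  pixel_size: 9.0e-06
  photon_count: 1.0e+04

tissue:
  electron_density: 3.34e+29   # m^-3, water-like
  attenuation_mu: 250.0        # m^-1, soft tissue at 13 keV

phantom:
  normal: {wall_thickness: 250.0e-06, roughness_amplitude: 6.8165e-08,
           roughness_correlation_length: 30.0e-06, nodule_count: 0,
           seed: 1000, boundary_amplitude: 9.0e-06}
  d3:     {wall_thickness: 290.0e-06, roughness_amplitude: 1.22697e-07,
           roughness_correlation_length: 30.0e-06, nodule_count: 0,
           seed: 1001, boundary_amplitude: 18.0e-06}
  d5:     {wall_thickness: 330.0e-06, roughness_amplitude: 1.90862e-07,
           roughness_correlation_length: 30.0e-06, nodule_count: 1,
           seed: 1002, boundary_amplitude: 30.0e-06}
  d7:     {wall_thickness: 370.0e-06, roughness_amplitude: 2.7266e-07,
           roughness_correlation_length: 30.0e-06, nodule_count: 2,
           seed: 1003, boundary_amplitude: 45.0e-06}
  d9:     {wall_thickness: 420.0e-06, roughness_amplitude: 3.68091e-07,
           roughness_correlation_length: 30.0e-06, nodule_count: 3,
           seed: 1004, boundary_amplitude: 63.0e-06}
  d11:    {wall_thickness: 470.0e-06, roughness_amplitude: 4.77155e-07,
           roughness_correlation_length: 30.0e-06, nodule_count: 4,
           seed: 1005, boundary_amplitude: 81.0e-06}

glcm:
  levels: 16
  distance: 1
  symmetric: true
  n_rois: 20
  roi_size: 50

pca:
  ccr_threshold: 0.80
  score_threshold: 8.5
  score_mode: raw
  sign_convention: anchor

cv:
  k: 10
  C: 1.0

seeds:
  phantom: 11
  noise: 12
  roi: 13
  cv: 14

grid_size: 256
grid_height: 256
n_angles: 180

# Gray-level rendering of detected intensities.  A fixed reference range
# (0 .. ref_high_factor * photon_count) keeps gray levels comparable across
# the six stage images; invert_display applies the radiographic display
# polarity (attenuating structure bright).  Per-image min-max scaling is
# available as quantization: minmax.
quantization: fixed
invert_display: true
ref_high_factor: 2.2

# ROIs are sampled inside the specimen silhouette eroded by this margin, so
# they sample wall texture rather than the steep border band of the organ.
mask_erosion_px: 16
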