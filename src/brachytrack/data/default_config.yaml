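# Default system configuration (units: mm, degrees, seconds, mCi).
# Reproduces the reference design: optimized diverging collimator
# (d = t = 0.3 mm, h = 30 mm, 45 deg acceptance, 38x38 holes) on six panels
# at 500 mm radius, 36 deg apart from 270 to 90 deg, staggered in z.
layout:
  radius: 500.0
  ring_angles: [270.0, 306.0, 342.0, 18.0, 54.0, 90.0]
  z_offsets: [-25.0, -15.0, -5.0, 5.0, 15.0, 25.0]
detector:
  pixels_per_side: 38
  pixel_pitch: 0.6
  active_pixel_size: 0.5
  scintillator_thickness: 4.0
  face_size: 25.8
collimator:
  hole_size_d: 0.3
  septal_thickness_t: 0.3
  height_h: 30.0
  holes_per_side: 38
  acceptance_angle: 45.0
  attenuation_coeff: 0.625
source:
  center: [0.0, 0.0, 0.0]
  axis: [0.0, 0.0, 1.0]
  diameter: 0.6
  length: 3.5
  activity_mci: 360.0
  exposure_time: 1.0
transport:
  n_photons: 1000000
  detection_efficiency: 1.0
  septal_penetration: false
  rng_seed: 0
  source_subsamples: 96
  ambient_background: 0.0
  septal_samples: 16
recon:
  upsample_factor: 4
  gaussian_sigma: 0.6
  volume_extent: 160.0
  voxel_size: 1.0
  iterations: 3
  nonnegativity: true
localize:
  threshold_fraction: 0.3
  refine_passes: 1
noiseless: false
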