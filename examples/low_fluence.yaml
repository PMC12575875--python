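# Low-fluence protocol: four tilted images, no axial exposure.
optics:
  voltage_kv: 300.0
  c1_nm: -250.0
  c3_mm: 2.7
  focal_spread_nm: 8.5
  illum_semiangle_mrad: 0.02
simulate:
  phantom: composite
  phantom_params:
    count: 15
    peak_phase: 0.05
    radius_range_nm: [0.3, 1.0]
    band_invnm: [0.5, 3.0]
    rms_phase: 0.03
  shape: [256, 256]
  pixel_size_nm: 0.05
  tilt_mrad: 5.0
  n_azimuths: 4
  include_axial: false
  total_fluence: 9000.0
reconstruct:
  iterations: 50
seed: 1
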