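# Example run configuration for the sclsettle CLI.
#
#   sclsettle all --config examples/config.yaml --out run/ --seed 1
#
# `preset` cohorts use the built-in reference trajectories (zonal, myopia,
# keratoconus, post_keratoplasty); explicit cohorts take geometry and
# trajectory settings directly.
cohorts:
  - name: demo
    group: myopia
    n_eyes: 2
    lens:
      decentration: [0.0, -0.3]
      tilt_deg: 0.5
protocol:
  n_meridians: 32
  image_size: [512, 512]
  axial_pitch_um: 15.0
  noise_level: 0.3
  time_points: [0, 30, 60, 120, 240]
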