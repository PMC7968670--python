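name: rest_of_world
filter:
  latitude_bands:
  - - 20
    - 60
  - - -40
    - -10
  date_range:
  - 0
  - 46300
exclude_rectangles:
- - - -25.27
    - 133.77
  - - -39.16
    - 154.86
- - - 51.09
    - -9.88
  - - 35.92
    - 8.12
prior:
  gamma_min: 0
  gamma_max: 5
  zeta_min: 1.0e-06
  zeta_max: 0.001
  eps_min: 0
  eps_max: 5.0e-06
phi: 2.0
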