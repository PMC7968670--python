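name: australia
filter:
  latitude_bands:
  - - 20
    - 60
  - - -40
    - -10
  date_range:
  - 0
  - 46300
  rectangle:
  - - -25.27
    - 133.77
  - - -39.16
    - 154.86
prior:
  gamma_min: 3
  gamma_max: 6
  zeta_min: 1.0e-06
  zeta_max: 0.001
  eps_min: 0
  eps_max: 5.0e-05
phi: 2.0
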