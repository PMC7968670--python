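name: timmermann
filter:
  latitude_bands:
  - - 20
    - 60
  - - -40
    - -10
  date_range:
  - 0
  - 46300
prior:
  gamma_min: 0.1
  gamma_max: 6
  zeta_min: 1.0e-07
  zeta_max: 0.1
  eps_min: 0
  eps_max: 0.001
phi: 2.0
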