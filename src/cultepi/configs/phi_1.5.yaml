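name: phi_1.5
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
  gamma_min: 2
  gamma_max: 10
  zeta_min: 1.0e-07
  zeta_max: 0.0001
  eps_min: 0
  eps_max: 5.0e-06
phi: 1.5
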