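name: france_spain_portugal
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
  - - 51.09
    - -9.88
  - - 35.92
    - 8.12
prior:
  gamma_min: 0.1
  gamma_max: 6
  zeta_min: 1.0e-09
  zeta_max: 0.01
  eps_min: 0
  eps_max: 0.0004
phi: 2.0
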