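label: europe_toy_one_phase
world:
  type: raster
  path: toy_coast.raster
T: 400
N0: 100
r: 0.4
m_schedule:
  breakpoints:
  - 0
  values:
  - 0.25
K_schedule:
  breakpoints:
  - 0
  - 320
  values:
  - 250
  - 24000
mu: 7.9e-06
mu_per_site: true
L: 341
sampling:
- deme:
  - 3
  - 1
  age: 0
  count: 30
  label: modern
- deme:
  - 3
  - 1
  age: 300
  count: 23
  label: ancient
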