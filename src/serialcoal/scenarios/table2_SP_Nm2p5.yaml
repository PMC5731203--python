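label: table2_SP_Nm2p5
world:
  type: square
  size: 50
T: 2000
N0: 100
r: 0.4
m_schedule:
  breakpoints:
  - 0
  values:
  - 0.005
K_schedule:
  breakpoints:
  - 0
  values:
  - 500
mu: 3.3e-06
mu_per_site: true
L: 300
sampling:
- deme:
  - 25
  - 25
  age: 0
  count: 30
  label: modern
- deme:
  - 25
  - 25
  age: 400
  count: 30
  label: ancient
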