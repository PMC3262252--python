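# Self-sustained (Goodwin-type) variant of the damped demo clock: the Hill
# exponent is raised and the degradation rates lowered until the dark
# (autonomous) system crosses its Hopf bifurcation and carries a stable limit
# cycle (DD period ~19.6 h).
states: [x1, x2, x3]
parameters:
  n1: 1.0
  g1: 1.0
  h: 16.0
  q1: 0.5
  m1: 0.1
  p1: 0.8
  r1: 0.3
  r2: 0.1
  m2: 0.1
  q2: 0.2
  q3: 0.15
  m3: 0.1
equations:
  - n1/(1 + (x3/g1)**h) + q1*theta - m1*x1
  - p1*x1 - r1*x2 + r2*x3 - m2*x2 - q2*theta*x2
  - r1*x2 - r2*x3 - m3*x3 + q3*theta*x2
light_params: [q1, q2, q3]
temp_params: [m1, m2, m3, p1, r1]
forcing_period: 24.0
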