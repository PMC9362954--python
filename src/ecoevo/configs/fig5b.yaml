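command: phase
params:
  xi: 0.15
  beta: 1.1
  eta: 0.85
  p: 0.3
  mu: 0.0
  sigma1: 0.75
  sigma2: 0.5
grid:
  axis1:
    name: sigma2
    lower: 0.0
    upper: 1.0
    n_points: 51
  axis2:
    name: eta
    lower: 0.01
    upper: 0.99
    n_points: 51
integration:
  dt: 0.01
  max_steps: 200000
  record_every: 100
  convergence_tol: 1.0e-12
initial:
- 0.35
- 0.35
output: out/fig5b
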