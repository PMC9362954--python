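command: sweep
params:
  xi: 0.25
  beta: 1.1
  eta: 0.85
  p: 0.65
  mu: 0.5
  sigma1: 0.75
  sigma2: 0.25
sweep:
  param: eta
  lower: 0.01
  upper: 0.99
  n: 101
integration:
  dt: 0.01
  max_steps: 200000
  record_every: 100
  convergence_tol: 1.0e-12
initial:
- 0.35
- 0.35
output: out/fig9d
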