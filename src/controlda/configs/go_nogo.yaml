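# Go/No-Go omission task, fitted parameterization.
task:
  name: go_nogo
params:
  w_tau_i: 1.94
  w_tau_v_plus: 11.63
  w_tau_v_minus: 0.01
  beta_tau: 0.66
  beta: 2.95
  kappa: 0.50
  r_O: 0.12
  c_f: -0.44
  c_l: -0.10
  c_p: -0.00
control:
  kappa: 0.50
da:
  alpha: 0.8
  xi: 0.7
  tau_delay: 0.25
  dt: 0.01
  window: 3.0
fit:
  w_rtc: 0.018
  w_rte: 0.018
simulate:
  n_trials: 500
  n_sessions: 9
solver:
  n_grid: 200
  tol: 1.0e-8
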