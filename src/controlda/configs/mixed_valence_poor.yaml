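# Mixed-valence active-avoidance task, poor-avoider parameterization.
task:
  name: mixed_valence
params:
  w_i: 0.01
  w_p_plus: 0.82
  w_p_minus: 0.74
  w_tau_i: 0.00
  w_tau_v_plus: 1.06
  w_tau_v_minus: 0.00
  kappa: 0.50
control:
  kappa: 0.50
da:
  alpha: 0.8
  xi: 0.7
  tau_delay: 0.25
  dt: 0.01
  window: 5.0
fit:
  w_rtc: 0.25
  w_rte: 0.25
  w_da: 0.1
  w_reg: 0.0
simulate:
  n_trials: 500
  n_sessions: 9
solver:
  n_grid: 200
  tol: 1.0e-8
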