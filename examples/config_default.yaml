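sp:
  C: 1.0
  g_leak: 0.14
  E_leak: -68.8
  I: 0.313
  sigma: 0.412
  kappa: 0.21
  V_threshold: -65.0
  V_rest: -68.8
  r_s: 0.7
  g_GABA: 0.14
  E_GABA: -68.8
  E_AMPA: 0.0
  g_max: 0.024
  tau_AMPA: 5.26
  A: 0.6
  B: 2.0
  D: 0.7
  E: 24.5
  gamma: 0.2
  alpha: 10.9
  tau: 7.0
gc:
  rho: 0.412
  count_per_sp: 100
  g_relay: 2.0
plasticity:
  eta_2: 0.0018
  eta_4: 0.0036
  L_W2: 10.0
  L_W4: 100.0
  tau_w: 4900.0
noise:
  c: 0.25
  e: 1.0
  cutoff_hz: 500.0
  order: 4
stimulus:
  f: 4.0
  kappa: 0.21
  geometry: global
  duration_s: 100.0
dt_ms: 0.05
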