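name: ecoli_TG1_rec_seeger
description: >
  Recombinant E. coli TG1 fed-batch (7.5 h lag, batch to 16.5 h,
  exponential feeding at specific feeding rate 0.13 1/h to 31 h).
provenance: >
  Setup from the second recombinant-TG1 scenario column; strain constants
  from the recombinant-TG1 calibrated-parameter column (identical to TG1
  except b2 = 15.6). V0, P_max, A_max, I_max are unprinted defaults.
initial_state: {G: 25.0, P: 5.0e-5, A: 0.0, C_M: 0.1, R: 0.0, I: 0.0, D: 0.0}
V0: 1.0
t0: 0.0
t_end: 31.0
lag: 7.5
phases:
  - {mode: batch, t_start: 0.0}
  - {mode: exponential, t_start: 16.5, M_F: 11.0, mu: 0.13, c_F: 500.0, y_R: 0.5}
pulses: []
parameters:
  vG: 1.92
  kG: 2.02
  etaG: 0.91
  vRP: 0.72
  kRP: 0.02
  etaRP: 0.71
  vF: 5.57
  kF: 0.01
  etaFA: 0.37
  etaFP: 0.31
  vRA: 0.04
  kRA: 0.12
  etaRA: 0.43
  vA: 0.2
  kA: 0.05
  etaA: 0.45
  r_max: 0.3
  delta: 0.1
  tau: 0.6
  rho: 0.008
  sigma_I: 1.0
  sigma_A: 1.23
  c: 0.01
  a1: 3.4e-4
  b1: 34.1
  a2: 0.015
  b2: 15.6
  P_max: 3.0
  A_max: 20.0
  I_max: 30.0
defaults_used: [V0, P_max, A_max, I_max]
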