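name: ecoli_TG1_riesenberg
description: >
  E. coli TG1 high-cell-density fed-batch (batch to 12 h, exponential
  feeding to 30 h, constant feeding to 35 h; 770 g/L feed). Cell density
  exceeds 100 g/L near the end, where self-produced inhibitors curb growth.
provenance: >
  Setup from the first TG1 scenario column; strain constants from the TG1
  calibrated-parameter column. V0, P_max, A_max, I_max are unprinted
  defaults.
initial_state: {G: 25.0, P: 5.0e-5, A: 0.0, C_M: 0.1, R: 0.0, I: 0.0, D: 0.0}
V0: 1.0
t0: 0.0
t_end: 35.0
lag: 4.0
phases:
  - {mode: batch, t_start: 0.0}
  - {mode: exponential, t_start: 12.0, M_F: 10.0, mu: 0.11, c_F: 770.0, y_R: 0.42}
  - {mode: constant, t_start: 30.0, M_F: 94.0, mu: 0.08, c_F: 770.0, y_R: 0.42}
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
  b2: 7.6
  P_max: 3.0
  A_max: 20.0
  I_max: 30.0
defaults_used: [V0, P_max, A_max, I_max]
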