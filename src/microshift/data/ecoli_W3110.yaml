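name: ecoli_W3110
description: >
  E. coli W3110 two-phase fed-batch (batch to 11.5 h, exponential feeding to
  16 h, then constant feeding to 33 h) with three glucose pulses during the
  constant phase.
provenance: >
  Initial values and setup from the W3110 scenario column of the published
  setup table; strain constants from the W3110 calibrated-parameter column.
  V0, P_max, A_max, I_max are unprinted defaults; pulse times and masses are
  placeholders (the protocol mentions three pulses but prints neither times
  nor amounts) and are not verifiable.
initial_state: {G: 5.0, P: 5.0e-5, A: 0.0, C_M: 0.2, R: 0.0, I: 0.0, D: 0.0}
V0: 1.0
t0: 0.0
t_end: 33.0
lag: 0.0
phases:
  - {mode: batch, t_start: 0.0}
  - {mode: exponential, t_start: 11.5, M_F: 4.6, mu: 0.3, c_F: 500.0, y_R: 0.39}
  - {mode: constant, t_start: 16.0, M_F: 20.5, mu: 0.19, c_F: 500.0, y_R: 0.39}
pulses:
  - {time: 19.0, glucose_mass: 1.0, volume_added: 0.0, note: placeholder pulse}
  - {time: 23.0, glucose_mass: 1.0, volume_added: 0.0, note: placeholder pulse}
  - {time: 27.0, glucose_mass: 1.0, volume_added: 0.0, note: placeholder pulse}
parameters:
  vG: 0.82
  kG: 0.005
  etaG: 0.69
  vRP: 0.09
  kRP: 0.02
  etaRP: 0.76
  vF: 0.46
  kF: 0.08
  etaFA: 0.12
  etaFP: 0.94
  vRA: 0.25
  kRA: 0.86
  etaRA: 0.94
  vA: 0.2
  kA: 0.05
  etaA: 0.93
  r_max: 0.3
  delta: 0.1
  tau: 0.6
  rho: 0.003
  sigma_I: 1.0
  sigma_A: 2.71
  c: 0.01
  a1: 3.0e-4
  b1: 35.5
  a2: 0.051
  b2: 4.9
  P_max: 3.0
  A_max: 20.0
  I_max: 30.0
defaults_used: [V0, P_max, A_max, I_max, pulses]
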