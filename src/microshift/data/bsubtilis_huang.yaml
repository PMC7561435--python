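name: bsubtilis_huang
description: >
  B. subtilis low-density fed-batch (batch to 10.5 h, exponential feeding
  at specific feeding rate 0.12 1/h to 27.3 h). Shows continuous low-level
  acetate production without a clear-cut metabolic shift.
provenance: >
  Setup from the B. subtilis scenario column; strain constants from the
  B. subtilis calibrated-parameter column. The setup table prints a
  specific feeding rate of 0.24 1/h, but the run description states
  0.12 1/h twice and only that value is consistent with the reported
  final density of about 17 g/L (0.24 drives the culture past 90 g/L);
  0.24 is treated as a misprint (exactly double) and 0.12 is used.
  V0, P_max, A_max, I_max are unprinted defaults.
initial_state: {G: 4.4, P: 5.0e-5, A: 0.0, C_M: 0.01, R: 0.0, I: 0.0, D: 0.0}
V0: 1.0
t0: 0.0
t_end: 27.3
lag: 0.0
phases:
  - {mode: batch, t_start: 0.0}
  - {mode: exponential, t_start: 10.5, M_F: 1.85, mu: 0.12, c_F: 500.0, y_R: 0.39}
pulses: []
parameters:
  vG: 1.98
  kG: 0.15
  etaG: 0.65
  vRP: 0.23
  kRP: 0.01
  etaRP: 0.09
  vF: 1.08
  kF: 0.04
  etaFA: 0.99
  etaFP: 0.92
  vRA: 0.35
  kRA: 0.21
  etaRA: 0.96
  vA: 0.2
  kA: 0.05
  etaA: 0.99
  r_max: 0.3
  delta: 0.1
  tau: 0.6
  rho: 0.052
  sigma_I: 1.0
  sigma_A: 1.15
  c: 0.01
  a1: 1.6e-4
  b1: 23.4
  a2: 0.010
  b2: 21.0
  P_max: 3.0
  A_max: 20.0
  I_max: 30.0
defaults_used: [V0, P_max, A_max, I_max]
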