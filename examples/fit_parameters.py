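"""Calibrate strain parameters against sparse noisy observations.

Generates a synthetic data set from the E. coli TG1 preset (15 samples per
output, 5 % multiplicative noise -- a realistic sampling of a fed-batch
run), perturbs the uptake parameters away from the truth and lets the
Nelder-Mead search pull them back by minimising the three-output
mean-squared error.
"""

from microshift import (
    CalibrationSpec,
    NoiseModel,
    calibrate,
    default_sampling_times,
    generate_observations,
    load_preset,
    simulate,
)

scenario = load_preset("ecoli_TG1_gen").scenario
truth = {"vG": scenario.params.vG, "etaG": scenario.params.etaG}

trajectory = simulate(scenario)
observations = generate_observations(
    trajectory,
    NoiseModel(relative_sd=0.05,
               sampling_times=default_sampling_times(scenario, 15), seed=7),
)

spec = CalibrationSpec(
    free_parameters=("vG", "etaG"),
    initial_guess={"vG": truth["vG"] * 1.3, "etaG": truth["etaG"] * 0.8},
    # the default simplex tolerance (1e-8) polishes far below the noise
    # floor of this data set; a modest iteration cap is plenty here
    max_iterations=150,
)
result = calibrate(scenario, observations, spec)

print(f"SSE: {result.initial_sse:.3f} (at guess) -> {result.sse:.3f} "
      f"after {result.n_evaluations} model evaluations")
for name, value in result.parameters.items():
    print(f"{name}: fitted {value:.3f}   truth {truth[name]:.3f}   "
          f"error {100 * (value / truth[name] - 1):+.1f}%")
print()
print("With 5% measurement noise the uptake parameters are recovered to a")
print("few percent; the residual SSE is the irreducible noise floor.")
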