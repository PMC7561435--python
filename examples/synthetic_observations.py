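"""Generate and export a synthetic sparse observation set.

Emulates how a fed-batch culture is actually sampled: a handful of time
points per output, each with multiplicative measurement error.  The CSV
written here is the same format the calibration CLI consumes.
"""

import numpy as np

from microshift import (
    NoiseModel,
    generate_observations,
    load_preset,
    simulate,
    write_observations,
)

scenario = load_preset("ecoli_W3110").scenario
trajectory = simulate(scenario)

noise = NoiseModel(
    relative_sd={"biomass": 0.05, "glucose": 0.05, "acetate": 0.10},
    sampling_times={
        "biomass": np.linspace(1.0, 32.0, 12),
        "glucose": np.linspace(1.0, 32.0, 10),
        "acetate": np.linspace(2.0, 32.0, 8),
    },
    seed=11,
)
obs = generate_observations(trajectory, noise)
write_observations(obs, "w3110_synthetic_observations.csv")

print("points per output:", obs.counts())
for out in ("biomass", "glucose", "acetate"):
    v = obs.values[out]
    print(f"{out:8s} range {v.min():8.3f} .. {v.max():8.3f} g/L")
print()
print("wrote w3110_synthetic_observations.csv (columns time_h, output,")
print("value_gL) -- feed it to `microshift calibrate --observations ...`.")
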