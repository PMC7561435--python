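"""One-at-a-time sensitivity scan of a preset.

Perturbs every strain parameter by +/-5 % and ranks them by the
range-normalised squared deviation of the three observed outputs
(biomass, glucose, acetate) from the baseline simulation.
"""

from microshift import load_preset, sensitivity_scan

scenario = load_preset("bsubtilis_huang").scenario
result = sensitivity_scan(scenario, grid_step=0.1)

print("top 8 parameters by max index over the two perturbation signs:")
print(result.ranking().head(8).to_string())
if result.failures:
    print("\nperturbations outside the admissible parameter space (skipped):")
    for p, s in result.failures:
        print(f"  {p} {s}5%")
print()
print("Large indices mark parameters whose 5% change visibly reshapes the")
print("culture dynamics; glucose-uptake kinetics dominate in every strain.")
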