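"""The three-species scenario across fractional orders.

Runs the baseline parameter set (prey starting far above carrying
capacity, predators split into susceptible and infected) for several
orders and reports the densities at t = 50.  Lower orders jump harder at
t = 0 (the ABC local term) but keep longer memory, so they retain MORE
prey at t = 50 than the classical model; alpha = 0.4 diverges outright
under the explicit scheme and is reported as a failure, not a trajectory.
Outputs (CSVs, figures, diagnostics) land in ``scenario_out/``.
"""

import numpy as np

from fracprey import ScenarioConfig, run_scenario

config = ScenarioConfig(outdir="scenario_out")
results = run_scenario(config)

print(f"requested orders: {config.alphas}; completed: {sorted(results)}")
print("\ndensities at t = 50 (per completed order):")
print(f"  {'alpha':>5} {'P':>9} {'S':>9} {'I':>9}")
for alpha, traj in sorted(results.items()):
    i50 = np.searchsorted(traj.grid, 50.0)
    p, s, i = traj.states[i50]
    print(f"  {alpha:>5g} {p:9.5f} {s:9.5f} {i:9.5f}")
print(
    "\nP and S decline from their initial 0.5 / 0.3 while the infected\n"
    "predator compartment I grows from 0.2 (its net growth rate d - n > 0);\n"
    "I grows faster at higher order, P is depleted further at higher order."
)
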