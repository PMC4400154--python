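"""Fit the 15 rate constants to a surrogate fluorescence dataset.

Generates the dl-Venus-like surrogate (saw tooth, declining basal levels,
Gaussian width 0.15), runs three desk-scale evolutionary fits (lambda=50,
mu=10, 10 generations each; the full-scale configuration is lambda=500,
mu=100, 25 generations) and keeps the lowest-RSS run, then summarizes the
fitted gradient.  Takes a few minutes.
"""

import numpy as np

from dlcact import build_schedule, simulate
from dlcact.dynamics import ModelParameters
from dlcact.ea import equilibrium_constants
from dlcact.fitting import average_gradient_width, fit_dynamics_multi
from dlcact.synthetic import SurrogateConfig, generate_surrogate_venus

schedule = build_schedule(n14=50)
dataset = generate_surrogate_venus(SurrogateConfig(seed=1, n14=50), schedule=schedule)

result, _ = fit_dynamics_multi(dataset, schedule, n_runs=3, seed=1)
print(f"best weighted RSS: {result.best_rss:.4g} "
      f"({result.best_rss / dataset.X.size:.2f} per grid cell)")
print("RSS-weighted parameter means (top 10 survivors):")
for name, m, s in zip(result.param_names, result.weighted_mean,
                      result.weighted_std):
    print(f"  {name:12s} {m:8.4f} +- {s:.4f}")

summary = equilibrium_constants([result])
for species, (q25, med, q75) in summary.quantiles.items():
    print(f"log10 import/export for {species}: {med:+.2f}")

best = ModelParameters.from_array(result.best_params)
traj = simulate(best, schedule)
print(f"fitted gradient width (Gaussian sigma, NC11-14 mean): "
      f"{average_gradient_width(traj):.3f}")
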