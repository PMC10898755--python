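"""Posterior-predictive concentration maps over the stratified grid.

Conditions the fitted spatial field on the grid (GP kriging draws), converts
to original-scale concentrations, and summarizes each grid point by its
posterior mean and 95% interval.
"""

import numpy as np

from roadmoss import (
    GridConfig,
    McmcConfig,
    conditional_spatial_draws,
    default_truth,
    fit_model,
    generate_design,
    generate_prediction_grid,
    pointwise_map_summaries,
    predictive_concentration_draws,
    simulate_concentrations,
)

sites, plan = generate_design(seed=1)
obs = simulate_concentrations(sites, plan, default_truth("Zn", 2006),
                              element="Zn", year=2006, seed=2)
draws = fit_model(obs, sites, McmcConfig(n_chains=2, n_iterations=800, seed=3))

# a reduced grid keeps the example quick; the default reproduces the full
# per-stratum densities (697, 743, 507, 121, 289)
grid_config = GridConfig(counts_north=(40, 40, 25, 8, 0),
                         counts_south=(40, 40, 25, 8, 30))
grid = generate_prediction_grid(grid_config, seed=4)

eta_star = conditional_spatial_draws(draws, sites, grid, K=100, seed=5)
predictive = predictive_concentration_draws(draws, grid, eta_star, seed=6)
maps = pointwise_map_summaries(predictive)

print(f"{len(grid)}-point grid, {predictive.K} predictive draws per point\n")
maps["stratum"] = [g.stratum for g in grid]
by_stratum = maps.groupby("stratum")[["mean", "q2.5", "q97.5"]].mean().round(1)
print("average of pointwise summaries by distance stratum (mg/kg):")
print(by_stratum.to_string())
print("\nconcentrations fall by an order of magnitude from the road corridor "
      "(stratum 1, 0-100 m) to the reference zone (stratum 5, 30-64 km); "
      "the interval width tracks distance from the sampled transects")
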