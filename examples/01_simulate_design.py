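"""Generate the synthetic study design and one concentration dataset.

Builds the default sampling network (12 transects with plots 10 m - 4 km from
the road, autocorrelation plots, roadside points, far reference sites), then
simulates zinc concentrations from the hierarchical spatial model.
"""

import numpy as np

from roadmoss import default_truth, generate_design, simulate_concentrations

sites, plan = generate_design(seed=1)
print(f"design: {len(sites)} locations, {sum(plan.values())} planned tissue samples")

truth = default_truth("Zn", 2006)
obs = simulate_concentrations(sites, plan, truth, element="Zn", year=2006, seed=2)
conc = np.array([o.concentration for o in obs])
print(f"simulated Zn 2006: {len(obs)} samples, "
      f"median {np.median(conc):.1f} mg/kg, range {conc.min():.1f}-{conc.max():.1f}")

# concentrations decay with distance to the road (log-linear surface)
by_band = {}
lookup = {s.site_id: s for s in sites}
for o in obs:
    d = lookup[o.site_id].distance_to_road
    band = "<=100 m" if d <= 100 else ("0.1-4 km" if d <= 4000 else "reference")
    by_band.setdefault(band, []).append(o.concentration)
for band, values in by_band.items():
    print(f"  {band:>10}: n={len(values):3d}  mean {np.mean(values):8.1f} mg/kg")
print("near-road samples are orders of magnitude above the reference sites, "
      "mirroring a fugitive-dust deposition gradient")
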