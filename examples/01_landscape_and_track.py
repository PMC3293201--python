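"""Generate a seismic-line landscape and a predator track on it.

Builds a 10 x 10 km landscape at the baseline line density (4.46 km/km²),
places prey at a low density, and simulates a day of 5-min fixes for a
predator that travels faster along lines, sticks to them, and is drawn
toward them when near. Prints the realised densities and how the fixes
distribute over the on / near / off classes.
"""
import numpy as np

from linefpt import (
    Domain,
    classify_locations,
    generate_landscape,
    place_prey,
    reference_params,
    simulate_track,
)

domain = Domain.square(10.0)
landscape = generate_landscape(4.46, domain, seed=1)
prey = place_prey(0.5, domain, radius_r=0.1, seed=2)
print(f"landscape: {len(landscape)} segments, density {landscape.density_S:.3f} km/km²")
print(f"prey: {len(prey)} items at {prey.density_N:.2f} km⁻², r = {prey.radius_r*1000:.0f} m")

params = reference_params()  # wolf-like step lengths and concentrations
track = simulate_track(params, landscape, n_steps=288, seed=3)  # one day
labels, counts = np.unique(classify_locations(track, landscape), return_counts=True)
share = {k: f"{v / len(track):.1%}" for k, v in zip(labels, counts)}
print(f"fix classes over one day: {share}")
print("(a walker with on-line affinity spends far more time within 27 m of a")
print(" centreline than the ~2% areal share of the on-line band)")
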