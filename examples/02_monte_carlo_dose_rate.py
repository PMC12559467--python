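"""Monte Carlo dose rate in a film active layer and its water variant.

Transports Am-241 alphas from the 48 kBq disk source through the EBT3
stack (active layer face-down on the source), scores dose per decay in a
0.01 mm voxel slab, and reports the mean dose rate in the central 1 mm
circular region of interest — the quantity used to convert exposure times
into doses. The run is reduced to 5e5 histories so the example finishes in
seconds; statistical uncertainty scales as 1/sqrt(N).
"""

from alphafilm import mc

stack = mc.film_stack("EBT3")
cfg_film = mc.SimulationConfig(stack=stack)
cfg_water = mc.SimulationConfig(stack=stack.water_variant())

grid_f = mc.run_simulation(cfg_film, 500_000, seed=1)
grid_w = mc.run_simulation(cfg_water, 500_000, seed=2)
res_f = mc.roi_mean_dose_rate(grid_f)
res_w = mc.roi_mean_dose_rate(grid_w)

print(f"EBT3 active layer: {res_f.dose_rate_gy_min:.3f} Gy/min (+-{res_f.sigma_rel_pct:.2f}%)")
print(f"water, same geometry: {res_w.dose_rate_gy_min:.3f} Gy/min (+-{res_w.sigma_rel_pct:.2f}%)")
print(
    f"water-film difference: {mc.percent_difference_vs_water(res_f, res_w):+.1f}% of the water rate"
)

import numpy as np

prof = mc.line_profiles(grid_f, res_f)
x = prof["x_mm"]
# single voxels are noisy at this history count; average the profile over
# small windows to show the shape
central = prof["horizontal"][np.abs(x) < 0.5].mean()
outside = prof["horizontal"][np.abs(np.abs(x) - 3.0) < 0.25].mean()
print(
    f"profile (normalized to ROI mean): {central:.2f} within the central 1 mm, "
    f"{outside:.2f} at 3 mm\n- the dose falls off steeply at the edge of the 5 mm source."
)
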