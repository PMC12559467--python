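"""Fit a power-law calibration curve to synthetic film measurements.

Generates a noisy synthetic dataset in memory, measures PVnorm at the
source footprint of each scan pair, converts exposure times to doses with
the (nominal) MC dose rate, and fits D = b * PVnorm^n with the offset
parameter locked at zero. The fitted (b, n) should recover the generating
truth within their standard errors.
"""

import numpy as np

from alphafilm.calibration import fit_power
from alphafilm.synthetic import default_truth, synthesize_points

truth = default_truth("EBT3", "water", seed=7)
rng = np.random.default_rng(7)
points = synthesize_points(truth, rng)

curve, points = fit_power(points, "EBT3", "water")
print(f"truth:  b = {truth.b_true:.1f} Gy, n = {truth.n_true:.3f}")
print(
    f"fitted: b = {curve.b:.1f} +- {curve.sigma_b:.1f} Gy, "
    f"n = {curve.n:.3f} +- {curve.sigma_n:.3f}, chi2_red = {curve.chi2_red:.2f}"
)
print(f"dose range covered: {curve.dose_range[0]:.1f} - {curve.dose_range[1]:.1f} Gy")
print("\n  t [min]   D [Gy]   PVnorm    D_fit [Gy]")
for p in points:
    print(
        f"  {p.exposure.t_min:7.1f}  {p.dose_gy:7.1f}   {p.pv_norm:.4f}   {p.d_fit:9.1f}"
    )
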