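"""Alpha stopping powers and CSDA ranges in film and water.

Builds the preset layer materials, evaluates the Bethe mass stopping power
at the Am-241 mean alpha energy (5.46 MeV), and integrates the reciprocal
stopping power into CSDA ranges. The ranges (tens of micrometres) explain
why only unlaminated films — with the 12-14 um active layer exposed — can
be used for alpha dosimetry: a polyester cover would absorb the particles
before they reach the sensitive layer.
"""

from alphafilm import materials as mat

E_ALPHA = 5.46  # MeV, mean Am-241 alpha energy

print(f"{'material':<22}{'S(5.46 MeV) [MeV cm2/g]':>26}{'CSDA range [um]':>18}")
for name in ["EBT3", "EBT-XD", "HD-V2", "water", "polyester"]:
    m = mat.PRESETS[name]
    S = mat.mass_stopping_power(m, E_ALPHA)
    r = mat.csda_range(m, E_ALPHA)
    print(f"{m.name:<22}{S:>26.1f}{r:>18.1f}")

print(
    "\nThe range in water (~43 um) sits inside the 40-60 um window expected "
    "for Am-241 alphas;\nthe film active layers (12-14 um) intercept only "
    "part of each track unless it enters obliquely."
)
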