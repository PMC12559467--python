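# Methods

## Problem and scope

An ²⁴¹Am disk source (48 kBq, active circle 5.0 mm diameter) irradiates
unlaminated GafChromic film lying face-down on it. The package computes the
absorbed-dose rate in the film's active layer (and in water at identical
geometry), converts exposure times to doses, calibrates the film's
green-channel response against those doses, and propagates a complete
relative uncertainty budget. Only the alpha emission is transported;
photons and conversion electrons of the decay contribute negligibly to a
12–14 µm slab in contact with the source (their energy-absorption per unit
areal mass is ~3–4 orders of magnitude below the alphas'), and decay
products beyond long-lived ²³⁷Np are not present experimentally.

## Stopping-power model

Mass stopping powers come from the Bethe formula per element with Bragg
additivity over the layer composition:

S(E) = K z_eff² (Z/A) β⁻² [ln(2 m_e c² β² γ² / I) − β²]  (MeV·cm²/g)

with K = 0.307075 MeV·cm²/mol and elemental mean excitation energies I
(ICRU-style values) embedded as constants. The Barkas effective charge
z_eff = 2(1 − exp(−125 β·2^(−2/3))) is applied **by default**: a bare
z = 2 overestimates stopping below ~2 MeV enough to push the 5.46 MeV CSDA
range in water to ~38 µm, outside the 40–60 µm window expected for Am-241
alphas, whereas with the correction the range is 42.6 µm, within ~2% of
published tabulations. `effective_charge=False` restores the uncorrected
formula. Below 0.5 MeV the formula degrades (the logarithm approaches
zero) and S is clamped to its 0.5 MeV value; transport stops at
E_cut = 0.1 MeV with local deposition — the residual range below the cut
is sub-micrometre, far below the 10 µm voxel pitch. Nuclear stopping,
shell/Bloch corrections, and phase effects are omitted; at 1–5.5 MeV these
are percent-level on S and smaller on the thin-slab energy deposit.

CSDA ranges are ∫ dE/(ρS) on a log-spaced grid, refined by doubling until
the result changes by <0.01% (the convergence target is stricter than the
0.1% verified in the tests).

## Transport and scoring

Each history is one decay. The emission point is uniform on the active
disk, the direction isotropic over the full sphere; downward alphas are
absorbed in the platinum/aluminum source backing (alpha backscatter albedo
≪ 1% and is neglected), so half of all histories score nothing but remain
in the per-decay normalization. The default energy is monoenergetic
5.46 MeV (the emission-weighted mean); the three principal lines
(5.486/5.443/5.388 MeV) are available behind a flag and change the ROI
dose rate by far less than the statistical uncertainty.

Tracks are straight lines (no angular scattering, no energy straggling):
over ≤50 µm path lengths the lateral displacement of a 5.46 MeV alpha from
multiple scattering is a few micrometres at most — below the 0.01 mm
lateral voxel pitch — and the scored quantity is a thin-slab mean, which
straggling leaves unchanged to first order. Energy loss uses
residual-range bookkeeping on a 4000-point range table (range↔energy
inversion by monotone interpolation), stepping 2 µm along the track
(< pitch/5 laterally for any direction) and depositing each step's ΔE at
the step midpoint's voxel. A track ends by stopping inside the layer
(remaining energy, including the sub-cutoff residual, deposited locally)
or by leaving through the backing, which is not scored. An optional air
gap (default 0: the film sits directly on the source) degrades energy and
offsets the entry point before the active layer; source self-absorption is
neglected (the active element is printed as nanometre-thin).

Scoring is one voxel slab spanning the active-layer thickness
(z = 14 µm EBT3, 12 µm EBT-XD/HD-V2), 0.01 mm lateral pitch, 12 × 12 mm
extent. Per-voxel statistical uncertainties are history-by-history: sums
of per-history deposits and their squares give the standard error of the
per-decay mean. The ROI dose rate is the mean of voxel doses whose centers
fall inside the central 1 mm circle, × activity × 60 (Gy/min); its
uncertainty treats voxels as independent. The water variant replaces every
layer's material by water at 1.0 g/cm³ at identical thicknesses; the
film/water percentage difference is quoted relative to the water rate.
Desk scale is 2×10⁶ histories per run (seconds of CPU; ~0.3% ROI
statistical error); the engine scales linearly for larger runs.

Known limitation: with these geometry and normalization conventions the
absolute ROI dose rates are bounded above by (half the emitted energy) /
(ROI areal mass) — about 4.0 (EBT3), 4.0 (EBT-XD), 5.6 (HD-V2) Gy/min —
and straight-line CSDA transport deposits ~55–70% of that bound because
most tracks outrange the thin slab. Condensed-history codes with full
scattering differ from this by percent-level amounts, not integer factors.
HD-V2's active layer (0.95 g/cm³, carbon-rich, low mean excitation energy)
stops *more* energy per gram than water, so its film dose rate slightly
exceeds the water-replacement value; the EBT3/EBT-XD layers are denser
than water and show the opposite ordering.

## Film response and calibration

Scans are 48-bit RGB TIFFs at 127 dpi (0.2 mm/pixel). The response is the
green-channel normalized pixel value PVnorm = PV_bg/PV_irr − 1 from
5×5-pixel ROIs at the source footprint, located automatically as the
centroid of pixels darker than background − 3σ (manual override
available). The PV uncertainty uses the ROI pixel standard deviation — not
the standard error of the mean — a deliberately conservative convention
standard in film-dosimetry protocols; replicate exposures are combined as
an unweighted mean with σ the larger of the propagated value and the
replicate sample sd.

The calibration fit D = a·PVnorm + b·PVnormⁿ locks a = 0 (the response
must vanish at zero net darkening) and solves for (b, n) by weighted
nonlinear least squares, weights 1/σ_D² with σ_D² = σ_MC²t² + σ_t²Ḋ² (the
time→dose conversion uncertainty), initialized at n₀ = 1,
b₀ = median(D/PV), bounded positive. Parameter errors use the scaled
("residual-consistent") covariance, so a misfitting point inflates σ_b and
σ_n; the reduced χ² uses dose-space residuals over σ_D with N − 2 degrees
of freedom. Unweighted fitting is available by flag.

Dose-range refinement codifies the manual pruning of film calibration
sets: while any retained point's fit-uncertainty component exceeds the
threshold (default 5%), the lowest- or highest-dose point — whichever has
the larger |relative dose error|, ties dropping the high end — is removed
and the curve refitted, stopping at a floor of 5 points (non-convergence
is flagged, not fatal).

## Uncertainty budget

At each point, as percentages of D_fit: experimental
100·|a + n·b·PV^(n−1)|·σ_PV/D_fit; fit 100·√(PV²σ_a² + PV^(2n)σ_b²)/D_fit
— the σ_n sensitivity (b·PVⁿ·ln PV·σ_n) and the full b–n covariance are
available behind flags but excluded by default, keeping the two-term
Devic-style form; MC/time 100·√(σ_MC²t² + σ_t²Ḋ²)/D_fit; total is the
quadrature sum, flagged above 5%. The relative dose error is
100·(D_fit − D)/D_fit, signed. Neglecting the b–n correlation makes the
default fit component conservative away from PVnorm = 1; the coverage of
D_fit ± 1.96σ_tot on held-out simulated points is ~95%.

## Synthetic-data generator

The generator emulates the scan protocol: background images at
40 000 ± 150 counts (≈0.4% pixel noise, typical flatbed behavior; both
configurable), an irradiated 5 mm footprint whose green level is the
power-law inversion PV_irr = PV_bg/(1 + (D/b)^(1/n)) at D = t·Ḋ, Gaussian
per-pixel noise, clipping to [0, 65535], triplicate pairs per exposure
time, and a manifest. Footprint edges can be erf-smoothed over 0.4 mm to
mimic the measured fall-off (off by default so unit tests see a sharp
support). Default schedules are 9 geometric times spanning each film's
usable dose window at its nominal water dose rate (e.g. 5.1–42.9 min for
EBT3); timing uncertainty defaults to 1 s and the rate uncertainty to
0.4%, the stopwatch/statistics scale of the protocol. Not emulated:
scanner PSF, lateral-response nonuniformity, lamp drift, Newton rings,
film curl — so passing recovery tests bound statistical, not systematic,
behavior on real film.

## Numerical and design notes

* Voxel/ROI membership is strict (center x² + y² < r²); the lattice count
  is verified against exhaustive enumeration.
* Same seed ⇒ bit-identical outputs: all sampling happens in a single
  numpy Generator stream; the jitted kernel is deterministic.
* The χ²-distribution check for correctly specified noise is performed at
  triplicate-level granularity (27 points, 25 dof), where the [0.5, 1.6]
  band holds ≥90% of the time; at 9 combined points (7 dof) the same band
  captures only ~70% of a true χ² distribution.
* Degenerate inputs: zero exposure gives PVnorm 0 (and a warning if the
  irradiated ROI is *brighter* than background); doses beyond the
  film's dynamic range trigger a saturation warning in the generator;
  sub-cutoff alphas deposit locally in the entry voxel.
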