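# Methods

This note documents the models, parameter choices, numerics and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Boltzmann inversion of angle ensembles

The hinge angle θ (degrees, interior angle between the arms) is treated as
the conformational coordinate, and each imaged particle as one equilibrium
draw. The density is estimated by histogram with 5° bins whose centers sit
on multiples of the bin width; 5° matches the binning used by the
nucleosome model and resolves the landscapes at the available sample sizes
(empirically, angular distributions converge for N ≳ 150; the estimator
warns below that). The landscape G(θ) = −ln p(θ) (k_BT units) is computed
only on bins with density ≥ 0.001 per degree — outside that range −ln p is
dominated by counting noise — and min-shifted to zero.

A cubic smoothing spline is fit to the retained (θ, G) points. The
smoothing penalty is chosen by generalized cross-validation by default and
is overridable; with fewer than five retained bins the fit degrades to an
interpolating spline. Torque is −dG/dθ per radian times k_BT, evaluated by
central differences of spline values on a 0.1° grid (an analytic spline
derivative is available as an option; the two agree to the finite-difference
error). Dividing torque by the radial coordinate d gives the force map
over d ∈ [11, 61] nm by default — from one cross-over repeat of the
square-lattice bundle (32 bp ≈ 11 nm) out to the arm length. Positive
torque opens the hinge, so positive mapped force is tensile on a sample.

Uncertainty: N-out-of-N bootstrap with replacement, 50 replicates by
default, reporting replicate mean and SD. Replicates on which a statistic
is undefined (e.g. an empty valid range after resampling) are skipped and
counted; more than 50% skips aborts. The "most likely angle" is the argmax
of a spline-smoothed density on a 0.1° grid, not the raw modal bin.

## Polymer models

Flexible linkages (a few unpaired nucleotides plus a biotin–neutravidin
bridge at each arm tip, lumped together) are Gaussian chains with vector
density p(R) = (3/2πnb²)^{3/2} exp(−3R²/2nb²). The values n = 4,
b = 1.5 nm (RMS end-to-end distance 3 nm) are an assumption calibrated to
the physical size of that linkage, not a measured quantity; both are
config-exposed because predictions of the coupled model shift by a few
degrees when the linker stiffness changes.

The dsDNA sample (249 bp ≈ 85 nm at 0.34 nm/bp helical rise; l_p = 50 nm)
is too short for Gaussian statistics and too flexible for a rigid rod. Its
scalar end-to-end density uses the stiff-polymer closed form, a function of
x = (l_p/L_c)(1 − R/L_c) with two dual series representations switched at
x = 0.2; at the switch point the three-term truncations of the two series
agree to ~1e-12 relative, so the branch choice is numerically invisible.
The density is treated as the 1-D density of the scalar end-to-end
distance with no additional R² measure factor — consistently with its use
in the closure integral, where only the two linker terms carry spherical
Jacobians. The normalization constant is computed by adaptive quadrature
on (0, L_c) and cached per (L_c, l_p).

Free energy is G(R) = −k_BT ln p(R), shifted to zero at the density mode;
force is a centered finite difference with a 0.1 nm step (configurable;
the truncation error at that step is far below the 3% plateau tolerance
used in tests). In the deep-compression regime the leading series term
makes G linear in R, giving the force plateau π² l_p k_BT / L_c², which
for the 249 bp sample is 0.281 pN.

k_BT = 4.114 pN·nm (298 K) throughout; configurable.

## Hinge–sample coupling

The coupled angle distribution reweights the free-hinge prior by the
probability that linker1 + sample + linker2 spans the tip-to-tip chord
2L sin(θ/2). Both linker vectors are summed over a spherical grid with
radial spacing ΔR = 2 nm, polar spacing ΔR/R and azimuthal spacing
ΔR/(R sin t) (near-equal-volume cells), truncated at the full extension
n·b; weights are the Gaussian density times the exact cell volume. The
sample extension is not gridded: it is fixed exactly by vector closure
against the chord, and the WLC density is evaluated there (zero at or
beyond L_c). The chord is placed on a fixed axis and the absolute azimuth
of linker1 is integrated out analytically (the closure distance depends
only on relative azimuth), reducing the 6-D sum to 5-D. Halving ΔR to
1 nm changes the prediction by ~0.1% total variation; the Monte-Carlo
importance sampler agrees within TV ≈ 0.01 at 2×10⁵ draws.

Force on the sample: G(θ) = −ln P(θ) min-shifted, F = −dG/dr with
dr/dθ = L cos(θ/2). Sign convention: F > 0 means the coupled free energy
falls with increasing tip separation — the sample pushes the arms apart,
i.e. it bears a compressive load; F < 0 means tension. This matches the
sign of the single-polymer compression force, to which the coupled force
reduces (within 5% in tests) for a flat prior and point-like linkers.

## Nucleosome unwrapping

States are (n₁, n₂) base pairs unwrapped from the two ends of the wrap,
0 ≤ n₁ + n₂ ≤ 147, enumerated exhaustively (~11,000 states). Geometry:
the remaining wrap occupies an arc of (147 − n₁ − n₂) × 1.67·2π/147 on a
superhelix of radius 4.18 nm (canonical crystallographic values, with
2.39 nm pitch in the 3-D backend); unwrapped DNA plus the 51 bp linker on
each side leaves along the exit tangent and stays straight; the hinge
angle follows from the end-to-end span through the chord relation,
clamping to 180° if the span exceeds the open hinge. The default backend
projects the superhelix onto its winding plane; a 3-D backend retains the
pitch (the two differ by ≲3 nm in span for moderate unwrapping).

Because the exit tangent rotates as DNA unwraps, θ(n₁, n₂) is *not*
globally monotone in the unwrapped count: within roughly the first 8 bp
of total unwrapping (arc still > 2π) and beyond ~60 bp the span
oscillates. In the thermally dominant window (≈8–59 bp total) θ increases
monotonically, which is the regime that shapes all predictions; the tests
assert monotonicity there only.

The unwrapping free energy ε(n₁, n₂) is a pluggable model. The shipped
default is a piecewise-constant net adhesion per base pair — 0.15 k_BT/bp
for the first 35 bp from each end (outer turn), 1.0 k_BT/bp beyond (inner
turn) — chosen once to reflect the literature consensus that initial
unwrapping costs of order thermal energy per few base pairs while the
inner turn is several-fold stiffer. ε(0,0) = 0 and the model is additive
across ends. Absolute unwrapping totals are calibration-dependent and
should be read relative to one another, not as absolute predictions; the
*ordering* across device variants (open-biased ≫ closed-biased ≫ free) is
robust to the calibration. All outputs are invariant under a constant
shift of ε (gauge freedom absorbed by the partition function).

State weights P_θ(n₁,n₂) · e^(−ε) are binned by total unwrapping (3 bp
bins) or marginalized over 5° angle bins, each normalized by the total
weight Z. Note the angle marginal counts every state separately, so an
angle bin's mass is the device probability times the *number* of states
mapping into it — with a flat ε the constrained distribution is the prior
modulated by state multiplicity, not the bare prior.

The tensile-force estimate differentiates the free-device landscape
spline at the constrained most-likely angle θ* (spline mode of the
constrained distribution) and projects onto the chord,
F = −k_BT (dG/dθ)/(L cos(θ/2)); positive = tension. Differentiating along
the chord is the default because the sample acts along the tip-to-tip
axis; the torque/radius alternative differs only by the cos(θ/2)
projection factor and can be recovered from the torque profile.

## Euler elastica

EI = l_p k_BT identifies the bending rigidity; thermal undulations are
deliberately excluded here (they are the WLC module's job), so the
elastica gives the mechanical load of the bent shape alone. Pinned ends
are the default — the biotin–neutravidin linkages at the arm tips rotate
freely — with clamped-clamped available (4× the critical load, same shape
relation). The modulus equation is solved by bracketed root finding on
m = k² ∈ (0, 1) to 1e-8 relative; the post-buckling branch meets the
critical load continuously as e → L_c. "Deformation" means end
shortening: a 36 nm deformation of the 85 nm rod is an end-to-end
distance of 49 nm. The elastica and WLC-plateau forces agree within 50%
over moderate compression, which is as close as the two pictures (pure
mechanics vs. free energy including entropy) should be expected to agree.

## Synthetic data

Device-variant ensembles are skew-normal distributions truncated to
(0°, 180°) plus 2° SD Gaussian measurement noise (an assumption standing
in for manual two-line angle measurement; there is no published error
model). Preset parameters were fit once to the reported summary
statistics: open-biased `nDFS.B` (skew 2, loc 73°, scale 14° → mean 83°,
~99% above 60°), flexible `nDFS.A` (skew 1, loc 59.8°, scale 18° → mean
70°), closed-biased `nDFS.C-35` (skew 2, loc 27°, scale 18° → ~93% below
60°). Draws falling outside (0, 180) after noise are redrawn.

What passing tests on these ensembles do show: the full analysis chain —
density → landscape → torque → force, coupling, unwrapping — recovers
known inputs at realistic sample sizes (N = 150–700) and reproduces the
closed-form physics. What they do not show: robustness to the failure
modes of real micrographs (mis-picked particles, projection of 3-D
conformations onto the grid plane, stain artifacts, operator bias in
angle drawing), none of which the generator emulates.

The WLC sampler inverts a 4001-point trapezoid CDF of the normalized
density; the coupled-system sampler draws hinge angles from the prior and
linker vectors from their exact 3-D Gaussians and importance-weights by
the closure-evaluated WLC density (it warns below an effective sample
size of 100). `make_fixture_suite` writes the standard CSV bundle with a
JSON manifest of every seed; regeneration is byte-identical.

## Problem sizes and determinism

Default analysis sizes — N = 500 ensembles, 2 nm coupling grids, 2×10⁵
Monte-Carlo draws, exhaustive 11k-state nucleosome sums — run in seconds
on one core; the acceptance script's Monte-Carlo confirmation uses 10⁴
draws. Every stochastic routine takes an explicit seed, and the pipeline
stamps outputs with a hash of the full configuration, so reruns are
bit-reproducible.

## Known limitations

* Angles are taken at face value as the conformational coordinate;
  projection effects of particles lying on a grid are not modeled.
* Arm-tip fraying, which softens the effective arm length at extreme
  angles, is outside the model (it plausibly accounts for ~10° of
  open-state discrepancy between coupled-model predictions and
  measurements on real devices).
* The unwrapping energy default is a calibration, not a measurement;
  absolute base-pair totals inherit its uncertainty.
* Histone subunit loss (H2A–H2B dimer dissociation) at large openings and
  sequence-dependent wrapping energetics are not modeled.
* The stiff-polymer density is inaccurate for l_p ≪ L_c; the Gaussian
  chain covers that regime for the linkers only.
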