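# ndfs

Statistical-mechanics analysis of nanoscale DNA force spectrometers
(nDFS) — DNA-origami hinges whose two stiff arms apply piconewton-scale
tension or compression to a molecule spanning them. The package turns
per-particle hinge-angle measurements (e.g. from negative-stain TEM) into
free-energy landscapes, torques and forces, and predicts how an
incorporated polymer sample or nucleosome reshapes the hinge's angular
distribution.

## Who this is for

Groups building or analyzing dynamic DNA-origami mechanical devices:
hinge/caliper designs used as force probes, molecular calipers, or
single-molecule actuators. The only experimental input required is a table
of hinge angles, one per imaged particle.

## What it computes

**Angular free-energy landscapes (Boltzmann inversion).** For an
equilibrated ensemble with angular density p(θ),

&nbsp;&nbsp;&nbsp;&nbsp;G(θ) = −k_BT ln p(θ),

minimum-shifted to zero and restricted to angles with density ≥ 0.001 per
degree. Torque is τ(θ) = −dG/dθ (differentiated on a smoothing-spline
fit), and the force on a sample held at radial position d along the arms
is F = τ/d. Uncertainties come from bootstrap resampling (default 50
replicates).

**Polymer statistics of the incorporated sample.** Flexible linkages are
Gaussian chains, p(R) ∝ exp(−3R²/2nb²); the dsDNA sample is a stiff
worm-like chain with the closed-form end-to-end density of Frey and
co-workers, a two-branch series in x = (l_p/L_c)(1 − R/L_c) switched at
x = 0.2. Boltzmann inversion of the WLC density gives the compressive
force F = −dG/dr, which plateaus at π² l_p k_BT / L_c².

**Hinge–sample coupling.** The angle distribution of a hinge with an
incorporated sample weights the free-hinge prior by the polymer factors
under the closure constraint |**R**_p1 + **R**_p2 + **R**_D| = 2L sin(θ/2),
evaluated by spherical-grid summation over both linker vectors (ΔR = 2 nm)
with the sample extension fixed exactly by closure. An
importance-sampling Monte-Carlo oracle cross-checks the grid sum.

**Nucleosome unwrapping.** Unwrapping states (n₁, n₂ base pairs released
from the two ends of the 147 bp wrap) map to hinge angles through a
tangent-line geometry; state weights P_θ(n₁,n₂) · exp(−ε(n₁,n₂)/k_BT) are
summed into 3 bp bins of total unwrapping and normalized by the partition
function. The unwrapping energy ε is pluggable (default: piecewise
per-bp adhesion, weak outer turn / strong inner turn).

**Euler elastica.** The compressed duplex as a post-buckled pinned-pinned
rod: e/L_c = 2E(k)/K(k) − 1 and F = 4K(k)² EI/L_c² with EI = l_p k_BT.

## Worked example

```python
import ndfs

# synthetic open-biased device ensemble (mean ~83 deg), N = 500 particles
ens = ndfs.generate_angle_ensemble(
    ndfs.DeviceVariantModel.preset("nDFS.B"), N=500, seed=1)
dist = ndfs.estimate_density(ens)                       # 5-degree bins
scape = ndfs.boltzmann_free_energy(dist)                # G(theta) in kBT
profile = ndfs.force_map(ndfs.torque_profile(scape))    # tau and F(theta, d)
boot = ndfs.bootstrap_uncertainty(ens, "mean", seed=1)

wlc = ndfs.WLCSpec(Lc=85.0, lp=50.0)                    # 249 bp sample
rod = ndfs.ElasticaSpec.from_wlc(wlc)
nuc = ndfs.NucleosomeSpec()
```

Output printed by the snippet above (full version in `docs/methods.md`):

```
peak angle:        81.4 deg
mean angle:        82.3 +/- 0.5 deg (bootstrap)
landscape range:   60-115 deg
force map range:   -2.86 to 4.49 pN
WLC mean EED:      61.4 nm
WLC force @49nm:   0.279 pN
elastica @49nm:    0.359 pN  (critical 0.281 pN)
coupled peak:      74.9 deg (free hinge 81.4 deg)
mean unwrapping:   57.8 bp (open-biased device)
constrained peak:  52.5 deg
```

Reading: the open-biased device explores 60–115° and can exert roughly
−3 pN (compression) to +4.5 pN (tension) on a sample at the arm tips.
A free 85 nm duplex has a mean end-to-end distance of 61.4 nm; bending it
to 49 nm costs ~0.28 pN (WLC) or ~0.36 pN (elastica). Incorporating the
duplex shifts the hinge peak from 81° to 75°; incorporating a nucleosome
constrains the hinge near 52° and biases the nucleosome tens of base
pairs open.

A CLI mirrors the library (`ndfs simulate`, `ndfs landscape`,
`ndfs couple`, `ndfs nucleosome`, `ndfs elastica`, `ndfs pipeline`); see
`ndfs --help`.

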