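"""Coupled hinge-linker-sample statistics.

A sample molecule spans the tips of the two hinge arms through a flexible
linkage at each end (Gaussian chain) while the middle section is a
stiff worm-like chain. In any conformation the three end-to-end vectors must
close onto the chord between the arm tips:

    |R_p1 + R_p2 + R_D| = 2 L sin(theta / 2),

with L the attachment radius and theta the hinge angle. The angle
distribution of the coupled system is the free-hinge distribution
reweighted by the polymer statistics,

    P(theta)  prop.to  p_hinge(theta) * sum over linker conformations of
               p(R_p1) p(R_p2) p_dsDNA(R_D),

where the sum runs over a spherical grid of both linker end-to-end vectors
(spacing dR, angular spacings dR/R and dR/(R sin t), radial cutoff n*b)
and R_D is fixed exactly by the closure constraint. The chord is placed on
a fixed axis and the overall azimuth of the first linker is integrated out
analytically (the closure distance depends only on the relative azimuth),
which reduces the six-dimensional sum to five dimensions.

Free energy and force on the sample follow by Boltzmann inversion of P and
the chain rule dr/dtheta = L cos(theta/2). The sign convention matches the
single-polymer module: F = -dG/dr is positive when the coupled free energy
falls with increasing tip separation, i.e. when the sample bears a
compressive load and pushes the arm tips apart; negative F means the sample
is held under tension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ModelError, ParameterError
from .landscape import AngularDistribution
from .polymer import (
    GaussianChainSpec,
    ThermalScale,
    WLCSpec,
    gaussian_eed_pdf,
    wlc_frey_pdf,
)


@dataclass(frozen=True)
class HingeGeometry:
    """Arm length and sample attachment radius (nm), vertex at the origin."""

    arm_length: float = 61.0
    attachment_radius: float = None

    def __post_init__(self) -> None:
        if self.attachment_radius is None:
            object.__setattr__(self, "attachment_radius", self.arm_length)
        if not self.arm_length > 0:
            raise ParameterError(f"arm length must be positive, got {self.arm_length}")
        if not (0 < self.attachment_radius <= self.arm_length):
            raise ParameterError(
                "attachment radius must lie in (0, arm_length], got "
                f"{self.attachment_radius} with arm length {self.arm_length}"
            )


def chord_distance(theta, geometry: HingeGeometry = HingeGeometry()):
    """Tip-to-tip chord 2 a sin(theta/2) at hinge angle ``theta`` (degrees) -> nm."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 180)):
        raise DomainError("hinge angle must lie in [0, 180] degrees")
    out = 2.0 * geometry.attachment_radius * np.sin(np.radians(theta) / 2.0)
    return out if out.ndim else float(out)


def chord_to_angle(r, geometry: HingeGeometry = HingeGeometry()):
    """Inverse chord relation; spans beyond 2a clamp to 180 degrees."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise DomainError("chord distance must be non-negative")
    ratio = np.clip(r / (2.0 * geometry.attachment_radius), 0.0, 1.0)
    out = 2.0 * np.degrees(np.arcsin(ratio))
    return out if out.ndim else float(out)


@dataclass
class CoupledSystemSpec:
    """Hinge prior + two Gaussian linkers + WLC sample + geometry."""

    hinge_dist: AngularDistribution
    linker1: GaussianChainSpec
    linker2: GaussianChainSpec
    sample: WLCSpec
    geometry: HingeGeometry = field(default_factory=HingeGeometry)
    grid_spacing: float = 2.0

    def __post_init__(self) -> None:
        if not self.grid_spacing > 0:
            raise ParameterError(f"grid spacing must be positive, got {self.grid_spacing}")


def _spherical_grid(spec: GaussianChainSpec, dR: float, reduce_azimuth: bool = False):
    """Quadrature nodes and weights for a 3-D Gaussian-chain vector.

    Nodes are cell centers of a spherical grid with radial spacing ``dR``,
    polar spacing ~dR/R and azimuthal spacing ~dR/(R sin t), truncated at the
    full extension R = n*b. Weights are the Gaussian vector density times the
    exact cell volume. With ``reduce_azimuth`` the azimuth is collapsed to a
    single node in the x-z plane carrying the full 2*pi ring weight; this is
    exact whenever the integrand depends on azimuth only relatively.
    """
    rmax = spec.max_extent
    radii = np.arange(0.5 * dR, rmax, dR)
    if radii.size == 0:
        radii = np.array([0.5 * rmax])
    pts = []
    wts = []
    for r in radii:
        ntheta = max(1, int(round(np.pi * r / dR)))
        dtheta = np.pi / ntheta
        p_r = gaussian_eed_pdf(r, spec)
        for j in range(ntheta):
            t = (j + 0.5) * dtheta
            nphi = max(1, int(round(2.0 * np.pi * r * np.sin(t) / dR)))
            dphi = 2.0 * np.pi / nphi
            w_cell = p_r * r ** 2 * np.sin(t) * dR * dtheta * dphi
            if reduce_azimuth:
                pts.append((r * np.sin(t), 0.0, r * np.cos(t)))
                wts.append(w_cell * nphi)
            else:
                for m in range(nphi):
                    phi = (m + 0.5) * dphi
                    pts.append(
                        (r * np.sin(t) * np.cos(phi), r * np.sin(t) * np.sin(phi), r * np.cos(t))
                    )
                    wts.append(w_cell)
    return np.asarray(pts), np.asarray(wts)


def _closure_kernel(spec: CoupledSystemSpec, chords: np.ndarray) -> np.ndarray:
    """For each chord length, the grid sum of linker weights times the WLC
    density at the closure-implied sample end-to-end distance."""
    pts1, w1 = _spherical_grid(spec.linker1, spec.grid_spacing, reduce_azimuth=True)
    pts2, w2 = _spherical_grid(spec.linker2, spec.grid_spacing, reduce_azimuth=False)
    # pairwise linker-vector sums, flattened
    s = pts1[:, None, :] + pts2[None, :, :]
    s = s.reshape(-1, 3)
    W = (w1[:, None] * w2[None, :]).ravel()
    rho2 = s[:, 0] ** 2 + s[:, 1] ** 2
    sz = s[:, 2]
    kernel = np.empty(chords.shape)
    for i, c in enumerate(chords):
        r_d = np.sqrt(rho2 + (c - sz) ** 2)
        kernel[i] = np.dot(W, wlc_frey_pdf(r_d, spec.sample))
    return kernel


def predict_coupled_angle_distribution(spec: CoupledSystemSpec) -> AngularDistribution:
    """Angle distribution of the hinge with the sample incorporated.

    Evaluated on the hinge prior's bins; renormalized to integrate to one.
    Bins where the closure is infeasible for every grid conformation (the
    required sample extension reaches the contour length) get zero density.
    """
    prior = spec.hinge_dist.normalized()
    centers = prior.bin_centers
    chords = chord_distance(np.clip(centers, 0.0, 180.0), spec.geometry)
    kernel = _closure_kernel(spec, chords)
    weights = prior.density * kernel
    total = np.sum(weights * prior.bin_widths)
    if total <= 0:
        raise ModelError(
            "coupled model assigns zero probability everywhere: the sample "
            "cannot span the hinge at any angle with prior support"
        )
    return AngularDistribution(prior.bin_edges, weights / total)


@dataclass
class CoupledLandscape:
    """Free energy (kBT) and sample force (pN) of the coupled system.

    ``force`` is F = -dG/dr along the chord; positive = the sample pushes the
    arm tips apart (it bears a compressive load), negative = tension.
    """

    theta: np.ndarray
    G: np.ndarray
    force: np.ndarray
    distribution: AngularDistribution


def coupled_free_energy_and_force(
    spec: CoupledSystemSpec, thermal: ThermalScale = ThermalScale()
) -> CoupledLandscape:
    """Boltzmann-invert the coupled distribution and differentiate along the chord."""
    dist = predict_coupled_angle_distribution(spec)
    pos = dist.density > 0
    if np.count_nonzero(pos) < 3:
        raise ModelError("coupled distribution has fewer than 3 bins with support")
    idx = np.flatnonzero(pos)
    if np.any(np.diff(idx) != 1):
        import warnings

        warnings.warn(
            "zero-density bins inside the support were excluded from the "
            "coupled free-energy landscape",
            stacklevel=2,
        )
    theta = dist.bin_centers[pos]
    G = -np.log(dist.density[pos])
    G = G - G.min()
    r = chord_distance(theta, spec.geometry)
    force = -thermal.kBT * np.gradient(G, r)
    return CoupledLandscape(theta=theta, G=G, force=force, distribution=dist)
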