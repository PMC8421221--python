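"""Nucleosome unwrapping under a hinge-imposed angular bias.

A nucleosome spanning the arm tips constrains the hinge: each unwrapping
state, indexed by the base pairs (n1, n2) released from the two ends of the
147 bp wrapped superhelix, fixes the end-to-end span of the
linker-nucleosome-linker assembly and hence a hinge angle theta(n1, n2)
through the chord relation. Unwrapped DNA (and the flanking linker DNA) is
taken to leave the histone surface along the tangent at the last point of
contact and to remain straight.

The joint weight of a state combines the device's angular probability with
the Boltzmann factor of the unwrapping free energy eps(n1, n2):

    weight(n1, n2) = P_theta(n1, n2) * exp(-eps(n1, n2) / kBT).

Binning the total n1 + n2 into w-bp bins i and normalizing by the partition
function Z (the sum of all weights) gives the unwrapping probability density
p_i = sum_{(n1,n2) in i} weight / (w Z). Marginalizing the same weights over
angle bins gives the constrained device angle distribution.

eps is pluggable. The default is a piecewise-constant net adhesion per base
pair: a weak outer-turn contact energy (thermally accessible, so free
nucleosomes breathe) and a stronger inner-turn energy. Absolute unwrapping
totals depend on this calibration and should be read as model-conditional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ModelError, ParameterError
from .coupling import HingeGeometry, chord_to_angle
from .landscape import AngularDistribution, FreeEnergyLandscape
from .polymer import RISE_PER_BP_NM, ThermalScale


@dataclass(frozen=True)
class PiecewiseAdhesionModel:
    """Per-bp net unwrapping free energy (kBT): weak outer turn, strong inner.

    gamma(k) = gamma_outer for the first ``outer_bp`` base pairs unwrapped
    from an end, gamma_inner beyond; eps(n1, n2) sums gamma over all
    unwrapped positions and is therefore additive across the two ends.
    """

    outer_bp: int = 35
    gamma_outer: float = 0.15
    gamma_inner: float = 1.0

    def per_end_energy(self, n) -> np.ndarray:
        """Cumulative unwrapping energy for ``n`` bp released from one end (kBT)."""
        n = np.asarray(n)
        k = np.arange(int(n.max()) + 1 if n.size else 1)
        gamma = np.where(k < self.outer_bp, self.gamma_outer, self.gamma_inner)
        cumulative = np.concatenate([[0.0], np.cumsum(gamma)])
        out = cumulative[n]
        return out if out.ndim else float(out)

    def energy(self, n1, n2) -> np.ndarray:
        return self.per_end_energy(np.asarray(n1)) + self.per_end_energy(np.asarray(n2))


@dataclass
class NucleosomeSpec:
    """Geometry and energetics of the wrapped construct.

    Defaults describe the 249 bp construct: a 147 bp superhelical wrap with
    51 bp of straight linker on each side, canonical crystallographic
    superhelix (radius 4.18 nm, 1.67 turns, pitch 2.39 nm).
    """

    total_bp: int = 249
    wrapped_bp: int = 147
    linker_bp: int = 51
    superhelix_radius: float = 4.18
    superhelix_turns: float = 1.67
    superhelix_pitch: float = 2.39
    rise_per_bp: float = RISE_PER_BP_NM
    energy_model: PiecewiseAdhesionModel = field(default_factory=PiecewiseAdhesionModel)
    angle_bin: float = 5.0
    unwrap_bin: int = 3
    geometry_backend: str = "planar"

    def __post_init__(self) -> None:
        if self.wrapped_bp + 2 * self.linker_bp > self.total_bp:
            raise ParameterError(
                "wrapped_bp + 2*linker_bp exceeds total_bp "
                f"({self.wrapped_bp} + 2*{self.linker_bp} > {self.total_bp})"
            )
        if self.geometry_backend not in ("planar", "helix3d"):
            raise ParameterError(f"unknown geometry backend {self.geometry_backend!r}")

    @property
    def wrap_angle_per_bp(self) -> float:
        """Superhelical winding per wrapped base pair (radians)."""
        return self.superhelix_turns * 2.0 * np.pi / self.wrapped_bp


def _validate_states(n1, n2, spec: NucleosomeSpec):
    n1 = np.asarray(n1)
    n2 = np.asarray(n2)
    if np.any(n1 < 0) or np.any(n2 < 0) or np.any(n1 + n2 > spec.wrapped_bp):
        raise DomainError(
            "unwrapping state requires n1, n2 >= 0 and n1 + n2 <= wrapped_bp"
        )
    return n1, n2


def unwrap_span(n1, n2, spec: NucleosomeSpec):
    """End-to-end span (nm) of linker + unwrapped tangents + remaining wrap.

    The planar backend projects the superhelix onto its winding plane; the
    helix3d backend keeps the superhelical pitch. Both extend each free DNA
    segment of (n_i + linker_bp) base pairs straight along the exit tangent.
    """
    n1, n2 = _validate_states(n1, n2, spec)
    abp = spec.wrap_angle_per_bp
    R = spec.superhelix_radius
    l1 = (n1 + spec.linker_bp) * spec.rise_per_bp
    l2 = (n2 + spec.linker_bp) * spec.rise_per_bp
    if spec.geometry_backend == "planar":
        phi_w = (spec.wrapped_bp - n1 - n2) * abp
        pA = -phi_w / 2.0
        pB = phi_w / 2.0
        e1x = R * np.cos(pA) + l1 * np.sin(pA)
        e1y = R * np.sin(pA) - l1 * np.cos(pA)
        e2x = R * np.cos(pB) - l2 * np.sin(pB)
        e2y = R * np.sin(pB) + l2 * np.cos(pB)
        out = np.hypot(e1x - e2x, e1y - e2y)
    else:
        # 3-D superhelix with pitch: wrap runs phi in [n1*abp, Phi - n2*abp]
        pitch_rate = spec.superhelix_pitch / (2.0 * np.pi)
        phi_full = spec.superhelix_turns * 2.0 * np.pi
        pA = n1 * abp
        pB = phi_full - n2 * abp
        tnorm = np.sqrt(R ** 2 + pitch_rate ** 2)

        def pos(phi):
            return np.stack(
                [R * np.cos(phi), R * np.sin(phi), pitch_rate * phi], axis=-1
            )

        def tangent(phi):
            return np.stack(
                [-R * np.sin(phi) / tnorm, R * np.cos(phi) / tnorm,
                 np.broadcast_to(pitch_rate / tnorm, np.shape(phi))],
                axis=-1,
            )

        e1 = pos(pA) - np.asarray(l1)[..., None] * tangent(pA)
        e2 = pos(pB) + np.asarray(l2)[..., None] * tangent(pB)
        out = np.linalg.norm(e1 - e2, axis=-1)
    return out if np.ndim(out) else float(out)


def unwrap_geometry_angle(
    n1, n2, spec: NucleosomeSpec, geometry: HingeGeometry = HingeGeometry()
):
    """Hinge angle theta(n1, n2) in degrees implied by the unwrapped span.

    Spans exceeding the fully open chord 2a clamp to 180 degrees with a
    warning.
    """
    span = np.asarray(unwrap_span(n1, n2, spec))
    if np.any(span > 2.0 * geometry.attachment_radius):
        warnings.warn(
            "unwrapped span exceeds the fully open chord; clamping to 180 degrees",
            stacklevel=2,
        )
    out = chord_to_angle(np.minimum(span, 2.0 * geometry.attachment_radius), geometry)
    return out if np.ndim(out) else float(out)


def unwrap_energy(n1, n2, spec: NucleosomeSpec):
    """Unwrapping free energy eps(n1, n2) in kBT; eps(0, 0) = 0."""
    n1, n2 = _validate_states(n1, n2, spec)
    out = spec.energy_model.energy(n1, n2)
    return out if np.ndim(out) else float(out)


@dataclass
class UnwrappingDistribution:
    """Probability density over binned total unwrapped base pairs (per bp)."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def integral(self) -> float:
        return float(np.sum(self.density) * self.bin_width)

    @property
    def mean(self) -> float:
        """Mean total unwrapped base pairs from the binned density."""
        return float(np.sum(self.bin_centers * self.density) * self.bin_width)


def _state_table(spec: NucleosomeSpec, geometry: HingeGeometry):
    n = np.arange(spec.wrapped_bp + 1)
    n1, n2 = np.meshgrid(n, n, indexing="ij")
    valid = (n1 + n2) <= spec.wrapped_bp
    n1 = n1[valid]
    n2 = n2[valid]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        theta = unwrap_geometry_angle(n1, n2, spec, geometry)
    eps = unwrap_energy(n1, n2, spec)
    return n1, n2, theta, eps


def _state_weights(
    device_dist: AngularDistribution,
    spec: NucleosomeSpec,
    geometry: HingeGeometry,
    flat_prior: bool,
):
    n1, n2, theta, eps = _state_table(spec, geometry)
    if flat_prior:
        p_theta = np.ones_like(theta)
    else:
        p_theta = np.asarray(device_dist.normalized().density_at(theta))
    w = p_theta * np.exp(-eps)
    Z = w.sum()
    if Z <= 0:
        raise ModelError(
            "device distribution assigns zero probability to every reachable "
            "unwrapping-state angle"
        )
    return n1, n2, theta, w, Z


def predict_unwrap_distribution(
    device_dist: AngularDistribution,
    spec: NucleosomeSpec = None,
    geometry: HingeGeometry = HingeGeometry(),
    flat_prior: bool = False,
) -> UnwrappingDistribution:
    """Probability density of total unwrapped base pairs under the device bias.

    Exhaustively enumerates all (n1, n2) states; ``flat_prior`` replaces the
    device distribution by a constant (a free nucleosome in a force-free
    frame), in which case only the Boltzmann factors survive.
    """
    spec = spec if spec is not None else NucleosomeSpec()
    n1, n2, _, w, Z = _state_weights(device_dist, spec, geometry, flat_prior)
    width = spec.unwrap_bin
    total = n1 + n2
    nbins = spec.wrapped_bp // width + 1
    edges = np.arange(nbins + 1) * width
    mass = np.bincount(total // width, weights=w, minlength=nbins)[:nbins]
    return UnwrappingDistribution(bin_edges=edges, density=mass / (width * Z))


def mean_total_unwrapped(
    device_dist: AngularDistribution,
    spec: NucleosomeSpec = None,
    geometry: HingeGeometry = HingeGeometry(),
    flat_prior: bool = False,
) -> float:
    """Exact (unbinned) mean of n1 + n2 under the joint state weights."""
    spec = spec if spec is not None else NucleosomeSpec()
    n1, n2, _, w, Z = _state_weights(device_dist, spec, geometry, flat_prior)
    return float(np.sum((n1 + n2) * w) / Z)


def predict_constrained_angle_distribution(
    device_dist: AngularDistribution,
    spec: NucleosomeSpec = None,
    geometry: HingeGeometry = HingeGeometry(),
    flat_prior: bool = False,
) -> AngularDistribution:
    """Device angle distribution with the nucleosome incorporated.

    Marginalizes the joint state weights over the angle bins the states map
    into; normalized per degree on a [0, 180] grid of ``spec.angle_bin`` bins.
    """
    spec = spec if spec is not None else NucleosomeSpec()
    _, _, theta, w, Z = _state_weights(device_dist, spec, geometry, flat_prior)
    edges = np.arange(0.0, 180.0 + spec.angle_bin / 2, spec.angle_bin)
    idx = np.clip(
        np.searchsorted(edges, theta, side="right") - 1, 0, edges.size - 2
    )
    mass = np.bincount(idx, weights=w, minlength=edges.size - 1)
    density = mass / (Z * spec.angle_bin)
    return AngularDistribution(edges, density)


def tensile_force_estimate(
    landscape: FreeEnergyLandscape,
    theta_star: float,
    geometry: HingeGeometry = HingeGeometry(),
    thermal: ThermalScale = ThermalScale(),
    step_deg: float = 0.1,
) -> float:
    """Force the free device exerts at the constrained angle theta_star (pN).

    Differentiates the free-device landscape spline at theta_star and
    projects onto the chord: F = -(dG/dtheta) / (dr/dtheta) * kBT with
    dr/dtheta = a cos(theta/2). Positive values mean tension on the sample
    (the landscape falls toward larger angles, so the device pulls open).
    """
    lo, hi = landscape.valid_range
    if not (lo + step_deg <= theta_star <= hi - step_deg):
        raise DomainError(
            f"theta_star={theta_star} is at or beyond the landscape valid range "
            f"[{lo}, {hi}]; the derivative is undefined there"
        )
    g_hi = landscape.g_at(theta_star + step_deg)
    g_lo = landscape.g_at(theta_star - step_deg)
    dG_drad = (g_hi - g_lo) / (2.0 * np.radians(step_deg))
    dr_drad = geometry.attachment_radius * np.cos(np.radians(theta_star) / 2.0)
    return float(-thermal.kBT * dG_drad / dr_drad)
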