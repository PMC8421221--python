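"""Boltzmann-inversion analysis of hinge-angle ensembles.

A device's conformational ensemble is observed as one hinge angle per
particle. Assuming the ensemble is equilibrated, the angular probability
density p(theta) maps onto a free-energy landscape

    G(theta) = -kBT ln p(theta),

shifted so its minimum over the well-sampled range is zero. The landscape is
restricted to angles where the density exceeds a cutoff (default 0.001 per
degree) because -ln p diverges where conformations are rarely observed.
Torque follows by differentiating a smoothing-spline fit to G, force at a
radial position d along an arm by dividing torque by d, and uncertainties by
bootstrap resampling of the ensemble.

Angles are degrees at every interface; derivatives are taken per radian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline, make_smoothing_spline

from .exceptions import DomainError, EstimationError, InputError
from .polymer import ThermalScale

#: Ensemble size below which the angular distribution is not yet converged.
CONVERGENCE_N = 150

#: Default probability-density cutoff (per degree) for landscape validity.
DENSITY_CUTOFF = 0.001

#: Default histogram bin width in degrees.
DEFAULT_BIN_WIDTH = 5.0

#: Default radial range along the arms for force maps (nm). The lower bound
#: is one cross-over repeat (32 bp) of the square-lattice bundle, the upper
#: bound the arm length.
DEFAULT_RADIAL_RANGE = (11.0, 61.0)


@dataclass
class AngleEnsemble:
    """Per-particle hinge angles (degrees) for one device variant."""

    angles: np.ndarray
    device_label: str = ""
    source: str = "measured"

    def __post_init__(self) -> None:
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if self.angles.size < 1:
            raise InputError("angle ensemble must contain at least one angle")
        if np.any(~np.isfinite(self.angles)):
            raise InputError("angle ensemble contains non-finite values")
        if np.any((self.angles <= 0) | (self.angles >= 180)):
            raise InputError("hinge angles must lie strictly inside (0, 180) degrees")

    def __len__(self) -> int:
        return int(self.angles.size)


@dataclass
class AngularDistribution:
    """Histogram density over hinge angle, normalized per degree."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.density.size + 1:
            raise InputError("bin_edges must have one more entry than density")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise InputError("bin_edges must be strictly ascending")
        if np.any(self.density < 0):
            raise InputError("density must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def bin_width(self) -> float:
        widths = self.bin_widths
        if not np.allclose(widths, widths[0]):
            raise InputError("bins are not uniform")
        return float(widths[0])

    @property
    def probabilities(self) -> np.ndarray:
        """Per-bin probability mass (density times width)."""
        return self.density * self.bin_widths

    @property
    def integral(self) -> float:
        return float(np.sum(self.probabilities))

    def normalized(self) -> "AngularDistribution":
        total = self.integral
        if total <= 0:
            raise InputError("cannot normalize an all-zero distribution")
        return AngularDistribution(self.bin_edges, self.density / total)

    def density_at(self, theta) -> np.ndarray:
        """Step-function lookup of the density at angle(s) ``theta`` (per degree)."""
        theta = np.asarray(theta, dtype=float)
        idx = np.searchsorted(self.bin_edges, theta, side="right") - 1
        inside = (idx >= 0) & (idx < self.density.size) & (theta < self.bin_edges[-1])
        out = np.where(inside, self.density[np.clip(idx, 0, self.density.size - 1)], 0.0)
        return out if out.ndim else float(out)


@dataclass
class FreeEnergyLandscape:
    """G(theta) in kBT units on the well-sampled angle range.

    ``spline`` is a smoothing-spline fit to (theta_grid, G), valid only on
    ``valid_range``.
    """

    theta_grid: np.ndarray
    G: np.ndarray
    valid_range: tuple
    spline: Callable = field(repr=False, default=None)

    def g_at(self, theta) -> np.ndarray:
        """Spline-evaluated free energy (kBT) at ``theta`` inside the valid range."""
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.valid_range
        if np.any(theta < lo) or np.any(theta > hi):
            raise DomainError(f"angle outside landscape valid range [{lo}, {hi}]")
        out = self.spline(theta)
        return out if out.ndim else float(out)


@dataclass
class TorqueForceProfile:
    """Torque (pN nm) versus angle, optionally with a (theta, d) force map.

    Sign convention: positive torque acts to open the hinge; dividing by a
    radial coordinate d gives the force on a sample held at d, positive
    meaning tensile (pulling the arms together is resisted).
    """

    theta_grid: np.ndarray
    torque: np.ndarray
    d_grid: np.ndarray = None
    force_map: np.ndarray = None


@dataclass
class BootstrapResult:
    point_estimate: float
    standard_deviation: float
    replicates: int
    skipped: int = 0


def _aligned_edges(angles: np.ndarray, bin_width: float) -> np.ndarray:
    # Bin centers sit on integer multiples of the bin width so that, e.g.,
    # 85 deg is the center of [82.5, 87.5) for 5-degree bins.
    k_lo = int(np.floor(angles.min() / bin_width + 0.5))
    k_hi = int(np.floor(angles.max() / bin_width + 0.5))
    return (np.arange(k_lo, k_hi + 2) - 0.5) * bin_width


def estimate_density(
    ensemble: AngleEnsemble,
    bin_width: float = DEFAULT_BIN_WIDTH,
    bin_edges: Sequence[float] = None,
) -> AngularDistribution:
    """Histogram the ensemble into a probability density per degree.

    Bins are aligned so their centers fall on integer multiples of
    ``bin_width`` unless explicit ``bin_edges`` are given. Warns when the
    ensemble is smaller than the empirical convergence size of ~150.
    """
    if bin_edges is None:
        if not bin_width > 0:
            raise InputError(f"bin width must be positive, got {bin_width}")
        bin_edges = _aligned_edges(ensemble.angles, bin_width)
    if len(ensemble) < CONVERGENCE_N:
        warnings.warn(
            f"ensemble size {len(ensemble)} is below the ~{CONVERGENCE_N} "
            "convergence threshold; the landscape may be under-sampled",
            stacklevel=2,
        )
    density, edges = np.histogram(ensemble.angles, bins=bin_edges, density=True)
    return AngularDistribution(edges, density)


def boltzmann_free_energy(
    dist: AngularDistribution,
    cutoff: float = DENSITY_CUTOFF,
    smoothing: float = None,
) -> FreeEnergyLandscape:
    """Boltzmann-invert a density into a free-energy landscape (kBT units).

    Bins with density below ``cutoff`` are excluded; the landscape minimum is
    shifted to zero. A cubic smoothing spline is fit to the retained points
    (``smoothing`` is the penalty parameter; None selects it by generalized
    cross-validation).
    """
    keep = dist.density >= cutoff
    if not np.any(keep):
        raise EstimationError("all bins fall below the density cutoff")
    theta = dist.bin_centers[keep]
    G = -np.log(dist.density[keep])
    G = G - G.min()
    if theta.size >= 5:
        spline = make_smoothing_spline(theta, G, lam=smoothing)
    else:
        spline = make_interp_spline(theta, G, k=min(3, theta.size - 1))
    return FreeEnergyLandscape(
        theta_grid=theta,
        G=G,
        valid_range=(float(theta[0]), float(theta[-1])),
        spline=spline,
    )


def torque_profile(
    landscape: FreeEnergyLandscape,
    thermal: ThermalScale = ThermalScale(),
    step_deg: float = 0.1,
    method: str = "fd",
) -> TorqueForceProfile:
    """Torque tau(theta) = -dG/dtheta (per radian) times kBT, in pN nm.

    ``method='fd'`` (default) differentiates spline evaluations on a fine
    grid by central differences; ``method='spline'`` uses the analytic
    derivative of the spline.
    """
    if landscape.theta_grid.size < 3:
        raise EstimationError("landscape has fewer than 3 valid grid points")
    lo, hi = landscape.valid_range
    grid = np.arange(lo, hi + 0.5 * step_deg, step_deg)
    grid = np.clip(grid, lo, hi)
    if method == "spline":
        dG_ddeg = landscape.spline.derivative()(grid)
    elif method == "fd":
        dG_ddeg = np.gradient(landscape.spline(grid), grid)
    else:
        raise InputError(f"unknown differentiation method {method!r}")
    dG_drad = dG_ddeg * (180.0 / np.pi)
    torque = -thermal.kBT * dG_drad
    return TorqueForceProfile(theta_grid=grid, torque=torque)


def force_map(
    profile: TorqueForceProfile,
    d_min: float = DEFAULT_RADIAL_RANGE[0],
    d_max: float = DEFAULT_RADIAL_RANGE[1],
    num: int = 101,
) -> TorqueForceProfile:
    """Force surface F(theta, d) = torque(theta)/d over a radial range (pN)."""
    if not (0 < d_min < d_max):
        raise DomainError(f"radial range requires 0 < d_min < d_max, got [{d_min}, {d_max}]")
    d = np.linspace(d_min, d_max, num)
    F = profile.torque[:, None] / d[None, :]
    return replace(profile, d_grid=d, force_map=F)


def peak_angle(dist: AngularDistribution, smoothing: float = None) -> float:
    """Most likely angle: argmax of a spline-smoothed density (degrees)."""
    centers = dist.bin_centers
    pos = dist.density > 0
    if np.count_nonzero(pos) < 5:
        return float(centers[np.argmax(dist.density)])
    spline = make_smoothing_spline(centers[pos], dist.density[pos], lam=smoothing)
    fine = np.arange(centers[pos][0], centers[pos][-1] + 0.05, 0.1)
    return float(fine[np.argmax(spline(fine))])


def _ensemble_mean(angles: np.ndarray) -> float:
    return float(np.mean(angles))


def _ensemble_peak(angles: np.ndarray) -> float:
    ens = AngleEnsemble(angles, source="bootstrap")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return peak_angle(estimate_density(ens))


STATISTICS: dict = {
    "mean": _ensemble_mean,
    "median": lambda a: float(np.median(a)),
    "std": lambda a: float(np.std(a, ddof=1)),
    "peak_angle": _ensemble_peak,
}


def bootstrap_uncertainty(
    ensemble: AngleEnsemble,
    statistic,
    replicates: int = 50,
    seed: int = None,
) -> BootstrapResult:
    """Bootstrap mean and SD of a statistic of the angle ensemble.

    Each replicate resamples N angles with replacement from the N observed
    ones and recomputes the statistic (a name from ``STATISTICS`` or a
    callable on a 1-D angle array). Replicates on which the statistic is
    undefined are skipped and counted; more than 50% skips is an error.
    """
    if replicates < 2:
        raise InputError("bootstrap requires at least 2 replicates")
    stat_fn = STATISTICS[statistic] if isinstance(statistic, str) else statistic
    rng = np.random.default_rng(seed)
    n = len(ensemble)
    values = []
    skipped = 0
    for _ in range(replicates):
        sample = rng.choice(ensemble.angles, size=n, replace=True)
        try:
            values.append(float(stat_fn(sample)))
        except Exception:
            skipped += 1
    if skipped > replicates / 2:
        raise EstimationError(
            f"statistic undefined on {skipped}/{replicates} bootstrap replicates"
        )
    values = np.asarray(values)
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return BootstrapResult(
        point_estimate=float(np.mean(values)),
        standard_deviation=sd,
        replicates=replicates,
        skipped=skipped,
    )
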