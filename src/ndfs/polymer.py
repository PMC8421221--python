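"""Closed-form polymer statistics for hinge-coupled samples.

Two chain models are provided. Flexible linkages (short ssDNA overhangs plus
a biotin-neutravidin bridge, lumped together) are described by the Gaussian
chain, whose end-to-end vector is normally distributed with variance n*b**2
(n Kuhn segments of length b). The dsDNA sample is described by the
stiff-polymer (large lp/Lc) approximation to the worm-like chain due to
Frey and co-workers, which gives the scalar end-to-end distance density as a
rapidly converging series in the compression variable

    x = (lp/Lc) * (1 - R/Lc).

Two dual series representations are used, switched at x = 0.2: a
three-term exponential series for strongly compressed chains (x > 0.2) and a
three-term image-sum series with a 1/(8 (pi x)^(3/2)) prefactor near full
extension (x <= 0.2). The two branches agree to high accuracy at the switch
point. Free energies follow by Boltzmann inversion, G(R) = -kBT ln p(R), and
the compressive force borne by the chain by F = -dG/dR.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize

from .exceptions import DomainError, ParameterError

#: Thermal energy at 298 K, in pN nm.
KBT_PN_NM = 4.114

#: Helical rise of B-form DNA, nm per base pair.
RISE_PER_BP_NM = 0.34

#: Branch switch point of the stiff-polymer series.
_FREY_SWITCH = 0.2


@dataclass(frozen=True)
class GaussianChainSpec:
    """Gaussian (flexible) chain: ``n`` Kuhn segments of length ``b`` (nm).

    ``n`` need not be an integer; only the variance parameter ``n * b**2``
    enters the statistics.
    """

    n: float
    b: float

    def __post_init__(self) -> None:
        if not (self.n > 0 and self.b > 0):
            raise ParameterError(
                f"Gaussian chain requires n > 0 and b > 0, got n={self.n}, b={self.b}"
            )

    @property
    def variance(self) -> float:
        """Mean-square end-to-end distance <R^2> = n b^2 (nm^2)."""
        return self.n * self.b ** 2

    @property
    def rms_eed(self) -> float:
        """Root-mean-square end-to-end distance (nm)."""
        return float(np.sqrt(self.variance))

    @property
    def max_extent(self) -> float:
        """Fully stretched contour, n*b (nm); used as an integration cutoff."""
        return self.n * self.b


@dataclass(frozen=True)
class WLCSpec:
    """Worm-like chain: contour length ``Lc`` and persistence length ``lp`` (nm).

    The stiff-polymer density implemented here is accurate when lp/Lc is not
    small compared to 1 (semiflexible to stiff regime).
    """

    Lc: float
    lp: float

    def __post_init__(self) -> None:
        if not (self.Lc > 0 and self.lp > 0):
            raise ParameterError(
                f"WLC requires Lc > 0 and lp > 0, got Lc={self.Lc}, lp={self.lp}"
            )

    @property
    def stiffness_ratio(self) -> float:
        return self.lp / self.Lc


@dataclass(frozen=True)
class ThermalScale:
    """Thermal energy kBT in pN nm (default: 298 K)."""

    kBT: float = KBT_PN_NM

    def __post_init__(self) -> None:
        if not self.kBT > 0:
            raise ParameterError(f"kBT must be positive, got {self.kBT}")


def contour_length(bp: float, rise_per_bp: float = RISE_PER_BP_NM) -> float:
    """Contour length in nm of a duplex of ``bp`` base pairs."""
    if not bp > 0:
        raise ParameterError(f"base-pair count must be positive, got {bp}")
    if not rise_per_bp > 0:
        raise ParameterError(f"rise per bp must be positive, got {rise_per_bp}")
    return bp * rise_per_bp


def gaussian_eed_pdf(R, spec: GaussianChainSpec):
    """3-D end-to-end vector density of a Gaussian chain at radius ``R`` (nm^-3).

    This is the density of the vector evaluated at magnitude R; the radial
    density of the scalar distance carries an extra 4 pi R^2 factor.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise DomainError("end-to-end distance must be non-negative")
    v = spec.variance
    out = (3.0 / (2.0 * np.pi * v)) ** 1.5 * np.exp(-3.0 * R ** 2 / (2.0 * v))
    return out if out.ndim else float(out)


def frey_shape(x):
    """Dimensionless shape function f(x) of the stiff-polymer EED density.

    Branches switch at x = 0.2; x <= 0 maps to 0 (beyond full extension).
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    hi = x > _FREY_SWITCH
    lo = (~hi) & (x > 0)
    if np.any(hi):
        xh = x[hi]
        out[hi] = (np.pi / 2.0) * (
            np.exp(-np.pi ** 2 * xh)
            - 4.0 * np.exp(-4.0 * np.pi ** 2 * xh)
            + 9.0 * np.exp(-9.0 * np.pi ** 2 * xh)
        )
    if np.any(lo):
        xl = x[lo]
        out[lo] = (
            1.0
            / (8.0 * (np.pi * xl) ** 1.5)
            * (
                (1.0 / xl - 2.0) * np.exp(-1.0 / (4.0 * xl))
                + (9.0 / xl - 2.0) * np.exp(-9.0 / (4.0 * xl))
                + (25.0 / xl - 2.0) * np.exp(-25.0 / (4.0 * xl))
            )
        )
    return out if out.ndim else float(out)


def _frey_unnormalized(R, Lc: float, lp: float):
    R = np.asarray(R, dtype=float)
    x = (lp / Lc) * (1.0 - R / Lc)
    out = (lp / Lc ** 2) * frey_shape(x)
    return np.where(R < Lc, out, 0.0)


@lru_cache(maxsize=128)
def _frey_norm(Lc: float, lp: float) -> float:
    val, _ = integrate.quad(
        lambda r: _frey_unnormalized(r, Lc, lp), 0.0, Lc, limit=200
    )
    return val


@lru_cache(maxsize=128)
def _frey_mode(Lc: float, lp: float) -> float:
    res = optimize.minimize_scalar(
        lambda r: -_frey_unnormalized(r, Lc, lp),
        bounds=(1e-9 * Lc, Lc * (1 - 1e-12)),
        method="bounded",
        options={"xatol": 1e-10 * Lc},
    )
    return float(res.x)


def wlc_frey_pdf(R, spec: WLCSpec, normalized: bool = True):
    """Stiff-polymer WLC end-to-end distance density (nm^-1).

    The density of the scalar end-to-end distance R on (0, Lc); zero at and
    beyond full extension. The normalization constant is computed once per
    (Lc, lp) pair by adaptive quadrature and cached.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise DomainError("end-to-end distance must be non-negative")
    out = _frey_unnormalized(R, spec.Lc, spec.lp)
    if normalized:
        out = out / _frey_norm(spec.Lc, spec.lp)
    return out if out.ndim else float(out)


def wlc_mode(spec: WLCSpec) -> float:
    """Most probable end-to-end distance of the stiff-polymer density (nm)."""
    return _frey_mode(spec.Lc, spec.lp)


@lru_cache(maxsize=128)
def _frey_mean(Lc: float, lp: float) -> float:
    norm = _frey_norm(Lc, lp)
    val, _ = integrate.quad(
        lambda r: r * _frey_unnormalized(r, Lc, lp) / norm, 0.0, Lc, limit=200
    )
    return val


def wlc_mean_eed(spec: WLCSpec) -> float:
    """Mean end-to-end distance of the stiff-polymer density by quadrature (nm)."""
    return _frey_mean(spec.Lc, spec.lp)


def wlc_free_energy(R, spec: WLCSpec, thermal: ThermalScale = ThermalScale()):
    """Free energy G(R) = -kBT ln p(R), shifted to zero at the density mode (pN nm)."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0) or np.any(R >= spec.Lc):
        raise DomainError(f"R must lie strictly inside (0, {spec.Lc}) nm")
    p = _frey_unnormalized(R, spec.Lc, spec.lp)
    p_mode = _frey_unnormalized(_frey_mode(spec.Lc, spec.lp), spec.Lc, spec.lp)
    G = -thermal.kBT * (np.log(p) - np.log(p_mode))
    return G if G.ndim else float(G)


def wlc_compression_force(
    R: float,
    spec: WLCSpec,
    thermal: ThermalScale = ThermalScale(),
    step: float = 0.1,
) -> float:
    """Force F = -dG/dR by a centered finite difference (pN).

    Positive values are the compressive load borne by the chain (R below the
    free-chain mode); negative values correspond to tension beyond the mode.
    The stencil half-width ``step`` must fit inside (0, Lc).
    """
    if not (0 < R < spec.Lc):
        raise DomainError(f"R must lie strictly inside (0, {spec.Lc}) nm")
    if R - step <= 0 or R + step >= spec.Lc:
        raise DomainError(
            f"insufficient stencil: R={R} with step={step} reaches the domain boundary"
        )
    g_hi = wlc_free_energy(R + step, spec, thermal)
    g_lo = wlc_free_energy(R - step, spec, thermal)
    return -(g_hi - g_lo) / (2.0 * step)
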