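"""Euler elastica treatment of the axially compressed dsDNA sample.

A strongly bent, inextensible rod of bending rigidity EI = lp*kBT and length
Lc under end loads follows the classical elastica. For pinned (freely
rotating) ends the post-buckling equilibrium relates the end-to-end distance
e to the elliptic modulus k through

    e / Lc = 2 E(k) / K(k) - 1,

with the compressive load F = 4 K(k)^2 EI / Lc^2 (K, E the complete
elliptic integrals of the first and second kind). As e -> Lc the modulus
k -> 0 and F approaches the Euler critical load pi^2 EI / Lc^2. Clamped
ends quadruple the critical load and follow the same shape relation with
F = 16 K(k)^2 EI / Lc^2.

This module treats the rod mechanically; thermal shape fluctuations are the
business of the worm-like-chain description in :mod:`ndfs.polymer`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ellipe, ellipk

from .exceptions import DomainError, ParameterError
from .polymer import ThermalScale, WLCSpec

_BOUNDARY_FACTORS = {"pinned-pinned": 4.0, "clamped-clamped": 16.0}


@dataclass(frozen=True)
class ElasticaSpec:
    """Elastic rod: bending rigidity EI (pN nm^2), length Lc (nm), end condition."""

    EI: float
    Lc: float
    boundary: str = "pinned-pinned"

    def __post_init__(self) -> None:
        if not (self.EI > 0 and self.Lc > 0):
            raise ParameterError(f"EI and Lc must be positive, got EI={self.EI}, Lc={self.Lc}")
        if self.boundary not in _BOUNDARY_FACTORS:
            raise ParameterError(
                f"boundary must be one of {sorted(_BOUNDARY_FACTORS)}, got {self.boundary!r}"
            )

    @classmethod
    def from_wlc(
        cls, wlc: WLCSpec, thermal: ThermalScale = ThermalScale(), boundary: str = "pinned-pinned"
    ) -> "ElasticaSpec":
        """Identify EI = lp * kBT from a worm-like-chain parameter set."""
        return cls(EI=wlc.lp * thermal.kBT, Lc=wlc.Lc, boundary=boundary)


def euler_critical_force(spec: ElasticaSpec) -> float:
    """Critical buckling load (pN): pi^2 EI/Lc^2 pinned, 4 pi^2 EI/Lc^2 clamped."""
    factor = _BOUNDARY_FACTORS[spec.boundary] / 4.0
    return factor * np.pi ** 2 * spec.EI / spec.Lc ** 2


def _ee_ratio(m: float) -> float:
    # end-to-end over length as a function of the elliptic parameter m = k^2
    return 2.0 * ellipe(m) / ellipk(m) - 1.0


def postbuckling_force(
    end_to_end: float, spec: ElasticaSpec, rtol: float = 1e-8
) -> float:
    """Compressive load (pN) holding the rod at the given end-to-end distance.

    Solves e/Lc = 2E(k)/K(k) - 1 for the modulus and returns
    (4 or 16) K(k)^2 EI / Lc^2. Valid for 0 < e < Lc; an unbent rod
    (e >= Lc) is below the buckling threshold and has no post-buckled
    solution.
    """
    if not (0 < end_to_end < spec.Lc):
        raise DomainError(
            f"post-buckling requires 0 < end_to_end < Lc, got {end_to_end} with Lc={spec.Lc}"
        )
    target = end_to_end / spec.Lc
    # _ee_ratio decreases monotonically from 1 (m->0) through -1 and below
    m = optimize.brentq(
        lambda m: _ee_ratio(m) - target, 1e-15, 1.0 - 1e-14, rtol=rtol, maxiter=200
    )
    factor = _BOUNDARY_FACTORS[spec.boundary]
    return factor * ellipk(m) ** 2 * spec.EI / spec.Lc ** 2
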