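"""Nucleosome unwrapping under angular bias: geometry, energetics, Eq-style
partition sums, and force estimates."""

import numpy as np
import pytest
from scipy.interpolate import make_interp_spline

from ndfs import (
    AngularDistribution,
    DomainError,
    FreeEnergyLandscape,
    HingeGeometry,
    NucleosomeSpec,
    ParameterError,
    PiecewiseAdhesionModel,
    mean_total_unwrapped,
    predict_constrained_angle_distribution,
    predict_unwrap_distribution,
    tensile_force_estimate,
    unwrap_energy,
    unwrap_geometry_angle,
    unwrap_span,
)


@pytest.fixture(scope="module")
def nuc():
    return NucleosomeSpec()


@pytest.fixture(scope="module")
def geom():
    return HingeGeometry(61.0)


def brute_force_planar_span(n1, n2, spec):
    """Coordinate-geometry oracle: lay the remaining wrap down base pair by
    base pair on the superhelix circle, take the exit tangent from the secant
    of the last two contact points, and extend the straight DNA from there."""
    abp = spec.wrap_angle_per_bp
    R = spec.superhelix_radius
    n_wrapped = spec.wrapped_bp - n1 - n2
    # bp boundaries of the remaining wrapped arc, laid down point by point
    phis = np.linspace(-n_wrapped * abp / 2.0, n_wrapped * abp / 2.0, n_wrapped + 1)
    points = np.stack([R * np.cos(phis), R * np.sin(phis)], axis=1)
    # secant approximation to the exit tangents (sub-bp refinement)
    d = abp * 1e-4
    t_in = points[0] - np.array([R * np.cos(phis[0] + d), R * np.sin(phis[0] + d)])
    t_out = points[-1] - np.array([R * np.cos(phis[-1] - d), R * np.sin(phis[-1] - d)])
    t_in /= np.linalg.norm(t_in)
    t_out /= np.linalg.norm(t_out)
    l1 = (n1 + spec.linker_bp) * spec.rise_per_bp
    l2 = (n2 + spec.linker_bp) * spec.rise_per_bp
    end1 = points[0] + l1 * t_in
    end2 = points[-1] + l2 * t_out
    return float(np.linalg.norm(end1 - end2))


class TestUnwrapGeometry:
    def test_closed_form_matches_coordinate_oracle(self, nuc, geom):
        for n1, n2 in [(0, 0), (10, 0), (20, 20), (35, 10), (5, 40)]:
            oracle_theta = 2 * np.degrees(
                np.arcsin(
                    min(brute_force_planar_span(n1, n2, nuc) / (2 * geom.attachment_radius), 1)
                )
            )
            assert unwrap_geometry_angle(n1, n2, nuc, geom) == pytest.approx(
                oracle_theta, abs=1.0
            )

    def test_mirror_symmetry_for_symmetric_construct(self, nuc, geom):
        n1 = np.arange(0, 74)
        n2 = 73 - n1
        assert np.allclose(
            unwrap_geometry_angle(n1, n2, nuc, geom),
            unwrap_geometry_angle(n2, n1, nuc, geom),
        )

    def test_monotone_in_n1_over_accessible_range(self, nuc, geom):
        # strictly more unwrapped DNA gives a larger span once past the
        # initial exit-tangent rotation (8 <= n1+n2 <= ~59); near full wrap
        # and deep into the inner turn the tangent geometry oscillates
        for n2 in (0, 10, 20):
            n1 = np.arange(max(0, 8 - n2), 59 - n2)
            theta = unwrap_geometry_angle(n1, n2, nuc, geom)
            assert np.all(np.diff(theta) >= -1e-9)

    def test_span_exceeding_open_chord_clamps_to_180(self, geom):
        spec = NucleosomeSpec(total_bp=600, wrapped_bp=147, linker_bp=220)
        with pytest.warns(UserWarning, match="clamping"):
            theta = unwrap_geometry_angle(70, 70, spec, geom)
        assert theta == pytest.approx(180.0)

    def test_planar_and_helix3d_backends_agree_roughly(self, geom):
        planar = NucleosomeSpec(geometry_backend="planar")
        helix = NucleosomeSpec(geometry_backend="helix3d")
        for n1, n2 in [(10, 10), (25, 5), (30, 30)]:
            assert unwrap_span(n1, n2, helix) == pytest.approx(
                unwrap_span(n1, n2, planar), abs=3.0
            )

    def test_invalid_states_rejected(self, nuc, geom):
        with pytest.raises(DomainError):
            unwrap_geometry_angle(-1, 0, nuc, geom)
        with pytest.raises(DomainError):
            unwrap_geometry_angle(100, 100, nuc, geom)

    def test_inconsistent_construct_rejected(self):
        with pytest.raises(ParameterError):
            NucleosomeSpec(total_bp=200, wrapped_bp=147, linker_bp=51)


class TestUnwrapEnergy:
    def test_reference_state_is_zero(self, nuc):
        assert unwrap_energy(0, 0, nuc) == 0.0

    def test_additive_across_ends(self, nuc):
        for n1, n2 in [(5, 7), (30, 40), (50, 2)]:
            assert unwrap_energy(n1, n2, nuc) == pytest.approx(
                unwrap_energy(n1, 0, nuc) + unwrap_energy(0, n2, nuc)
            )

    def test_outer_turn_thermally_accessible(self, nuc, geom):
        # with ~0.15 kBT/bp outer-turn adhesion, a free nucleosome breathes:
        # nonzero mean unwrapping with no applied load
        mean = mean_total_unwrapped(None, nuc, geom, flat_prior=True)
        assert 2.0 < mean < 30.0

    def test_inner_turn_stiffer_than_outer(self, nuc):
        m = nuc.energy_model
        outer_per_bp = unwrap_energy(m.outer_bp, 0, nuc) / m.outer_bp
        total = unwrap_energy(m.outer_bp + 10, 0, nuc)
        inner_per_bp = (total - unwrap_energy(m.outer_bp, 0, nuc)) / 10
        assert inner_per_bp > outer_per_bp


class TestUnwrapDistribution:
    def test_normalization(self, ndfs_b_density, nuc, geom):
        dist = predict_unwrap_distribution(ndfs_b_density, nuc, geom)
        assert dist.integral == pytest.approx(1.0, abs=1e-9)

    def test_flat_prior_reduces_to_boltzmann_of_energy(self, nuc, geom):
        """With a constant angular prior the device drops out of the partition
        sum, leaving the pure Boltzmann distribution of the unwrapping energy
        (naive double-loop oracle)."""
        toy = NucleosomeSpec(
            total_bp=40,
            wrapped_bp=20,
            linker_bp=10,
            energy_model=PiecewiseAdhesionModel(outer_bp=8, gamma_outer=0.3, gamma_inner=1.2),
        )
        dist = predict_unwrap_distribution(None, toy, geom, flat_prior=True)
        w = toy.unwrap_bin
        nbins = toy.wrapped_bp // w + 1
        mass = np.zeros(nbins)
        for n1 in range(toy.wrapped_bp + 1):
            for n2 in range(toy.wrapped_bp + 1 - n1):
                mass[(n1 + n2) // w] += np.exp(-unwrap_energy(n1, n2, toy))
        expected = mass / (w * mass.sum())
        assert np.allclose(dist.density, expected, rtol=1e-12)

    def test_exhaustive_enumeration_oracle_with_device_prior(self, geom):
        toy = NucleosomeSpec(total_bp=60, wrapped_bp=30, linker_bp=15)
        edges = np.arange(0.0, 185.0, 5.0)
        rng = np.random.default_rng(8)
        density = rng.uniform(0.2, 1.0, size=edges.size - 1)
        prior = AngularDistribution(edges, density / np.sum(density * 5.0))
        dist = predict_unwrap_distribution(prior, toy, geom)
        w = toy.unwrap_bin
        mass = np.zeros(toy.wrapped_bp // w + 1)
        for n1 in range(toy.wrapped_bp + 1):
            for n2 in range(toy.wrapped_bp + 1 - n1):
                theta = unwrap_geometry_angle(n1, n2, toy, geom)
                p = float(prior.density_at(theta))
                mass[(n1 + n2) // w] += p * np.exp(-unwrap_energy(n1, n2, toy))
        expected = mass / (w * mass.sum())
        assert np.allclose(dist.density, expected, rtol=1e-12)

    def test_gauge_invariance_under_constant_energy_shift(self, ndfs_b_density, geom):
        class Shifted:
            def __init__(self, base, shift):
                self.base, self.shift = base, shift

            def energy(self, n1, n2):
                return self.base.energy(n1, n2) + self.shift

        base = PiecewiseAdhesionModel()
        a = predict_unwrap_distribution(
            ndfs_b_density, NucleosomeSpec(energy_model=base), geom
        )
        b = predict_unwrap_distribution(
            ndfs_b_density, NucleosomeSpec(energy_model=Shifted(base, 3.7)), geom
        )
        assert np.allclose(a.density, b.density, rtol=1e-9)

    def test_open_prior_unwraps_more_than_closed_prior(
        self, ndfs_b_density, ndfs_c35_density, nuc, geom
    ):
        mean_open = mean_total_unwrapped(ndfs_b_density, nuc, geom)
        mean_closed = mean_total_unwrapped(ndfs_c35_density, nuc, geom)
        assert mean_open > mean_closed
        # the two device extremes separate by roughly a factor of two
        assert mean_open > 1.5 * mean_closed
        assert 10.0 < mean_closed < 45.0


class TestConstrainedAngles:
    def test_total_mass_one(self, ndfs_b_density, nuc, geom):
        con = predict_constrained_angle_distribution(ndfs_b_density, nuc, geom)
        assert con.integral == pytest.approx(1.0, abs=1e-9)

    def test_flat_energy_weights_are_prior_times_multiplicity(self, geom):
        """With eps == 0 each state contributes its device-bin probability, so
        an angle bin's mass is the prior density times the number of states
        mapping into it (3-state toy, enumerated by hand)."""
        toy = NucleosomeSpec(
            total_bp=3,
            wrapped_bp=1,
            linker_bp=1,
            energy_model=PiecewiseAdhesionModel(gamma_outer=0.0, gamma_inner=0.0),
            rise_per_bp=0.34,
        )
        edges = np.arange(0.0, 185.0, 5.0)
        density = np.full(edges.size - 1, 1.0 / 180.0)
        prior = AngularDistribution(edges, density)
        con = predict_constrained_angle_distribution(prior, toy, geom)
        # states: (0,0), (1,0), (0,1); the mirror pair shares one angle bin
        thetas = [unwrap_geometry_angle(a, b, toy, geom) for a, b in [(0, 0), (1, 0), (0, 1)]]
        expected = np.zeros(edges.size - 1)
        for theta in thetas:
            expected[int(theta // 5)] += 1.0
        expected /= expected.sum() * 5.0
        assert np.allclose(con.density, expected, rtol=1e-12)

    def test_nucleosome_pulls_device_to_smaller_angles(self, ndfs_b_density, nuc, geom):
        from ndfs import peak_angle

        con = predict_constrained_angle_distribution(ndfs_b_density, nuc, geom)
        assert peak_angle(con) <= peak_angle(ndfs_b_density)


class TestTensileForce:
    def _quadratic(self, k, theta0, lo, hi):
        theta = np.arange(lo, hi + 0.1, 2.0)
        G = 0.5 * k * np.radians(theta - theta0) ** 2
        return FreeEnergyLandscape(
            theta, G, (theta[0], theta[-1]), make_interp_spline(theta, G, k=3)
        )

    def test_flat_landscape_gives_zero_force(self, geom, thermal):
        theta = np.arange(40.0, 121.0, 2.0)
        scape = FreeEnergyLandscape(
            theta,
            np.zeros_like(theta),
            (40.0, 120.0),
            make_interp_spline(theta, np.zeros_like(theta), k=3),
        )
        assert tensile_force_estimate(scape, 80.0, geom, thermal) == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_landscape_matches_closed_form(self, geom, thermal):
        k, theta0, theta_star = 10.0, 85.0, 53.0
        scape = self._quadratic(k, theta0, 40.0, 120.0)
        force = tensile_force_estimate(scape, theta_star, geom, thermal)
        expected = (
            thermal.kBT
            * k
            * np.radians(theta0 - theta_star)
            / (geom.attachment_radius * np.cos(np.radians(theta_star) / 2.0))
        )
        assert force == pytest.approx(expected, rel=0.01)
        assert force > 0  # below the minimum the device pulls open: tension

    def test_device_surrogate_force_order_of_magnitude(self, ndfs_b_density, geom, thermal):
        # measured-device estimates were 0.37 and 0.16 pN; a synthetic
        # open-biased surrogate landscape must land within the same decade
        from ndfs import boltzmann_free_energy

        scape = boltzmann_free_energy(ndfs_b_density)
        force = tensile_force_estimate(scape, 65.0, geom, thermal)
        assert 0.03 < force < 3.7

    def test_edge_evaluation_rejected(self, geom, thermal):
        scape = self._quadratic(10.0, 85.0, 40.0, 120.0)
        with pytest.raises(DomainError):
            tensile_force_estimate(scape, 40.0, geom, thermal)
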