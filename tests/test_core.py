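"""Unit and property tests for the QDO parameterization chain."""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad

import vdwqdo
from vdwqdo import core
from vdwqdo.constants import HARTREE_TO_MEV


class TestDrudeFrequency:
    @pytest.mark.parametrize(
        "alpha1, c6, expected, tol",
        [
            (2.67, 6.38, 1.19326, 1e-5),      # neon
            (197.2, 3103.0, 0.1064, 5e-5),    # strontium
            (1.0, 0.75, 1.0, 1e-15),          # identity case of 4 C6/(3 alpha^2)
        ],
    )
    def test_values(self, alpha1, c6, expected, tol):
        assert core.drude_frequency(alpha1, c6) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("alpha1, c6, name", [(0.0, 1.0, "alpha1"), (1.0, -2.0, "c6")])
    def test_domain_errors_name_the_quantity(self, alpha1, c6, name):
        with pytest.raises(ValueError, match=name):
            core.drude_frequency(alpha1, c6)


class TestEquilibriumDistance:
    @pytest.mark.parametrize("alpha1, expected", [(2.67, 5.87), (27.3, 8.19)])
    def test_noble_gas_values(self, alpha1, expected):
        assert core.equilibrium_distance(alpha1) == pytest.approx(expected, abs=0.005)

    def test_seventh_power_homogeneity(self):
        assert core.equilibrium_distance(2.67 * 2**7) == pytest.approx(
            2 * core.equilibrium_distance(2.67), rel=1e-12
        )

    def test_phi_follows_from_fine_structure_constant(self):
        # Phi = alpha_fsc^(-4/21), numerically ~2.5528 bohr
        assert vdwqdo.VDW_RADIUS_PHI == pytest.approx(2.5528, abs=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            core.equilibrium_distance(-1.0)


class TestHigherDispersionCoefficients:
    def test_direct_ratio(self):
        c8, _ = core.higher_dispersion_coefficients(1.0, 5.0)
        assert c8 == pytest.approx(1.0, rel=1e-15)

    def test_neon_values_from_printed_oscillator(self):
        # mu*omega from the printed mu = 0.37164 and omega = 1.19326
        c8, c10 = core.higher_dispersion_coefficients(6.38, 0.37164 * 1.19326)
        assert c8 == pytest.approx(71.93, rel=1e-3)
        assert c10 == pytest.approx(993.5, rel=1e-3)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            core.higher_dispersion_coefficients(1.0, 0.0)


class TestGaussianOverlap:
    def test_normalized_at_contact(self):
        assert core.gaussian_overlap(0.7, 0.0) == 1.0

    @pytest.mark.parametrize("mu_omega, r", [(0.44346, 5.875), (0.1, 3.0), (2.0, 1.5)])
    def test_against_numerical_quadrature(self, mu_omega, r):
        """Contact-normalized 3-D overlap of the two drudon ground-state
        densities, via direct numerical integration in cylindrical
        coordinates."""
        t = mu_omega

        def density_product(rho, z, sep):
            # product of two normalized Gaussians centered at 0 and sep*e_z
            na = (t / math.pi) ** 1.5
            return (
                rho
                * na * math.exp(-t * (rho**2 + z**2))
                * na * math.exp(-t * (rho**2 + (z - sep) ** 2))
            )

        span = 12.0 / math.sqrt(t)

        def integral(sep):
            val, _ = dblquad(
                density_product, -span, span + sep, 0.0, span,
                args=(sep,), epsabs=1e-14, epsrel=1e-12,
            )
            return 2 * math.pi * val

        s_numeric = integral(r) / integral(0.0)
        assert core.gaussian_overlap(mu_omega, r) == pytest.approx(s_numeric, abs=1e-8)

    def test_strictly_decreasing(self):
        r = np.linspace(0, 10, 200)
        s = core.gaussian_overlap(0.44346, r)
        assert np.all(np.diff(s) < 0)

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            core.gaussian_overlap(1.0, -0.1)


class TestSolveMuOmega:
    def test_neon(self):
        t = core.solve_mu_omega(2.67, 6.38, core.equilibrium_distance(2.67))
        assert t == pytest.approx(0.44346, rel=1e-4)

    def test_strontium_damped(self):
        t = core.solve_mu_omega(197.2, 3103.0, 8.88, damped=True)
        assert t == pytest.approx(0.11354, rel=2e-4)

    def test_residual_vanishes_at_root(self):
        alpha1, c6 = 11.1, 64.3
        r_e = core.equilibrium_distance(alpha1)
        t = core.solve_mu_omega(alpha1, c6, r_e)
        omega = core.drude_frequency(alpha1, c6)
        residual = core._dipole_force_balance(t, alpha1, c6, r_e, omega, False)
        assert abs(residual) < 1e-12 * (6 * c6 / r_e**7)

    def test_no_solution_reports_interval(self):
        # At a tiny forced equilibrium distance the dispersion force
        # overwhelms any exchange wall: no balance exists.
        with pytest.raises(core.NoPhysicalSolutionError, match="scanned interval"):
            core.solve_mu_omega(2.67, 6.38, 0.5)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            core.solve_mu_omega(2.67, 6.38, -1.0)


class TestParameterizationChain:
    def test_neon_oscillator_triple(self, ne_params):
        assert ne_params.q == pytest.approx(1.18865, rel=1e-4)
        assert ne_params.mu == pytest.approx(0.37164, rel=1e-4)
        assert ne_params.omega == pytest.approx(1.19326, rel=1e-4)

    def test_strontium_damped_triple(self, sr_params):
        assert sr_params.q == pytest.approx(1.5433, rel=2e-4)
        assert sr_params.mu == pytest.approx(1.0671, rel=2e-4)
        assert sr_params.omega == pytest.approx(0.1064, rel=5e-4)

    def test_alpha1_round_trip_all_elements(self, table):
        for element in table:
            atom = table[element]
            damped = table.families.get(element) == "group_II"
            params = vdwqdo.qdo_parameters(
                atom, damped=damped,
                r_e_override=atom.re_ref if damped else None,
            )
            assert params.q**2 / (params.mu * params.omega**2) == pytest.approx(
                atom.alpha1, rel=1e-10
            )
            assert params.mu * params.omega == pytest.approx(params.mu_omega, rel=1e-12)

    def test_exchange_prefactor_invariant_under_q_split(self, ne_params):
        """A k_e q^2 must not depend on how {q, mu, omega} split at fixed
        alpha1 and mu*omega."""
        p = ne_params
        a1 = core.exchange_amplitude(p.mu_omega, p.q, p.c6, p.c8, p.c10, p.r_e)
        a2 = core.exchange_amplitude(p.mu_omega, 2 * p.q, p.c6, p.c8, p.c10, p.r_e)
        assert a2 * (2 * p.q) ** 2 == pytest.approx(a1 * p.q**2, rel=1e-12)


class TestPotential:
    def test_neon_well_depth_at_equilibrium(self, ne_params):
        v = core.potential(ne_params, ne_params.r_e) * HARTREE_TO_MEV
        assert v == pytest.approx(-3.586, abs=0.002)

    def test_force_balance_by_finite_difference(self, table, noble_atoms):
        for atom in noble_atoms:
            params = vdwqdo.qdo_parameters(atom)
            r_e, d_e = params.r_e, core.well_depth_closed_form(params)
            h = 1e-6 * r_e
            deriv = (core.potential(params, r_e + h) - core.potential(params, r_e - h)) / (2 * h)
            assert abs(deriv) < 1e-8 * d_e / r_e

    def test_analytic_derivative_matches_finite_difference(self, ne_params):
        for r in (4.5, 5.875, 8.0, 12.0):
            h = 1e-6
            fd = (core.potential(ne_params, r + h) - core.potential(ne_params, r - h)) / (2 * h)
            assert core.potential_derivative(ne_params, r) == pytest.approx(fd, rel=1e-6)

    def test_asymptotics_reach_c6_over_r6(self, noble_atoms):
        for atom in noble_atoms:
            params = vdwqdo.qdo_parameters(atom)
            r = 50 * params.r_e
            assert abs(core.potential(params, r) * r**6 / params.c6 + 1) < 1e-3
        params = vdwqdo.qdo_parameters(noble_atoms[1])  # Ne
        r = 100 * params.r_e
        assert core.potential(params, r) / (-params.c6 / r**6) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("damped", [False, True])
    def test_single_minimum_and_single_zero_crossing(self, noble_atoms, damped):
        """One repulsive-to-attractive crossing and one interior minimum on
        [0.7 R_e, 10 R_e].

        The undamped dispersion series diverges at short range and for the
        heaviest atom (Rn, the softest oscillator) that divergence reaches
        ~0.705 R_e, so the undamped topology claim is checked over its
        validated range He-Xe; the damped potential, whose short-range limit
        is well-defined, is checked for all six atoms.
        """
        atoms = noble_atoms if damped else noble_atoms[:-1]
        for atom in atoms:
            params = vdwqdo.qdo_parameters(atom, damped=damped)
            r = np.linspace(0.7 * params.r_e, 10 * params.r_e, 4000)
            v = core.potential(params, r)
            sign_changes = np.count_nonzero(np.diff(np.sign(v)))
            assert sign_changes == 1
            dv = np.diff(v)
            minima = np.count_nonzero((dv[:-1] < 0) & (dv[1:] > 0))
            assert minima == 1

    def test_warns_below_half_equilibrium(self, ne_params, caplog):
        with caplog.at_level("WARNING", logger="vdwqdo.core"):
            core.potential(ne_params, 0.4 * ne_params.r_e)
        assert any("dispersion series" in rec.message for rec in caplog.records)

    def test_rejects_nonpositive_separation(self, ne_params):
        with pytest.raises(ValueError):
            core.potential(ne_params, 0.0)


class TestWellDepth:
    def test_closed_form_equals_direct_evaluation(self, ne_params, sr_params):
        for params in (ne_params, sr_params):
            direct = -core.potential(params, params.r_e)
            assert core.well_depth_closed_form(params) == pytest.approx(direct, rel=1e-12)

    def test_positive_for_all_noble_gases(self, noble_atoms):
        for atom in noble_atoms:
            assert core.well_depth_closed_form(vdwqdo.qdo_parameters(atom)) > 0

    @pytest.mark.parametrize(
        "element, expected_mev",
        [("Ne", 4.049), ("Ar", 12.00), ("Rn", 30.38)],
    )
    def test_scaling_law_values(self, table, element, expected_mev):
        d_e = core.well_depth_scaling_law(table[element]) * HARTREE_TO_MEV
        assert d_e == pytest.approx(expected_mev, abs=0.005)
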