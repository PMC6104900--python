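"""Linear stability machinery: dispersion, matrix, polynomial, roots, scans."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixmi import (
    ModelParameters,
    PlaneWaveAnsatz,
    build_perturbation_matrix,
    carrier_wavenumbers,
    derive_coefficients,
    det_M,
    growth_rate,
    polynomial_coefficients,
    scan_instability,
    self_consistent_lam0,
    solve_omega,
    unperturbed_frequency,
)
from helixmi.mi_analysis import (
    PerturbationMatrix,
    SingularDispersionError,
    block_spectrum,
    dispersion_aux,
    printed_q_simplified,
)


def matched_distance(r1, r2):
    """Greedy nearest-neighbour pairing distance between two root multisets."""
    pool = list(r2)
    worst = 0.0
    for z in r1:
        i = int(np.argmin(np.abs(np.asarray(pool) - z)))
        worst = max(worst, abs(pool[i] - z))
        pool.pop(i)
    return worst


def random_matrix(rng, mode="rederived"):
    """Stability operator for a random physical parameter/wavenumber draw."""
    params = ModelParameters(
        chi=rng.uniform(-2.0, 2.0), D=rng.uniform(0.01, 0.1),
        V=rng.uniform(1e-4, 0.1), r=rng.uniform(0.05, 3.0),
        k=rng.uniform(0.01, 0.1))
    coeffs = derive_coefficients(params)
    lam0 = rng.uniform(-0.01, 0.01)
    ansatz = PlaneWaveAnsatz.from_amplitudes(
        k=rng.uniform(0.0, 0.5), lam0=lam0, phi0=rng.uniform(0.0, 0.1),
        psi0=complex(rng.uniform(-0.01, 0.01), rng.uniform(-0.01, 0.01)))
    w0 = unperturbed_frequency(ansatz.k, coeffs, lam0)
    return build_perturbation_matrix(ansatz.k, rng.uniform(0.01, 2.0), w0,
                                     ansatz, coeffs, mode=mode)


class TestCarrierDispersion:
    def test_frequency_vanishes_when_k_squared_equals_A(self):
        # chi < 0 makes A positive so k = sqrt(A) is real
        c = derive_coefficients(ModelParameters(chi=-0.3))
        aux = dispersion_aux(c)
        assert aux.A > 0.0
        assert unperturbed_frequency(math.sqrt(aux.A), c) == pytest.approx(0.0, abs=1e-18)

    def test_zero_wavenumber_limit(self, fig2_coeffs):
        aux = dispersion_aux(fig2_coeffs, lam0=0.002)
        w0 = unperturbed_frequency(0.0, fig2_coeffs, 0.002)
        assert w0 == pytest.approx(aux.eta * aux.A / aux.B, rel=1e-14)

    def test_reference_set_value_is_frozen(self, fig2_coeffs):
        # regression pin: direct evaluation of the carrier dispersion
        assert unperturbed_frequency(0.0, fig2_coeffs, 0.002) == pytest.approx(
            -0.0152391296, rel=1e-8)

    def test_pole_raises(self, fig2_coeffs):
        aux = dispersion_aux(fig2_coeffs, lam0=0.01)
        assert aux.B < 0.0
        with pytest.raises(SingularDispersionError):
            unperturbed_frequency(math.sqrt(-aux.B), fig2_coeffs, 0.01)

    def test_carrier_wavenumbers_solve_quartic(self, fig2_coeffs):
        aux = dispersion_aux(fig2_coeffs, lam0=0.002, phi0_sq=1e-6)
        res = carrier_wavenumbers(fig2_coeffs, lam0=0.002, phi0_sq=1e-6)
        for k_sq in (res.k_plus_sq, res.k_minus_sq):
            assert abs(k_sq**2 - aux.mu * k_sq + aux.mu1) < 1e-12 * max(1.0, abs(aux.mu1))

    def test_vanishing_mu1_factorizes(self, fig2_coeffs):
        # phi0 chosen so mu1 = 0: the quartic factors as k^2 (k^2 - mu)
        c = fig2_coeffs
        q = c.Q1 + c.Q2 * 0.002
        phi0_sq = q**2 / (c.beta_over_wg * c.c2)
        res = carrier_wavenumbers(c, lam0=0.002, phi0_sq=phi0_sq)
        aux = dispersion_aux(c, 0.002, phi0_sq)
        assert abs(aux.mu1) < 1e-14 * q**2
        roots = sorted([res.k_plus_sq, res.k_minus_sq], key=abs)
        assert roots[0] == pytest.approx(0.0, abs=1e-12)
        assert roots[1] == pytest.approx(aux.mu, rel=1e-10)

    def test_complex_branch_flagged_not_rejected(self):
        # hole-type coupling with a large amplitude drives mu^2 < 4 mu1
        c = derive_coefficients(ModelParameters(chi=-1.5))
        res = carrier_wavenumbers(c, lam0=0.0, phi0_sq=1000.0)
        assert res.complex_branch
        assert res.k_plus_sq == res.k_minus_sq.conjugate()

    def test_self_consistent_stretch_balances_charge_pressure(self, fig2_coeffs):
        c = fig2_coeffs
        lam0 = self_consistent_lam0(c, 0.01)
        residual = c.W_g * (lam0 - c.alpha0 * lam0**2 + c.gamma2 * lam0**3) + c.c2 * 0.01
        assert abs(residual) < 1e-15
        assert lam0 < 0.0  # compressive for electron-type coupling


class TestPerturbationMatrix:
    def test_vanishing_charge_amplitude_clears_coupling_entries(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.1, lam0=0.002, phi0=0.0, psi0=0.001)
        m = build_perturbation_matrix(0.1, 0.2, -0.01, a, fig2_coeffs, "as_printed")
        for name in ("m13", "m23", "m31", "m32"):
            assert m.entries[name] == 0.0

    def test_zero_perturbation_wavenumber(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.1, lam0=0.0, phi0=1e-3)
        m = build_perturbation_matrix(0.1, 0.0, -0.01, a, fig2_coeffs, "as_printed")
        assert m.entries["m11"] == pytest.approx(fig2_coeffs.Q1, rel=1e-14)
        assert m.entries["m45"] == 0.0

    def test_modes_agree_on_charge_entry(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.1, lam0=0.002, phi0=1e-3, psi0=0.001)
        mp = build_perturbation_matrix(0.1, 0.3, -0.01, a, fig2_coeffs, "as_printed")
        mr = build_perturbation_matrix(0.1, 0.3, -0.01, a, fig2_coeffs, "rederived")
        assert mp.entries["m11"] == mr.entries["m11"]
        assert mp.entries["m13"] == mr.entries["m13"]

    def test_discrepancy_report_lists_known_conflicts(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.1, lam0=0.002, phi0=1e-3, psi0=0.001 + 0.002j)
        mr = build_perturbation_matrix(0.1, 0.3, -0.01, a, fig2_coeffs, "rederived")
        # sign of 2 alpha0 lam0 in m33, lam0 power in m44, K*K1 factor in m45,
        # b1/b2 mixing in the lam->psi rows
        assert {"m33", "m44", "m45", "m43", "m43b"} <= set(mr.discrepancies)

    def test_unknown_mode_rejected(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes()
        with pytest.raises(ValueError, match="mode"):
            build_perturbation_matrix(0.0, 0.1, 0.0, a, fig2_coeffs, "reconciled")


class TestDeterminant:
    def test_block_factorization_when_charge_decouples(self, fig2_coeffs, rng):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.2, lam0=0.003, phi0=0.0, psi0=0.01)
        m = build_perturbation_matrix(0.2, 0.4, -0.02, a, fig2_coeffs, "rederived")
        e = m.entries
        for _ in range(5):
            om = complex(rng.normal(), rng.normal())
            expected = ((e["m11"] ** 2 - om**2) * (e["m33"] - om**2)
                        * ((e["m44"] - om**2) ** 2 - (2 * m.w0 * om + e["m45"]) ** 2))
            assert det_M(om, m) == pytest.approx(expected, rel=1e-10)

    def test_leading_behaviour_is_omega_eighth(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.1, lam0=0.002, phi0=1e-3)
        m = build_perturbation_matrix(0.1, 0.3, -0.01, a, fig2_coeffs, "rederived")
        for om in (1e3, 1e3j, 1e3 * cmath.exp(0.3j)):
            assert det_M(om, m) / om**8 == pytest.approx(1.0, rel=1e-4)

    def test_determinant_vanishes_at_solver_roots(self, rng):
        m = random_matrix(rng)
        res = solve_omega(m, "det_roots")
        assert np.all(res.residuals < 1e-8 * m.scale)


class TestPolynomialCoefficients:
    def test_printed_constant_term_cancellation(self, rng):
        # the +/- m11^2 m33 m45^2 terms of the printed constant cancel
        for _ in range(50):
            entries = {name: rng.normal() for name in
                       ("m11", "m13", "m23", "m31", "m32", "m33", "m43", "m43b",
                        "m44", "m45")}
            m = PerturbationMatrix(K=0.1, K1=0.2, w0=rng.normal(), mode="as_printed",
                                   entries=entries)
            q = polynomial_coefficients(m, "as_printed").Q
            q_simplified = printed_q_simplified(entries)
            assert q == pytest.approx(q_simplified, rel=1e-12, abs=1e-300)

    def test_odd_coefficients_vanish_without_cross_term(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.0, lam0=0.002, phi0=1e-3)
        m = build_perturbation_matrix(0.0, 0.3, -0.01, a, fig2_coeffs, "as_printed")
        assert m.entries["m45"] == 0.0
        for form in ("as_printed", "expanded"):
            pc = polynomial_coefficients(m, form)
            assert pc.T == 0.0 and pc.N == 0.0 and pc.Z == 0.0

    def test_even_polynomial_when_w0_and_cross_term_vanish(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.0, lam0=0.002, phi0=1e-3)
        m = build_perturbation_matrix(0.0, 0.3, 0.0, a, fig2_coeffs, "rederived")
        roots = solve_omega(m, "expanded_poly").roots
        # an even polynomial's roots come in +/- pairs
        assert matched_distance(roots, -roots) < 1e-10

    def test_expanded_form_reproduces_determinant_values(self, rng):
        m = random_matrix(rng)
        pc = polynomial_coefficients(m, "expanded").monic_coefficients()
        for _ in range(5):
            om = complex(rng.normal(), rng.normal())
            poly_val = np.polyval(pc, om)
            assert poly_val == pytest.approx(det_M(om, m), rel=1e-9, abs=1e-18)

    def test_expanded_form_valid_even_for_asymmetric_split(self, fig2_coeffs, rng):
        # m13 m32 = m23 m31 holds structurally (both are 2 Q2 c2 a1 a2),
        # so the expanded coefficients stay exact for a1 != a2
        a = PlaneWaveAnsatz(k=0.1, lam0=0.0, a1=1e-3, a2=2e-3)
        m = build_perturbation_matrix(0.1, 0.3, -0.01, a, fig2_coeffs, "rederived")
        pc = polynomial_coefficients(m, "expanded").monic_coefficients()
        for _ in range(3):
            om = complex(rng.normal(), rng.normal())
            assert np.polyval(pc, om) == pytest.approx(det_M(om, m), rel=1e-9, abs=1e-18)

    def test_expanded_form_rejects_unstructured_entries(self, rng):
        entries = {name: rng.normal() for name in
                   ("m11", "m13", "m23", "m31", "m32", "m33", "m43", "m43b",
                    "m44", "m45")}
        m = PerturbationMatrix(K=0.1, K1=0.2, w0=0.3, mode="as_printed", entries=entries)
        with pytest.raises(ValueError, match="m13"):
            polynomial_coefficients(m, "expanded")


class TestRoots:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_real_inputs_give_conjugate_closed_root_sets(self, seed):
        m = random_matrix(np.random.default_rng(seed))
        roots = solve_omega(m, "det_roots").roots
        assert matched_distance(roots, np.conj(roots)) < 1e-6 * (1 + np.max(np.abs(roots)))

    def test_charge_block_roots_are_plus_minus_m11(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.2, lam0=0.003, phi0=0.0, psi0=0.01)
        m = build_perturbation_matrix(0.2, 0.4, -0.02, a, fig2_coeffs, "rederived")
        roots = solve_omega(m, "det_roots").roots
        m11 = m.entries["m11"]
        for target in (m11, -m11):
            assert np.min(np.abs(roots - target)) < 1e-8 * max(1.0, abs(m11))

    def test_polynomial_and_determinant_routes_agree(self, rng):
        for _ in range(10):
            m = random_matrix(rng)
            r_det = solve_omega(m, "det_roots").roots
            r_poly = solve_omega(m, "expanded_poly").roots
            scale = max(1.0, np.max(np.abs(r_det)))
            assert matched_distance(r_det, r_poly) < 1e-6 * scale

    def test_roots_sorted_by_descending_imaginary_part(self, rng):
        m = random_matrix(rng)
        roots = solve_omega(m, "det_roots").roots
        assert np.all(np.diff(roots.imag) <= 1e-12)


class TestGrowthRate:
    def test_no_growth_without_nonlinearity_or_coupling(self):
        c = derive_coefficients(ModelParameters(D=0.0, chi=0.0))
        a = PlaneWaveAnsatz.from_amplitudes(k=0.1, lam0=0.002, phi0=1e-3)
        for k1 in (0.05, 0.2, 0.5, 1.0):
            assert growth_rate(0.1, k1, a, c) < 1e-10

    def test_growth_is_even_in_perturbation_wavenumber(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.2, lam0=0.002, phi0=1e-3, psi0=0.002)
        w0 = unperturbed_frequency(0.2, fig2_coeffs, 0.002)
        for k1 in (0.05, 0.3, 0.8):
            g_plus = growth_rate(0.2, k1, a, fig2_coeffs, w0=w0)
            g_minus = growth_rate(0.2, -k1, a, fig2_coeffs, w0=w0)
            assert g_plus == pytest.approx(g_minus, rel=1e-6, abs=1e-12)

    def test_growth_matches_blockwise_spectra_when_charge_dark(self, fig2_coeffs):
        a = PlaneWaveAnsatz.from_amplitudes(k=0.15, lam0=0.002, phi0=0.0)
        w0 = unperturbed_frequency(0.15, fig2_coeffs, 0.002)
        m = build_perturbation_matrix(0.15, 0.1, w0, a, fig2_coeffs, "rederived")
        full = solve_omega(m, "det_roots").growth
        blocks = block_spectrum(m)
        blockwise = max(0.0, max(np.max(b.imag) for b in blocks.values()))
        assert full == pytest.approx(blockwise, abs=1e-8)


class TestScan:
    def test_single_point_grid(self, fig2_params):
        scan = scan_instability([0.3], fig2_params, lam0="fixed", lam0_value=0.002,
                                phi0=1e-3)
        assert scan.growth.shape == (1, 1)
        assert len(scan.table()) == 1

    def test_empty_sweep_equals_mapped_growth_rate(self, fig2_params):
        c = derive_coefficients(fig2_params)
        grid = np.linspace(0.05, 0.6, 5)
        scan = scan_instability(grid, fig2_params, k=0.1, lam0="fixed",
                                lam0_value=0.002, phi0=1e-3)
        a = PlaneWaveAnsatz.from_amplitudes(k=0.1, lam0=0.002, phi0=1e-3)
        direct = [growth_rate(0.1, k1, a, c) for k1 in grid]
        np.testing.assert_allclose(scan.growth[0], direct, rtol=1e-9, atol=1e-12)

    def test_sweep_recomputes_coefficients(self, fig2_params):
        grid = np.linspace(0.05, 0.5, 4)
        scan = scan_instability(grid, fig2_params, lam0="fixed", lam0_value=0.002,
                                phi0=1e-3, sweep=("chi", [0.3, 0.6]))
        assert scan.growth.shape == (2, 4)
        assert scan.table().shape[0] == 8

    def test_radius_sweep_reties_rotational_stiffness(self, fig2_params):
        grid = np.array([0.1])
        scan = scan_instability(grid, fig2_params, lam0="fixed", lam0_value=0.002,
                                phi0=0.0, sweep=("r", [1.0, 2.0]), xi_policy="track")
        # growth in the rotation sector scales with sqrt(beta*lam0) ~ sqrt(r)
        assert scan.growth[1, 0] > scan.growth[0, 0] > 0.0

    def test_empty_grid_rejected(self, fig2_params):
        with pytest.raises(ValueError, match="nonempty"):
            scan_instability([], fig2_params)

    def test_unstable_measure_and_boundaries(self, fig2_params):
        grid = np.linspace(0.01, 1.2, 60)
        scan = scan_instability(grid, fig2_params, k=0.0, lam0="fixed",
                                lam0_value=0.002, phi0=0.0)
        measure = scan.unstable_measure()[0]
        bounds = scan.boundaries()[0]
        assert measure > 0.0
        assert len(bounds) >= 1  # the rotation lobe has an upper edge
        # edge location: (xi/I) K1^2 = beta lam0 (1 - gamma2 lam0^2)
        c = derive_coefficients(fig2_params)
        k1_edge = math.sqrt(c.beta * 0.002 * (1 - c.gamma2 * 0.002**2) / (-c.c1))
        assert bounds[-1] == pytest.approx(k1_edge, abs=0.05)
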