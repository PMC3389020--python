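"""Equilibrium-manifold construction: kernel bases, residuals, Jacobians."""

import dataclasses

import numpy as np
import pytest

from crnstab import (
    NetworkError,
    build_manifold,
    deficiency_basis,
    fixtures,
    kinetic_matrix,
    manifold_equations,
    manifold_jacobian,
    network_from_reactions,
    newton_refine,
    phi_inverse,
    phi_map,
    psi,
    rho_matrix_tree,
    select_reference_complexes,
    species_rhs,
    structural_report,
)
from conftest import edelstein_curve_point


def _cidx(net, name):
    return [net.complex_name(i) for i in range(net.n_complexes)].index(name)


# ---------------------------------------------------------------------------
# kinetic matrix and mass-action evaluation
# ---------------------------------------------------------------------------

class TestKinetics:
    def test_edelstein_autocatalytic_block(self, edelstein_net):
        net, K = edelstein_net
        A = kinetic_matrix(net, K)
        ia, i2a = _cidx(net, "A"), _cidx(net, "2A")
        block = A[np.ix_([ia, i2a], [ia, i2a])]
        np.testing.assert_allclose(block, [[-8.5, 1.0], [8.5, -1.0]])

    def test_single_reaction(self):
        net = network_from_reactions(["A", "B"], [({"A": 1}, {"B": 1}, 2.0)])
        A = kinetic_matrix(net, net.K)
        np.testing.assert_allclose(A, [[-2.0, 0.0], [2.0, 0.0]])

    def test_column_sums_zero_and_block_structure(self, edelstein_model):
        A = edelstein_model.A_k
        np.testing.assert_allclose(A.sum(axis=0), 0.0, atol=1e-12)
        # no coupling between the two linkage classes
        for ci, cls_i in enumerate(edelstein_model.report.linkage_classes):
            for cj, cls_j in enumerate(edelstein_model.report.linkage_classes):
                if ci != cj:
                    assert np.all(A[np.ix_(list(cls_i), list(cls_j))] == 0)

    def test_k_length_mismatch(self, edelstein_net):
        net, _ = edelstein_net
        with pytest.raises(NetworkError, match="rate constants"):
            kinetic_matrix(net, np.ones(5))

    def test_psi_monomials(self, edelstein_net):
        net, _ = edelstein_net
        # complex order (A, B, C, 2A, A+B)
        np.testing.assert_allclose(
            psi(net, np.array([2.0, 3.0, 5.0])), [2, 3, 5, 4, 6])
        np.testing.assert_allclose(psi(net, np.ones(3)), np.ones(5))
        with pytest.raises(ValueError):
            psi(net, np.array([-1.0, 1.0, 1.0]))

    def test_rhs_zero_at_closed_form_equilibrium(self, edelstein_net):
        net, K = edelstein_net
        c, _ = edelstein_curve_point(1.0)
        np.testing.assert_allclose(c, [1.0, 18.75, 11.25])
        np.testing.assert_allclose(species_rhs(net, K, c), 0.0, atol=1e-12)

    def test_rhs_in_stoichiometric_subspace(self, edelstein_model):
        net, K = edelstein_model.net, edelstein_model.K
        B = edelstein_model.report.B
        rng = np.random.default_rng(7)
        for _ in range(20):
            c = 10.0 ** rng.uniform(-2, 2, size=3)
            rhs = species_rhs(net, K, c)
            assert abs(B.T @ rhs).max() <= 1e-12 * max(np.abs(rhs).max(), 1.0)


# ---------------------------------------------------------------------------
# kernel basis rho
# ---------------------------------------------------------------------------

class TestRho:
    def test_edelstein_values(self, edelstein_model):
        m = edelstein_model
        net = m.net
        # class {A, 2A}: rho = (1, 8.5); class {B, C, A+B}: rho = (1, 0.2, 0.2)
        assert m.rho[_cidx(net, "A")] == pytest.approx(1.0)
        assert m.rho[_cidx(net, "2A")] == pytest.approx(8.5)
        assert m.rho[_cidx(net, "B")] == pytest.approx(1.0)
        assert m.rho[_cidx(net, "C")] == pytest.approx(0.2)
        assert m.rho[_cidx(net, "A + B")] == pytest.approx(0.2)

    def test_kernel_property(self, edelstein_model):
        m = edelstein_model
        for cls in m.report.linkage_classes:
            idx = list(cls)
            resid = m.A_k[np.ix_(idx, idx)] @ m.rho[idx]
            assert np.abs(resid).max() <= 1e-12 * np.abs(m.A_k).max()
            assert np.all(m.rho[idx] > 0)

    def test_symmetric_pair(self):
        net = network_from_reactions(
            ["A", "B"], [({"A": 1}, {"B": 1}, 1.0), ({"B": 1}, {"A": 1}, 1.0)])
        model = build_manifold(net, net.K)
        np.testing.assert_allclose(model.rho, [1.0, 1.0])

    @pytest.mark.parametrize("seed", range(30))
    def test_matrix_tree_matches_nullspace(self, seed):
        """Spanning-tree expansion equals the SVD kernel to 1e-10."""
        spec = fixtures.FixtureSpec(
            n_species=2 + seed % 3, n_complexes=4 + seed % 4,
            n_classes=1 + seed % 2, extra_edges=seed % 2, seed=1000 + seed)
        net, K = fixtures.random_weakly_reversible(spec)
        if net.n_complexes > 8:
            pytest.skip("matrix-tree oracle limited to n <= 8")
        rep = structural_report(net)
        try:
            model = build_manifold(net, K, rep)
        except NetworkError:
            pytest.skip("network outside the manifold-supported class")
        for ci, cls in enumerate(rep.linkage_classes):
            tree_rho = rho_matrix_tree(net, K, cls)
            ref = model.ref_complexes[ci]
            for p in cls:
                expected = tree_rho[p] / tree_rho[ref]
                assert model.rho[p] == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# deficiency basis, eta, reference complexes
# ---------------------------------------------------------------------------

class TestDeficiencySubspace:
    def test_edelstein_omega(self, edelstein_model):
        # complex order (A, B, C, 2A, A+B)
        np.testing.assert_allclose(
            edelstein_model.omega[:, 0], [1, -1, 0, -1, 1], atol=1e-10)

    def test_defining_properties(self, edelstein_model):
        m = edelstein_model
        omega = m.omega
        assert np.abs(m.report.Y @ omega).max() <= 1e-12
        for cls in m.report.linkage_classes:
            assert abs(omega[list(cls)].sum(axis=0)).max() <= 1e-12

    def test_chain_empty_basis(self, chain3_report):
        assert deficiency_basis(chain3_report).shape == (3, 0)

    def test_eta_solves_linear_system(self, edelstein_model):
        m = edelstein_model
        resid = np.linalg.norm(m.A_k @ m.eta - m.omega, axis=0)
        assert np.all(resid <= 1e-10 * np.linalg.norm(m.omega, axis=0))

    def test_eta_minimum_norm_gauge(self, edelstein_model):
        """lstsq eta is orthogonal to the kernel of A_k (span of rho blocks)."""
        m = edelstein_model
        for cls in m.report.linkage_classes:
            b = np.zeros(m.net.n_complexes)
            b[list(cls)] = m.rho[list(cls)]
            assert abs(b @ m.eta).max() <= 1e-10 * np.linalg.norm(b)

    def test_eta_gauge_invariance(self, edelstein_model):
        """Shifting eta by kernel vectors leaves H unchanged identically."""
        m = edelstein_model
        rng = np.random.default_rng(11)
        shift = np.zeros_like(m.eta)
        for cls in m.report.linkage_classes:
            idx = list(cls)
            shift[idx, :] += np.outer(m.rho[idx], rng.normal(size=m.alpha_dim))
        shifted = dataclasses.replace(m, eta=m.eta + shift)
        for _ in range(20):
            c = 10.0 ** rng.uniform(-1, 1, size=3)
            a = rng.normal(scale=5.0, size=1)
            np.testing.assert_allclose(
                manifold_equations(m, c, a),
                manifold_equations(shifted, c, a),
                rtol=0, atol=1e-8 * (1 + np.abs(a).max()))

    def test_edelstein_reference_selection(self, edelstein_model):
        m = edelstein_model
        net = m.net
        assert set(m.selected) == {_cidx(net, "A"), _cidx(net, "B"), _cidx(net, "C")}
        np.testing.assert_allclose(m.Y0, np.eye(3))
        assert m.ref_complexes == (_cidx(net, "A"), _cidx(net, "B"))
        np.testing.assert_allclose(m.Yhat[_cidx(net, "2A")], [2, 0, 0])
        np.testing.assert_allclose(m.Yhat[_cidx(net, "A + B")], [1, 1, 0])

    def test_yhat_identity(self, edelstein_model):
        m = edelstein_model
        np.testing.assert_allclose(m.Yhat @ m.Y0.T, m.net.Y.T, atol=1e-12)

    def test_rank_deficient_y_rejected(self):
        # complexes A+B and 2A+2B: Y = [[1,2],[1,2]] has rank 1 < m = 2
        net = network_from_reactions(
            ["A", "B"],
            [({"A": 1, "B": 1}, {"A": 2, "B": 2}, 1.0),
             ({"A": 2, "B": 2}, {"A": 1, "B": 1}, 1.0)])
        rep = structural_report(net)
        with pytest.raises(NetworkError, match="rank"):
            select_reference_complexes(rep)


# ---------------------------------------------------------------------------
# manifold residuals and Jacobians
# ---------------------------------------------------------------------------

class TestManifoldEquations:
    def test_closed_form_residuals(self, edelstein_model):
        """H equals (c_C - 0.2 c_B + a, c_A^2 - 8.5 c_A - a, c_A c_B - 0.2 c_B + 2a)."""
        m = edelstein_model
        rng = np.random.default_rng(3)
        for _ in range(25):
            c = 10.0 ** rng.uniform(-1, 1.2, size=3)
            a = rng.normal(scale=8.0)
            expected = np.array([
                c[2] - 0.2 * c[1] + a,
                c[0] ** 2 - 8.5 * c[0] - a,
                c[0] * c[1] - 0.2 * c[1] + 2 * a,
            ])
            np.testing.assert_allclose(
                manifold_equations(m, c, [a]), expected, rtol=1e-12, atol=1e-12)

    def test_zero_at_equilibrium(self, edelstein_model):
        c, a = edelstein_curve_point(1.0)
        H = manifold_equations(edelstein_model, c, a)
        np.testing.assert_allclose(H, 0.0, atol=1e-12)

    def test_alpha_zero_is_complex_balanced(self, chain3):
        """For delta = 0, H(c) = 0 implies A_k Psi(c) = 0 (complex balancing)."""
        net, K = chain3
        m = build_manifold(net, K)
        rng = np.random.default_rng(8)
        for _ in range(10):
            c0 = 10.0 ** rng.uniform(-1, 1, size=3)
            c, _, ok = newton_refine(m, c0, np.zeros(0))
            assert ok
            resid = m.A_k @ psi(m.net, c)
            assert np.abs(resid).max() <= 1e-10 * max(np.abs(K).max(), 1.0)

    def test_component_count(self, edelstein_model, chain3):
        m = edelstein_model
        assert len(m.nonref) == m.report.s + m.report.deficiency == 3
        net, K = chain3
        mc = build_manifold(net, K)
        assert len(mc.nonref) == 2  # s + delta = 2 + 0

    def test_jacobian_matches_finite_differences(self, edelstein_model):
        m = edelstein_model
        rng = np.random.default_rng(5)
        for _ in range(10):
            c = 10.0 ** rng.uniform(-0.5, 1.0, size=3)
            a = rng.normal(scale=5.0, size=1)
            Jc, Ja = manifold_jacobian(m, c, a)
            x = np.concatenate([c, a])
            J = np.hstack([Jc, Ja])
            for i in range(len(x)):
                h = 1e-6 * (1 + abs(x[i]))
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                fd = (manifold_equations(m, xp[:3], xp[3:])
                      - manifold_equations(m, xm[:3], xm[3:])) / (2 * h)
                np.testing.assert_allclose(
                    J[:, i], fd, rtol=1e-6, atol=1e-6 * max(1, np.abs(fd).max()))

    def test_nonpositive_c_rejected(self, edelstein_model):
        with pytest.raises(ValueError):
            manifold_equations(edelstein_model, [1.0, -1.0, 1.0], [0.0])

    def test_newton_points_are_equilibria(self, edelstein_model):
        """100 Newton-solved manifold points satisfy ||Y A_k Psi|| <= 1e-8 ||K||."""
        m = edelstein_model
        rng = np.random.default_rng(12)
        Y = m.net.Y
        solved = 0
        for _ in range(1200):
            if solved >= 100:
                break
            c0 = 10.0 ** rng.uniform(-1.5, 1.5, size=3)
            c, a, ok = newton_refine(m, c0)
            if not ok:
                continue
            solved += 1
            rhs = Y @ m.A_k @ psi(m.net, c)
            assert np.linalg.norm(rhs) <= 1e-8 * np.linalg.norm(m.K)
        assert solved >= 100

    def test_solution_set_is_one_dimensional(self, edelstein_model):
        """rank [J_c J_alpha] = s + delta = 3 at solutions: 1 free direction."""
        m = edelstein_model
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(200):
            c0 = 10.0 ** rng.uniform(-1, 1, size=3)
            c, a, ok = newton_refine(m, c0)
            if not ok:
                continue
            Jc, Ja = manifold_jacobian(m, c, a)
            assert np.linalg.matrix_rank(np.hstack([Jc, Ja])) == 3
            checked += 1
        assert checked >= 20


# ---------------------------------------------------------------------------
# species <-> complex space bijection
# ---------------------------------------------------------------------------

class TestPhi:
    def test_identity_for_edelstein(self, edelstein_model):
        rng = np.random.default_rng(9)
        for _ in range(5):
            v = 10.0 ** rng.uniform(-2, 2, size=3)
            np.testing.assert_allclose(phi_map(edelstein_model, v), v)

    def test_square_root_case(self):
        # single species, reference complex 2A: phi(psi0) = sqrt(psi0)
        net = network_from_reactions(
            ["A"], [({"A": 2}, {"A": 3}, 1.0), ({"A": 3}, {"A": 2}, 1.0)])
        model = build_manifold(net, net.K)
        np.testing.assert_allclose(model.Y0, [[2.0]])
        np.testing.assert_allclose(phi_map(model, np.array([4.0])), [2.0])

    def test_round_trip(self, edelstein_model):
        rng = np.random.default_rng(100)
        for _ in range(100):
            c = 10.0 ** rng.uniform(-3, 3, size=3)
            back = phi_map(edelstein_model, phi_inverse(edelstein_model, c))
            np.testing.assert_allclose(back, c, rtol=1e-12)

    def test_positivity_required(self, edelstein_model):
        with pytest.raises(ValueError):
            phi_map(edelstein_model, np.array([1.0, 0.0, 1.0]))
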