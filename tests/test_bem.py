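"""Charge-based boundary element solver against dense and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from recimeg.bem import (ChargeOperator, SolverConfig, SolverError, apply_operator,
                         assemble_rhs, E_total_at_points, normal_E_from_charge,
                         potential_from_charges, solve_charges)
from recimeg.geometry import ConductivityLayer, HeadModel, build_icosphere


def _uniform_incident(head, E0):
    return np.tile(E0, (head.total_faces, 1))


class TestAssembleRhs:
    def test_zero_contrast_and_tangential_field_give_zero(self, small_sphere_head):
        head = small_sphere_head
        # tangential field: project a constant onto the tangent plane per face
        E0 = np.array([1.0, 0.2, -0.5])
        n = head.face_normals
        Etan = E0 - np.einsum("ij,j->i", n, E0)[:, None] * n
        assert np.allclose(assemble_rhs(head, Etan), 0.0, atol=1e-12)
        uniform = HeadModel([ConductivityLayer(build_icosphere(0.08, 1), 0.3, 0.3, "u")])
        assert np.allclose(assemble_rhs(uniform, _uniform_incident(uniform, E0)), 0.0)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, a, b):
        head = HeadModel([ConductivityLayer(build_icosphere(0.08, 1), 0.3, 0.0, "s")])
        rng = np.random.default_rng(0)
        E1 = rng.standard_normal((head.total_faces, 3))
        E2 = rng.standard_normal((head.total_faces, 3))
        lhs = assemble_rhs(head, a * E1 + b * E2)
        rhs = a * assemble_rhs(head, E1) + b * assemble_rhs(head, E2)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_size_mismatch_rejected(self, small_sphere_head):
        with pytest.raises(ValueError):
            assemble_rhs(small_sphere_head, np.zeros((3, 3)))


class TestApplyOperator:
    def test_zero_input_and_matrix_consistency(self, two_sphere_head, two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        assert np.allclose(apply_operator(head, np.zeros(head.total_faces), operator=op), 0.0)
        # column-by-column application equals the dense assembly
        rng = np.random.default_rng(1)
        for j in rng.integers(0, head.total_faces, size=8):
            e = np.zeros(head.total_faces)
            e[j] = 1.0
            assert np.allclose(op.matvec(e), op.matrix[:, j], atol=1e-12)

    def test_single_face_mesh_is_identity(self):
        verts = np.array([[0, 0, 0], [0.01, 0, 0], [0, 0.01, 0]], dtype=float)
        from recimeg.geometry import TriangleMesh
        tri = TriangleMesh(verts, np.array([[0, 1, 2]]))
        head = HeadModel([ConductivityLayer(tri, 0.3, 0.0, "one")])
        rho = np.array([2.5])
        assert np.allclose(apply_operator(head, rho), rho)

    def test_blocked_backend_matches_direct(self, two_sphere_head):
        head = two_sphere_head
        cfg_b = SolverConfig(backend="blocked")
        op_d = ChargeOperator(head, SolverConfig())
        op_b = ChargeOperator(head, cfg_b)
        rho = np.random.default_rng(2).standard_normal(head.total_faces)
        a, b = op_d.matvec(rho), op_b.matvec(rho)
        assert np.linalg.norm(a - b) <= 1e-4 * np.linalg.norm(a)


class TestSolveCharges:
    def test_zero_field_and_zero_contrast_give_zero(self, two_sphere_head):
        head = two_sphere_head
        sol = solve_charges(head, np.zeros((head.total_faces, 3)))
        assert np.allclose(sol.rho, 0.0)
        assert sol.iterations == 0
        uniform = HeadModel([ConductivityLayer(build_icosphere(0.08, 1), 0.3, 0.3, "u")])
        sol2 = solve_charges(uniform, _uniform_incident(uniform, np.array([1.0, 0, 0])))
        assert np.allclose(sol2.rho, 0.0)

    def test_matches_dense_direct_solve(self, two_sphere_head, two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        E = _uniform_incident(head, np.array([0.7, -0.3, 1.1]))
        sol = solve_charges(head, E, operator=op)
        dense = np.linalg.solve(op.matrix, assemble_rhs(head, E))
        assert np.linalg.norm(sol.rho - dense) <= 1e-3 * np.linalg.norm(dense)
        # converged to the configured tolerance
        rhs = assemble_rhs(head, E)
        res = np.linalg.norm(op.matvec(sol.rho) - rhs) / np.linalg.norm(rhs)
        assert res <= op.config.gmres_rel_tol

    def test_charge_neutrality_per_surface(self, two_sphere_head, two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        E = _uniform_incident(head, np.array([1.0, 0.0, 0.0]))
        sol = solve_charges(head, E, operator=op)
        for name in ("skin", "skull"):
            sl = head.layer_slice(name)
            a, r = head.face_areas[sl], sol.rho[sl]
            assert abs(np.sum(a * r)) <= 1e-3 * np.sum(a * np.abs(r))

    def test_linearity_of_solutions(self, two_sphere_head, two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        rng = np.random.default_rng(3)
        E1 = rng.standard_normal((head.total_faces, 3))
        E2 = rng.standard_normal((head.total_faces, 3))
        s12 = solve_charges(head, 2.0 * E1 - 0.5 * E2, operator=op).rho
        s1 = solve_charges(head, E1, operator=op).rho
        s2 = solve_charges(head, E2, operator=op).rho
        assert np.linalg.norm(s12 - (2 * s1 - 0.5 * s2)) <= 5e-4 * np.linalg.norm(s12)

    def test_residual_history_non_increasing(self, two_sphere_head, two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        E = _uniform_incident(head, np.array([0.0, 1.0, 0.5]))
        sol = solve_charges(head, E, operator=op)
        h = sol.residual_history
        assert len(h) >= 1 and np.all(np.diff(h) <= 1e-12)

    def test_nonconvergence_signals_with_history(self, two_sphere_head):
        cfg = SolverConfig(gmres_rel_tol=1e-13, max_iterations=2)
        head = two_sphere_head
        E = _uniform_incident(head, np.array([1.0, 0, 0]))
        with pytest.raises(SolverError) as err:
            solve_charges(head, E, config=cfg)
        assert len(err.value.residual_history) >= 1


class TestPotentialAndField:
    def test_zero_charge_zero_potential(self, two_sphere_head, two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        pts = np.array([[0.2, 0, 0], [0, 0.3, 0.1]])
        assert np.allclose(potential_from_charges(head, np.zeros(head.total_faces), pts,
                                                  operator=op), 0.0)

    def test_uniformly_charged_sphere_gauss_law(self):
        mesh = build_icosphere(0.08, 3)
        head = HeadModel([ConductivityLayer(mesh, 0.3, 0.0, "s")])
        op = ChargeOperator(head)
        rho = np.ones(head.total_faces)  # solver units
        pts = np.array([[0.2, 0, 0], [0, 0, 0.5]])
        phi = potential_from_charges(head, rho, pts, operator=op)
        # solver-unit closed form: phi = (sum A) / (2 pi r)
        total = head.face_areas.sum()
        for val, p in zip(phi, pts):
            assert abs(val - total / (2 * np.pi * np.linalg.norm(p))) < 2e-3 * abs(val)

    def test_neutral_distribution_decays_faster_than_monopole(self, two_sphere_head,
                                                              two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        E = _uniform_incident(head, np.array([1.0, 0, 0]))
        rho = solve_charges(head, E, operator=op).rho
        d1, d2 = 1.0, 2.0
        p1 = potential_from_charges(head, rho, np.array([[d1, 0.3, 0.2]]), operator=op)
        p2 = potential_from_charges(head, rho, np.array([[2 * d1, 0.6, 0.4]]), operator=op)
        assert abs(p2[0]) < abs(p1[0]) / 2  # faster than 1/d

    def test_E_total_reduces_to_incident_for_zero_charge(self, two_sphere_head,
                                                         two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        pts = np.array([[0.0, 0.0, 0.02]])
        E_inc = np.array([[1.0, 2.0, 3.0]])
        out = E_total_at_points(head, np.zeros(head.total_faces), E_inc, pts, operator=op)
        assert np.allclose(out, E_inc)

    def test_interior_field_of_contrast_sphere_matches_closed_form(self):
        # conducting sphere sigma1 embedded in medium sigma2, uniform applied E
        s1, s2 = 0.1, 0.3
        mesh = build_icosphere(0.08, 4)
        head = HeadModel([ConductivityLayer(mesh, s1, s2, "sph")])
        op = ChargeOperator(head)
        E0 = np.array([1.0, 0.0, 0.0])
        sol = solve_charges(head, _uniform_incident(head, E0), operator=op)
        pts = np.array([[0, 0, 0], [0.02, 0.01, -0.015], [0, -0.03, 0.02]])
        E_in = E_total_at_points(head, sol.rho, np.tile(E0, (3, 1)), pts, operator=op)
        expected = 3 * s2 / (s1 + 2 * s2) * E0
        for row in E_in:
            assert np.linalg.norm(row - expected) < 0.02 * np.linalg.norm(expected)

    def test_divergence_free_off_sources(self, two_sphere_head, two_sphere_operator):
        head, op = two_sphere_head, two_sphere_operator
        E = _uniform_incident(head, np.array([1.0, 0, 0]))
        rho = solve_charges(head, E, operator=op).rho
        c = np.array([0.0, 0.0, 0.02])
        h = 1e-3
        div = 0.0
        scale = 0.0
        for k in range(3):
            d = np.zeros(3)
            d[k] = h
            Ep = E_total_at_points(head, rho, np.array([[1, 0, 0]]), (c + d)[None], operator=op)
            Em = E_total_at_points(head, rho, np.array([[1, 0, 0]]), (c - d)[None], operator=op)
            div += (Ep[0, k] - Em[0, k]) / (2 * h)
            scale += np.linalg.norm(Ep[0]) / h
        assert abs(div) <= 1e-6 * scale


class TestNormalEFromCharge:
    def test_coefficient_matches_tissue_conductivities(self):
        # WM/GM interface coefficient in rho/eps0 units
        s_wm, s_gm = 0.126, 0.275
        mesh = build_icosphere(0.06, 1)
        head = HeadModel([ConductivityLayer(mesh, s_wm, s_gm, "wm")])
        rho = np.ones(mesh.n_faces)
        nE = normal_E_from_charge(head, rho, "wm", side="outside")
        coeff_c_units = nE[0] / 2.0  # stored units are rho/(2 eps0)
        assert np.isclose(coeff_c_units, s_wm / (s_wm - s_gm))
        assert np.isclose(coeff_c_units, -0.8456, atol=1e-4)

    def test_zero_charge_gives_zero(self, two_sphere_head):
        out = normal_E_from_charge(two_sphere_head, np.zeros(two_sphere_head.total_faces),
                                   "skull")
        assert np.allclose(out, 0.0)

    def test_zero_contrast_surface_rejected(self):
        mesh = build_icosphere(0.08, 1)
        head = HeadModel([ConductivityLayer(mesh, 0.3, 0.3, "u")])
        with pytest.raises(ValueError):
            normal_E_from_charge(head, np.zeros(mesh.n_faces), "u")

    def test_matches_side_limit_of_total_field(self):
        """The charge shortcut equals the outside limit of n . E_total.

        A coil-driven (inductive) incident field is used: a static uniform
        field induces no interior charge in an insulated conductor, which
        would make the comparison degenerate.  The self-face contribution at
        the evaluation height is taken analytically (uniform charged panel:
        E_n = rho_t * Omega / 2 pi with Omega its subtended solid angle);
        the remaining faces are evaluated with the solver's own quadrature.
        """
        from recimeg.geometry import solid_angles
        from recimeg.sensors import make_magnetometer, primary_E
        outer = build_icosphere(0.09, 3)
        inner = build_icosphere(0.07, 3)
        head = HeadModel([
            ConductivityLayer(outer, 0.25, 0.0, "skin"),
            ConductivityLayer(inner, 0.1, 0.25, "inner"),
        ])
        op = ChargeOperator(head)
        els = make_magnetometer("m", [0.03, 0.02, 0.12], [0.3, 0.1, 1.0]).elements
        rho = solve_charges(head, primary_E(els, head.face_centers), operator=op).rho
        sl = head.layer_slice("inner")
        centers, normals = head.face_centers[sl], head.face_normals[sl]
        areas, tris = head.face_areas[sl], head.triangles[sl]
        sel = np.arange(0, inner.n_faces, 53)
        nE_charge = normal_E_from_charge(head, rho, "inner", side="outside")[sel]
        limits = np.empty(len(sel))
        for row, j in enumerate(sel):
            p = centers[j] + 0.01 * np.sqrt(areas[j]) * normals[j]
            rho_excl = rho.copy()
            rho_excl[sl.start + j] = 0.0
            E = E_total_at_points(head, rho_excl, primary_E(els, p[None]), p[None],
                                  operator=op)[0]
            omega = abs(solid_angles(tris[j][None], p[None])[0, 0])
            limits[row] = normals[j] @ E + rho[sl.start + j] * omega / (2 * np.pi)
        big = np.abs(limits) > 0.3 * np.abs(limits).max()
        rel = np.abs(nE_charge[big] - limits[big]) / np.abs(limits[big])
        assert np.median(rel) < 0.03
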