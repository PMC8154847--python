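import numpy as np
import pytest

from mtfe import (
    ElasticMaterial,
    VoxelImage,
    apply_compression_bc,
    assemble,
    assign_homogeneous,
    hex8_stiffness,
    hex_to_tet_subdivide,
    recover_strains,
    solve,
    tet10_stiffness,
    voxels_to_hex_mesh,
)
from mtfe.fe_solver import _pcg_solve
from mtfe.phantoms import analytic_axial_stiffness

MAT = ElasticMaterial(E=14800.0, nu=0.3)
H = 0.0104


def block_mesh(shape, spacing=H):
    mask = VoxelImage(np.ones(shape, np.uint8), spacing, value_kind="mask")
    return voxels_to_hex_mesh(mask)


def rigid_body_check(K, coords):
    """Rigid translations and infinitesimal rotations give zero force."""
    n = len(coords)
    norm = np.abs(K).max()
    for t in np.eye(3):
        u = np.tile(t, n)
        assert np.abs(K @ u).max() < 1e-9 * norm
    for ax in range(3):
        w = np.zeros(3)
        w[ax] = 1.0
        u = np.cross(np.tile(w, (n, 1)), coords - coords.mean(0)).ravel()
        assert np.abs(K @ u).max() < 1e-8 * norm * (np.abs(u).max() + 1)


class TestHex8Stiffness:
    def test_symmetric_with_six_rigid_modes(self):
        K = hex8_stiffness(MAT, H)
        assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()
        ev = np.linalg.eigvalsh(K)
        assert (np.abs(ev) < 1e-9 * ev.max()).sum() == 6

    def test_linearity_in_modulus(self):
        K1 = hex8_stiffness(ElasticMaterial(E=1000.0, nu=0.3), H)
        K2 = hex8_stiffness(ElasticMaterial(E=2000.0, nu=0.3), H)
        np.testing.assert_allclose(K2, 2 * K1, rtol=1e-14)

    def test_single_element_patch(self):
        # nu=0 bar: prescribe uniform axial compression, strain is exact
        mesh = block_mesh((1, 1, 1))
        K = hex8_stiffness(ElasticMaterial(E=14800.0, nu=0.0), H)
        strain = -0.05
        u = np.zeros((8, 3))
        u[:, 2] = strain * (mesh.nodes[:, 2] - mesh.nodes[:, 2].min())
        _, nodal, e1, e3 = recover_strains(mesh, u)
        np.testing.assert_allclose(nodal[:, 2], strain, atol=1e-14)
        np.testing.assert_allclose(e3, strain, atol=1e-14)


class TestTet10Stiffness:
    def setup_method(self):
        hm = block_mesh((1, 1, 1))
        self.tm = hex_to_tet_subdivide(hm)

    def test_symmetric_with_six_rigid_modes(self):
        corners = self.tm.nodes[self.tm.elements[0, :4]]
        K = tet10_stiffness(MAT, corners)
        assert np.abs(K - K.T).max() < 1e-12 * np.abs(K).max()
        ev = np.linalg.eigvalsh(K)
        assert (np.abs(ev) < 1e-9 * ev.max()).sum() == 6

    def test_rigid_translation_zero_force(self):
        corners = self.tm.nodes[self.tm.elements[0, :4]]
        K = tet10_stiffness(MAT, corners)
        u = np.tile([1.0, -2.0, 0.5], 10)
        assert np.abs(K @ u).max() < 1e-9 * np.abs(K).max()

    def test_degenerate_rejected(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            tet10_stiffness(MAT, flat)

    def test_patch_test_linear_field_exact(self):
        # 2x2x2 cube block subdivided into tets; prescribe an affine field
        # on the boundary, solve the interior: recovered strain must be the
        # exact constant strain of the field
        tm = hex_to_tet_subdivide(block_mesh((2, 2, 2), spacing=1.0))
        asg = assign_homogeneous(tm, MAT)
        K = assemble(tm, asg).K.tocsc()
        A = np.array([[2e-3, 1e-3, 0.0], [0.0, -1e-3, 5e-4], [4e-4, 0.0, -2e-3]])
        u_exact = tm.nodes @ A.T
        coords = tm.nodes
        on_bnd = (
            np.isclose(coords, 0.0) | np.isclose(coords, 2.0)
        ).any(axis=1)
        pres = np.repeat(on_bnd, 3)
        import scipy.sparse.linalg as spla

        u = u_exact.ravel().copy()
        free = ~pres
        u[free] = spla.spsolve(
            K[free][:, free], -K[free][:, pres] @ u_exact.ravel()[pres]
        )
        np.testing.assert_allclose(u, u_exact.ravel(), atol=1e-10)
        elem_strain, _, _, _ = recover_strains(tm, u.reshape(-1, 3))
        S = 0.5 * (A + A.T)
        expected = np.array(
            [S[0, 0], S[1, 1], S[2, 2], 2 * S[0, 1], 2 * S[1, 2], 2 * S[0, 2]]
        )
        np.testing.assert_allclose(
            elem_strain, np.tile(expected, (tm.n_elements, 1)), atol=1e-10
        )


class TestAssemble:
    def test_single_element_equals_element_matrix(self):
        mesh = block_mesh((1, 1, 1))
        K = assemble(mesh, assign_homogeneous(mesh, MAT)).K.toarray()
        Ke = hex8_stiffness(MAT, H)
        # gather global DOFs in element-local corner order
        dof = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in mesh.elements[0]])
        np.testing.assert_allclose(K[np.ix_(dof, dof)], Ke, rtol=1e-12)

    def test_two_element_shared_block_sums(self):
        mesh = block_mesh((2, 1, 1))
        K = assemble(mesh, assign_homogeneous(mesh, MAT)).K.toarray()
        # brute-force dense assembly
        Ke = hex8_stiffness(MAT, H)
        dense = np.zeros((36, 36))
        for el in mesh.elements:
            dof = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in el])
            dense[np.ix_(dof, dof)] += Ke
        np.testing.assert_allclose(K, dense, rtol=1e-12)

    def test_rigid_modes_in_global_matrix(self):
        mesh = block_mesh((2, 2, 2))
        K = assemble(mesh, assign_homogeneous(mesh, MAT)).K
        rigid_body_check(K, mesh.nodes)

    def test_unassigned_elements_rejected(self):
        from mtfe.materials import MaterialAssignment

        mesh = block_mesh((2, 1, 1))
        bad = MaterialAssignment(element_E=np.array([1.0]), nu=0.3, scheme="hete")
        with pytest.raises(ValueError, match="covers"):
            assemble(mesh, bad)


class TestBoundaryConditions:
    def test_single_voxel_corner_sets(self):
        bc = apply_compression_bc(block_mesh((1, 1, 1)), 0.1)
        assert len(bc.fixed_nodes) == 4
        assert len(bc.driven_nodes) == 4

    def test_prism_plane_counts(self):
        mesh = block_mesh((1, 1, 10))
        bc = apply_compression_bc(mesh, 0.1)
        assert len(bc.fixed_nodes) == 4
        assert len(bc.driven_nodes) == 4
        assert mesh.n_nodes - len(bc.fixed_nodes) - len(bc.driven_nodes) == 36

    def test_zero_displacement_zero_solution(self):
        mesh = block_mesh((1, 1, 3))
        sol = solve(assemble(mesh, assign_homogeneous(mesh, MAT)),
                    apply_compression_bc(mesh, 0.0))
        assert np.abs(sol.u).max() == 0.0
        assert np.abs(sol.reactions).max() == 0.0

    def test_tet_end_planes_only(self):
        tm = hex_to_tet_subdivide(block_mesh((1, 1, 2)))
        bc = apply_compression_bc(tm, 0.1)
        z = tm.nodes[:, 2]
        assert np.allclose(z[bc.fixed_nodes], z.min())
        assert np.allclose(z[bc.driven_nodes], z.max())
        # mid-edge nodes on the end faces are included: 4 corners + 4 edge
        # midpoints + 1 face-diagonal midpoint
        assert len(bc.fixed_nodes) == 9


class TestSolve:
    def test_bar_theory_oracle(self, prism_mesh, nu0_material):
        sysm = assemble(prism_mesh, assign_homogeneous(prism_mesh, nu0_material))
        bc = apply_compression_bc(prism_mesh, 0.1)
        sol = solve(sysm, bc)
        S_ref = analytic_axial_stiffness(14800.0, H, 0.0, 10 * H, "prism")
        S = abs(sol.reactions[bc.fixed_nodes, 2].sum()) / 0.1
        assert S == pytest.approx(S_ref, rel=1e-8)

    def test_global_equilibrium(self, small_tube):
        _, (_, mask, _) = small_tube
        mesh = voxels_to_hex_mesh(mask)
        bc = apply_compression_bc(mesh, 0.1)
        sol = solve(assemble(mesh, assign_homogeneous(mesh, MAT)), bc)
        total = sol.reactions.sum(axis=0)
        scale = np.abs(sol.reactions[:, 2]).sum()
        np.testing.assert_allclose(total / scale, 0.0, atol=1e-6)
        fixed_f = sol.reactions[bc.fixed_nodes, 2].sum()
        driven_f = sol.reactions[bc.driven_nodes, 2].sum()
        assert fixed_f == pytest.approx(-driven_f, rel=1e-6)

    def test_direct_and_iterative_agree(self):
        mesh = block_mesh((10, 10, 10))
        sysm = assemble(mesh, assign_homogeneous(mesh, MAT))
        bc = apply_compression_bc(mesh, 0.1)
        sol = solve(sysm, bc)  # direct path (3993 DOFs)

        K = sysm.K
        ndof = K.shape[0]
        prescribed = np.zeros(ndof, bool)
        u_val = np.zeros(ndof)
        for n in bc.fixed_nodes:
            prescribed[3 * n: 3 * n + 3] = True
        zd = 3 * bc.driven_nodes + 2
        prescribed[zd] = True
        u_val[zd] = -0.1
        free = ~prescribed
        uf = _pcg_solve(K[free][:, free], -K[free][:, prescribed] @ u_val[prescribed])
        u_it = u_val.copy()
        u_it[free] = uf
        np.testing.assert_allclose(
            u_it.reshape(-1, 3), sol.u, atol=1e-6 * np.abs(sol.u).max()
        )

    def test_modulus_scaling(self, prism_mesh):
        bc = apply_compression_bc(prism_mesh, 0.1)
        s1 = solve(assemble(prism_mesh, assign_homogeneous(
            prism_mesh, ElasticMaterial(E=10000.0, nu=0.3))), bc)
        s2 = solve(assemble(prism_mesh, assign_homogeneous(
            prism_mesh, ElasticMaterial(E=20000.0, nu=0.3))), bc)
        np.testing.assert_allclose(s2.reactions, 2 * s1.reactions, rtol=1e-9)
        np.testing.assert_allclose(s2.element_strain, s1.element_strain, atol=1e-12)

    def test_stiffness_invariant_to_inplane_translation(self, prism_mask):
        m1 = voxels_to_hex_mesh(prism_mask)
        shifted = VoxelImage(
            prism_mask.data, prism_mask.spacing, origin=(3.0, -2.0, 0.0),
            value_kind="mask",
        )
        m2 = voxels_to_hex_mesh(shifted)
        bc1, bc2 = apply_compression_bc(m1, 0.1), apply_compression_bc(m2, 0.1)
        S = []
        for m, bc in ((m1, bc1), (m2, bc2)):
            sol = solve(assemble(m, assign_homogeneous(m, MAT)), bc)
            S.append(abs(sol.reactions[bc.fixed_nodes, 2].sum()) / 0.1)
        assert S[0] == pytest.approx(S[1], rel=1e-9)


class TestRecoverStrains:
    def test_uniform_compression_principal_strains(self, prism_mesh, nu0_material):
        bc = apply_compression_bc(prism_mesh, 0.1)
        sol = solve(assemble(prism_mesh, assign_homogeneous(prism_mesh, nu0_material)), bc)
        expected = -0.1 / (10 * H)
        np.testing.assert_allclose(sol.nodal_e3, expected, rtol=1e-10)
        np.testing.assert_allclose(sol.nodal_e1, 0.0, atol=1e-10 * abs(expected))

    def test_rigid_translation_zero_strain(self, prism_mesh):
        u = np.tile([0.3, -0.1, 0.7], (prism_mesh.n_nodes, 1))
        elem, nodal, e1, e3 = recover_strains(prism_mesh, u)
        assert np.abs(elem).max() < 1e-12
        assert np.abs(e1).max() < 1e-12 and np.abs(e3).max() < 1e-12

    def test_principal_strains_invariant_to_relabeling(self, prism_mesh):
        from mtfe.meshing import HexMesh

        bc = apply_compression_bc(prism_mesh, 0.05)
        sol = solve(assemble(prism_mesh, assign_homogeneous(prism_mesh, MAT)), bc)
        perm = np.random.default_rng(0).permutation(prism_mesh.n_nodes)
        inv = np.argsort(perm)
        relabeled = HexMesh(
            nodes=prism_mesh.nodes[perm],
            elements=inv[prism_mesh.elements],
            spacing=prism_mesh.spacing,
        )
        _, _, e1p, e3p = recover_strains(relabeled, sol.u[perm])
        np.testing.assert_allclose(np.sort(e1p), np.sort(sol.nodal_e1), atol=1e-12)
        np.testing.assert_allclose(np.sort(e3p), np.sort(sol.nodal_e3), atol=1e-12)
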