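"""Total-Lagrangian solver: assembly, statics, implicit dynamics."""

import numpy as np
import pytest

import breastfem as bf
from breastfem.mesh import box_mesh


@pytest.fixture(scope="module")
def block():
    return box_mesh(2, 2, 2)


@pytest.fixture(scope="module")
def block_model(block):
    return bf.FEModel(block, {"adipose": bf.neo_hookean(10.0)})


class TestVonMises:
    def test_hydrostatic_is_zero(self):
        assert bf.von_mises(4.2 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("s", [3.0, -2.5])
    def test_uniaxial(self, s):
        sig = np.zeros((3, 3))
        sig[0, 0] = s
        assert bf.von_mises(sig) == pytest.approx(abs(s), rel=1e-12)

    def test_pure_shear(self):
        tau = 1.7
        sig = np.zeros((3, 3))
        sig[0, 1] = sig[1, 0] = tau
        assert bf.von_mises(sig) == pytest.approx(np.sqrt(3.0) * tau, rel=1e-12)


class TestAssembly:
    def test_zero_residual_at_reference(self, block_model):
        f, _ = block_model.assemble(np.zeros(block_model.n_dof), tangent=False)
        assert np.abs(f).max() == 0.0

    def test_affine_displacement_gives_uniform_stress(self, block):
        """Patch consistency: a homogeneous deformation gradient produces
        identical element stresses."""
        model = bf.FEModel(block, {"adipose": bf.neo_hookean(10.0)})
        Fh = np.array([[1.1, 0.02, 0.0], [0.0, 0.95, 0.03], [0.01, 0.0, 1.05]])
        u = (block.nodes @ (Fh - np.eye(3)).T).ravel()
        sig = model.element_cauchy(u)
        assert np.abs(sig - sig[0]).max() < 1e-10

    def test_tangent_matches_fd_of_residual(self, block_model, rng):
        u = 0.3 * rng.standard_normal(block_model.n_dof)
        _, K = block_model.assemble(u)
        h = 1e-6
        for j in rng.choice(block_model.n_dof, 8, replace=False):
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            fd = (block_model.assemble(up, tangent=False)[0]
                  - block_model.assemble(um, tangent=False)[0]) / (2 * h)
            col = K[:, j].toarray().ravel()
            assert np.abs(col - fd).max() <= 1e-4 * max(1.0, np.abs(fd).max())

    def test_inverted_element_reported_with_id(self, block, block_model):
        u = np.zeros(block_model.n_dof)
        n = block.tets[0, 0]
        u[3 * n:3 * n + 3] = 100.0  # crush one corner
        with pytest.raises(bf.InvertedElementError, match="element"):
            block_model.assemble(u)

    def test_wrapper_matches_model(self, block):
        mats = {"adipose": bf.neo_hookean(10.0)}
        f1, _ = bf.assemble_internal(block, mats, np.zeros(3 * block.n_nodes))
        assert np.abs(f1).max() == 0.0

    def test_doubling_density_doubles_gravity_load(self, block):
        bcs = bf.BoundaryConditions.from_mesh(block)
        f1 = bf.FEModel(block, {"adipose": bf.neo_hookean(
            10.0, density_kgm3=950.0)}).gravity_forces(bcs)
        f2 = bf.FEModel(block, {"adipose": bf.neo_hookean(
            10.0, density_kgm3=1900.0)}).gravity_forces(bcs)
        assert np.allclose(f2, 2.0 * f1, rtol=1e-12)


class TestStatics:
    def test_zero_gravity_zero_displacement(self, block):
        bcs = bf.BoundaryConditions.from_mesh(block)
        bcs.gravity = np.zeros(3)
        res = bf.solve_static(block, {"adipose": bf.neo_hookean(10.0)}, bcs)
        assert np.abs(res.nodal_displacement).max() == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_hanging_block_matches_refined_solution(self):
        """Tip deflection of a soft block hanging under its own weight
        within 2% of the same solver on a mesh refined 2x per axis
        (mesh-refinement oracle).  The block hangs from its top face with
        axial gravity; the deflection is read at the free-face centre.
        This also guards against volumetric locking at nu = 0.49."""
        mats = {"adipose": bf.neo_hookean(10.0)}

        def tip_deflection(n):
            mesh = box_mesh(n, n, 2 * n, lengths=(20.0, 20.0, 60.0))
            bcs = bf.BoundaryConditions(
                driven_nodes=mesh.node_sets["top"],
                symmetry_nodes=np.empty(0, int),
                gravity=np.array([0.0, 0.0, -9800.0]))
            res = bf.solve_static(mesh, mats, bcs)
            bot = mesh.node_sets["torso_base"]
            ctr = bot[np.argmin(np.linalg.norm(mesh.nodes[bot, :2] - 10.0,
                                               axis=1))]
            return res.nodal_displacement[0][ctr, 2]

        coarse, fine = tip_deflection(3), tip_deflection(6)
        assert abs(coarse) > 0.5  # a real sag, not a trivial zero
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_reaction_balances_gravity(self, block):
        mats = {"adipose": bf.neo_hookean(10.0)}
        bcs = bf.BoundaryConditions.from_mesh(block)
        model = bf.FEModel(block, mats)
        res = bf.solve_static(block, mats, bcs, model=model)
        f_grav = model.gravity_forces(bcs)
        # total support reaction equals total weight
        assert res.reaction_forces[0].sum() == pytest.approx(-f_grav.sum(),
                                                             rel=1e-5)


class TestDynamics:
    def flat_trajectory(self, duration=0.2):
        return bf.build_synthetic_gait(duration=duration, amp_y=0.0,
                                       amp_x=0.0, noise_sd=0.0)

    def test_equilibrium_is_fixed_point(self, block):
        mats = {"adipose": bf.neo_hookean(10.0)}
        bcs = bf.BoundaryConditions.from_mesh(block)
        model = bf.FEModel(block, mats)
        stat = bf.solve_static(block, mats, bcs, model=model)
        dyn = bf.solve_dynamic(block, mats, bcs, self.flat_trajectory(),
                               n_steps=20, static_prestate=stat, model=model)
        drift = np.abs(dyn.nodal_displacement
                       - stat.nodal_displacement[0]).max()
        assert drift < 1e-6

    def test_rigid_translation_produces_no_stress(self):
        """Objectivity: when every node is driven through the same
        translation, the von Mises field stays (numerically) zero."""
        mesh = box_mesh(2, 2, 2)
        mats = {"adipose": bf.neo_hookean(10.0)}
        bcs = bf.BoundaryConditions(driven_nodes=np.arange(mesh.n_nodes),
                                    symmetry_nodes=np.empty(0, int),
                                    gravity=np.zeros(3))
        traj = bf.build_synthetic_gait(duration=0.2, amp_y=12.0, amp_x=5.0,
                                       noise_sd=0.0)
        dyn = bf.solve_dynamic(mesh, mats, bcs, traj, n_steps=20)
        assert dyn.element_von_mises.max() < 1e-9

    def test_column_responds_at_driving_frequency(self):
        """Spectral check: a base-driven column's tip motion is dominated
        by the driving frequency."""
        mesh = box_mesh(1, 1, 4, lengths=(10.0, 10.0, 40.0))
        mats = {"adipose": bf.neo_hookean(50.0)}
        bcs = bf.BoundaryConditions(driven_nodes=mesh.node_sets["torso_base"],
                                    symmetry_nodes=np.empty(0, int),
                                    gravity=np.zeros(3))
        f_drive = 1.0 / 0.38
        traj = bf.build_synthetic_gait(duration=1.7, amp_y=2.0, amp_x=0.0,
                                       noise_sd=0.0, ramp_cycles=1.0)
        dyn = bf.solve_dynamic(mesh, mats, bcs, traj, n_steps=300)
        tip = mesh.node_sets["top"][0]
        y = dyn.nodal_displacement[60:, tip, 1]
        spec = np.abs(np.fft.rfft(y - y.mean()))
        freqs = np.fft.rfftfreq(y.size, 0.005)
        assert freqs[np.argmax(spec)] == pytest.approx(f_drive, rel=0.15)

    def test_trajectory_too_short_rejected(self, block):
        mats = {"adipose": bf.neo_hookean(10.0)}
        bcs = bf.BoundaryConditions.from_mesh(block)
        with pytest.raises(ValueError, match="shorter"):
            bf.solve_dynamic(block, mats, bcs, self.flat_trajectory(0.05),
                             n_steps=600)

    def test_symmetry_plane_follows_torso_exactly(self, coarse_mesh,
                                                  coarse_static, materials):
        """The sagittal-plane nodes carry zero displacement normal to the
        (torso-attached) symmetry plane at every frame."""
        traj = bf.build_synthetic_gait(duration=0.3, amp_y=20.0, amp_x=8.0,
                                       noise_sd=0.0)
        dyn = bf.solve_dynamic(coarse_mesh, materials, coarse_static["bcs"],
                               traj, n_steps=20,
                               static_prestate=coarse_static["result"],
                               model=coarse_static["model"])
        sym = coarse_mesh.node_sets["symmetry_plane"]
        clav = coarse_mesh.node_sets["clavicle"][0]
        gap = dyn.nodal_displacement[:, sym, 0] \
            - dyn.nodal_displacement[:, clav, 0][:, None]
        assert np.abs(gap).max() <= 1e-8

    def test_newton_iterations_bounded(self, coarse_mesh, coarse_static,
                                       materials):
        traj = bf.build_synthetic_gait(duration=0.3, amp_y=20.0, amp_x=8.0,
                                       noise_sd=0.0)
        dyn = bf.solve_dynamic(coarse_mesh, materials, coarse_static["bcs"],
                               traj, n_steps=10,
                               static_prestate=coarse_static["result"],
                               model=coarse_static["model"])
        from collections import Counter
        per_step = Counter(d["label"] for d in dyn.convergence_log)
        assert max(per_step.values()) <= 25
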