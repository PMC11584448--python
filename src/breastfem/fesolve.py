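"""Total-Lagrangian finite-element solver for the labelled anatomy mesh.

Elements are 4-node constant-strain tetrahedra carrying the hyperelastic
materials of :mod:`breastfem.constitutive`; skin shells are hyperelastic
membranes (thickness x incompressible plane-stress Neo-Hookean energy, no
bending).  Near-incompressibility (nu = 0.49) is handled by patch-based
mean dilatation; the consistent tangent is closed-form (cross-checked in
the tests against a complex-step derivative of the stress), so Newton's
method converges quadratically.  The mass matrix is lumped (row sum).

Boundary conditions: the torso-base node set is glued to the rigid torso
and follows a prescribed displacement trajectory in X and Y (Z held at
zero); the sagittal symmetry plane carries a zero-normal-displacement
condition expressed in the torso frame, i.e. its x-DOFs translate rigidly
with the driven base.  Gravity defaults to (0, -9800, 0) mm/s^2 and can be
switched per component.

Statics: incremental gravity loading with full Newton-Raphson.
Dynamics: implicit Newmark (average acceleration, gamma = 1/2, beta = 1/4)
with full Newton-Raphson per step and automatic local step bisection.
Units mm-kg-s (stress kPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .constitutive import (ConstitutiveModel, InvertedElementError, det3, inv3,
                           pk1_iso_stress, pk1_local_tangent_analytic)
from .mesh import LabelledTetMesh
from .trajectory import Trajectory

DEFAULT_GRAVITY = np.array([0.0, -9800.0, 0.0])  # mm/s^2


class ConvergenceError(RuntimeError):
    """Newton iteration or step bisection failed; carries the residual log."""

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log or []


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Equivalent von Mises stress sqrt(3/2 dev(s):dev(s)), batched."""
    s = np.asarray(stress, dtype=float)
    tr = np.trace(s, axis1=-2, axis2=-1) / 3.0
    dev = s - tr[..., None, None] * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


@dataclass
class BoundaryConditions:
    """Driven base, symmetry plane and gravity switches."""

    driven_nodes: np.ndarray
    symmetry_nodes: np.ndarray
    gravity: np.ndarray = field(default_factory=lambda: DEFAULT_GRAVITY.copy())
    gravity_components: dict | None = None  # component label -> bool
    drive_symmetry_x: bool = True

    def __post_init__(self):
        self.driven_nodes = np.unique(np.asarray(self.driven_nodes, dtype=int))
        self.symmetry_nodes = np.unique(np.asarray(self.symmetry_nodes, dtype=int))
        self.gravity = np.asarray(self.gravity, dtype=float)

    @classmethod
    def from_mesh(cls, mesh: LabelledTetMesh, **kw) -> "BoundaryConditions":
        return cls(driven_nodes=mesh.node_sets["torso_base"],
                   symmetry_nodes=mesh.node_sets["symmetry_plane"], **kw)

    def gravity_on(self, component: str) -> bool:
        if self.gravity_components is None:
            return True
        return bool(self.gravity_components.get(component, True))


@dataclass
class SimulationResult:
    """Histories of a static (single-frame) or dynamic run."""

    times: np.ndarray
    nodal_displacement: np.ndarray     # (n_frames, n_nodes, 3) mm
    nodal_velocity: np.ndarray         # mm/s
    nodal_acceleration: np.ndarray     # mm/s^2
    element_von_mises: np.ndarray      # (n_frames, n_tets) kPa
    convergence_log: list
    prescribed_dofs: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    reaction_forces: np.ndarray | None = None   # (n_frames, n_prescribed)
    #: kinetic energy of the discrete (Newmark recursion) state per frame;
    #: together with reaction_forces it closes the discrete energy balance
    discrete_kinetic_energy: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.times.size


class FEModel:
    """Precomputed element data and assembly for one mesh + material set."""

    def __init__(self, mesh: LabelledTetMesh, materials: dict):
        mesh.validate()
        self.mesh = mesh
        self.materials = materials
        self.n_dof = 3 * mesh.n_nodes
        X = mesh.nodes
        tets = mesh.tets

        # shape-function gradients G (n_el, 4, 3) and reference volumes
        D = np.stack([X[tets[:, i]] - X[tets[:, 0]] for i in (1, 2, 3)], axis=2)
        self.V0 = det3(np.swapaxes(D, 1, 2)) / 6.0
        Dinv = inv3(D)                       # rows of Dinv are grads of N1..N3
        G = np.empty((tets.shape[0], 4, 3))
        G[:, 1:, :] = Dinv                   # row a of D^-1 = grad N_{a+1}
        G[:, 0, :] = -G[:, 1:, :].sum(axis=1)
        self.G = G
        self.edof = (3 * tets[:, :, None] + np.arange(3)).reshape(-1, 12)
        self._rows = np.repeat(self.edof, 12, axis=1).ravel()
        self._cols = np.tile(self.edof, (1, 12)).ravel()

        missing = set(np.unique(mesh.element_component)) - set(materials)
        if missing:
            raise KeyError(f"materials missing for components: {sorted(missing)}")
        self.groups = {c: np.flatnonzero(mesh.element_component == c)
                       for c in np.unique(mesh.element_component)}

        # mean-dilatation patches: tets sharing a patch (and component)
        # average their volumetric strain, relieving locking at nu = 0.49
        comps, code = np.unique(mesh.element_component, return_inverse=True)
        ep = mesh.element_patch
        if ep is None:
            raw = np.arange(mesh.n_tets, dtype=np.int64)
        else:
            ep = np.asarray(ep, dtype=np.int64)
            raw = np.where(ep >= 0, ep * len(comps) + code,
                           -(np.arange(mesh.n_tets, dtype=np.int64) + 1))
        _, self.patch = np.unique(raw, return_inverse=True)
        self.n_patch = int(self.patch.max()) + 1
        self.Vp = np.bincount(self.patch, weights=self.V0,
                              minlength=self.n_patch)
        d_e = np.array([materials[c].d_incomp
                        for c in mesh.element_component])
        self.d_patch = np.empty(self.n_patch)
        self.d_patch[self.patch] = d_e        # uniform within a patch
        self._prow = np.repeat(self.patch, 12)
        self._pcol = self.edof.ravel()

        # skin membranes: local orthonormal tangent basis + 2D shape grads
        sh = mesh.shells
        self.has_shells = sh.shape[0] > 0 and "skin" in materials
        if self.has_shells:
            e1 = X[sh[:, 1]] - X[sh[:, 0]]
            e2 = X[sh[:, 2]] - X[sh[:, 0]]
            t1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
            e2p = e2 - np.einsum("ij,ij->i", e2, t1)[:, None] * t1
            t2 = e2p / np.linalg.norm(e2p, axis=1, keepdims=True)
            p1 = np.stack([np.einsum("ij,ij->i", e1, t1),
                           np.zeros(sh.shape[0])], axis=1)
            p2 = np.stack([np.einsum("ij,ij->i", e2, t1),
                           np.einsum("ij,ij->i", e2, t2)], axis=1)
            Dm = np.stack([p1, p2], axis=2)          # (n_sh, 2, 2) columns p1,p2
            det = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
            self.A0 = 0.5 * np.abs(det)
            Dminv = np.empty_like(Dm)
            Dminv[:, 0, 0] = Dm[:, 1, 1]
            Dminv[:, 0, 1] = -Dm[:, 0, 1]
            Dminv[:, 1, 0] = -Dm[:, 1, 0]
            Dminv[:, 1, 1] = Dm[:, 0, 0]
            Dminv /= det[:, None, None]
            Gs = np.empty((sh.shape[0], 3, 2))
            Gs[:, 1:, :] = Dminv                 # rows of Dm^-1 = grad N_1, N_2
            Gs[:, 0, :] = -Gs[:, 1:, :].sum(axis=1)
            self.Gs = Gs
            self.sh_edof = (3 * sh[:, :, None] + np.arange(3)).reshape(-1, 9)
            self._sh_rows = np.repeat(self.sh_edof, 9, axis=1).ravel()
            self._sh_cols = np.tile(self.sh_edof, (1, 9)).ravel()

        self.mass = self._lumped_mass()

    # -- mass and external load ------------------------------------------

    def _lumped_mass(self) -> np.ndarray:
        m = np.zeros(self.mesh.n_nodes)
        for comp, idx in self.groups.items():
            rho = self.materials[comp].density
            np.add.at(m, self.mesh.tets[idx], (rho * self.V0[idx] / 4.0)[:, None])
        if self.has_shells:
            rho = self.materials["skin"].density
            ms = rho * self.A0 * self.mesh.shell_thickness / 3.0
            np.add.at(m, self.mesh.shells, ms[:, None])
        return m

    def gravity_forces(self, bcs: BoundaryConditions) -> np.ndarray:
        """External nodal gravity load vector (length 3 n_nodes)."""
        f = np.zeros((self.mesh.n_nodes, 3))
        for comp, idx in self.groups.items():
            if not bcs.gravity_on(comp):
                continue
            rho = self.materials[comp].density
            w = (rho * self.V0[idx] / 4.0)[:, None, None] * bcs.gravity
            np.add.at(f, self.mesh.tets[idx], np.broadcast_to(w, (idx.size, 4, 3)))
        if self.has_shells and bcs.gravity_on("skin"):
            rho = self.materials["skin"].density
            w = (rho * self.A0 * self.mesh.shell_thickness / 3.0)[:, None, None] \
                * bcs.gravity
            np.add.at(f, self.mesh.shells, np.broadcast_to(w, (self.A0.size, 3, 3)))
        return f.ravel()

    # -- kinematics -------------------------------------------------------

    def deformation_gradients(self, u: np.ndarray, idx=None) -> np.ndarray:
        """F per tet (optionally a subset) for nodal displacements u."""
        un = u.reshape(-1, 3)
        els = self.mesh.tets if idx is None else self.mesh.tets[idx]
        G = self.G if idx is None else self.G[idx]
        ue = un[els]
        return np.eye(3) + np.einsum("eai,eaJ->eiJ", ue, G)

    def _element_state(self, u: np.ndarray):
        """Per-tet J, J F^-T, isochoric PK1, and the patch pressure
        U'(theta) of the mean-dilatation volumetric term."""
        n = self.mesh.n_tets
        J = np.empty(n)
        JFinvT = np.empty((n, 3, 3))
        P_iso = np.empty((n, 3, 3))
        Fs = {}
        for comp, idx in self.groups.items():
            F = self.deformation_gradients(u, idx)
            Jg = det3(F)
            if np.any(Jg <= 0.0):
                bad = idx[int(np.argmin(Jg))]
                raise InvertedElementError(
                    f"element {bad} ({comp}) inverted (J = {Jg.min():.3g})")
            J[idx] = Jg
            JFinvT[idx] = Jg[:, None, None] * np.swapaxes(inv3(F), -1, -2)
            P_iso[idx] = pk1_iso_stress(self.materials[comp], F)
            Fs[comp] = F
        theta = np.bincount(self.patch, weights=J * self.V0,
                            minlength=self.n_patch) / self.Vp
        pressure = (2.0 / self.d_patch) * (theta - 1.0)   # U'(theta), kPa
        return J, JFinvT, P_iso, pressure, Fs

    def element_cauchy(self, u: np.ndarray) -> np.ndarray:
        """Cauchy stress tensor per tet (n_tet, 3, 3), with the volumetric
        pressure taken from the patch-averaged dilatation."""
        un = u.reshape(-1, 3)
        J, JFinvT, P_iso, pressure, _ = self._element_state(u)
        P = P_iso + pressure[self.patch, None, None] * JFinvT
        F = np.eye(3) + np.einsum("eai,eaJ->eiJ", un[self.mesh.tets], self.G)
        sig = (P @ np.swapaxes(F, -1, -2)) / J[:, None, None]
        return 0.5 * (sig + np.swapaxes(sig, -1, -2))

    def element_von_mises(self, u: np.ndarray) -> np.ndarray:
        return von_mises(self.element_cauchy(u))

    def strain_energy(self, u: np.ndarray) -> float:
        """Total strain energy (kPa mm^3 = micro-J) at displacement u,
        isochoric per element plus volumetric per mean-dilatation patch."""
        from .constitutive import _invariants, _iso_derivatives
        total = 0.0
        J_all = np.empty(self.mesh.n_tets)
        for comp, idx in self.groups.items():
            F = self.deformation_gradients(u, idx)
            J, _, I1b, I2b, _ = _invariants(F)
            J_all[idx] = J
            mat = self.materials[comp]
            if mat.kind == "neo_hookean":
                W = 0.5 * mat.mu * (I1b - 3.0)
            else:
                c = mat.coefficients
                a, b = I1b - 3.0, I2b - 3.0
                W = (c["C10"] * a + c["C01"] * b + c["C11"] * a * b
                     + c["C20"] * a ** 2 + c["C02"] * b ** 2)
            total += float(np.dot(np.atleast_1d(W), self.V0[idx]))
        theta = np.bincount(self.patch, weights=J_all * self.V0,
                            minlength=self.n_patch) / self.Vp
        total += float(np.dot((1.0 / self.d_patch) * (theta - 1.0) ** 2, self.Vp))
        if self.has_shells:
            Fs = self._shell_F(u)
            C = np.einsum("eia,eib->eab", Fs, Fs)
            detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
            mu = self.materials["skin"].mu
            W = 0.5 * mu * (C[:, 0, 0] + C[:, 1, 1] + 1.0 / detC - 3.0)
            total += float(np.dot(W, self.A0 * self.mesh.shell_thickness))
        return total

    def kinetic_energy(self, v: np.ndarray) -> float:
        return 0.5 * float(np.dot(self.mass, (v.reshape(-1, 3) ** 2).sum(axis=1)))

    # -- assembly ---------------------------------------------------------

    def _shell_F(self, u, dtype=float):
        un = u.reshape(-1, 3)
        x = (self.mesh.nodes + un)[self.mesh.shells].astype(dtype)
        return np.einsum("eai,eab->eib", x, self.Gs)   # (n_sh, 3, 2)

    @staticmethod
    def _membrane_P(mu, Fs):
        """Incompressible plane-stress Neo-Hookean membrane stress dW/dF_s."""
        C = np.einsum("eia,eib->eab", Fs, Fs)
        detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
        if not np.iscomplexobj(Fs) and np.any(detC.real <= 0):
            raise InvertedElementError("degenerate skin membrane element")
        Cinv = np.empty_like(C)
        Cinv[:, 0, 0] = C[:, 1, 1]
        Cinv[:, 0, 1] = -C[:, 0, 1]
        Cinv[:, 1, 0] = -C[:, 1, 0]
        Cinv[:, 1, 1] = C[:, 0, 0]
        Cinv = Cinv / detC[:, None, None]
        return mu * (Fs - (1.0 / detC)[:, None, None] * np.einsum(
            "eia,eab->eib", Fs, Cinv))

    def assemble(self, u: np.ndarray, tangent: bool = True):
        """Internal nodal force vector and (optionally) the consistent
        tangent stiffness of the mean-dilatation formulation.

        The tangent is the element-local linearization at frozen patch
        pressure plus the exact rank-one volumetric coupling
        G_p^T diag(U''_p / V_p) G_p per patch.  Raises
        :class:`InvertedElementError` naming the first element with
        det F <= 0.
        """
        f = np.zeros(self.n_dof)
        J, JFinvT, P_iso, pressure, Fs = self._element_state(u)
        p_e = pressure[self.patch]
        P = P_iso + p_e[:, None, None] * JFinvT
        fe = np.einsum("eiJ,eaJ->eai", P, self.G) * self.V0[:, None, None]
        np.add.at(f.reshape(-1, 3), self.mesh.tets, fe)

        kdata = []
        if tangent:
            for comp, idx in self.groups.items():
                A = pk1_local_tangent_analytic(self.materials[comp], Fs[comp],
                                               p_e[idx])
                Ke = np.einsum("eaJ,eiJkL,ebL->eaibk", self.G[idx], A,
                               self.G[idx], optimize=True)
                Ke = Ke.reshape(idx.size, 12, 12) * self.V0[idx][:, None, None]
                kdata.append((idx, Ke))

        shell_K = None
        if self.has_shells:
            mu = self.materials["skin"].mu
            tsk = self.mesh.shell_thickness
            Fs = self._shell_F(u)
            P = self._membrane_P(mu, Fs)
            fe = np.einsum("eib,eab->eai", P, self.Gs) * (self.A0 * tsk)[:, None, None]
            np.add.at(f.reshape(-1, 3), self.mesh.shells, fe)
            if tangent:
                h = 1e-30
                Ks = np.empty((self.A0.size, 9, 9))
                un = u.reshape(-1, 3)
                xc = (self.mesh.nodes + un)[self.mesh.shells].astype(complex)
                for a in range(3):
                    for i in range(3):
                        xp = xc.copy()
                        xp[:, a, i] += 1j * h
                        Fp = np.einsum("eai,eab->eib", xp, self.Gs)
                        Pp = self._membrane_P(mu, Fp).imag / h
                        dfe = np.einsum("eib,ecb->eci", Pp, self.Gs) \
                            * (self.A0 * tsk)[:, None, None]
                        Ks[:, :, 3 * a + i] = dfe.reshape(-1, 9)
                shell_K = Ks

        if not tangent:
            return f, None
        data = np.empty((self.mesh.n_tets, 12, 12))
        for idx, Ke in kdata:
            data[idx] = Ke
        K = sparse.coo_matrix((data.ravel(), (self._rows, self._cols)),
                              shape=(self.n_dof, self.n_dof)).tocsr()
        # volumetric patch coupling: b_e = d(deformed volume)/du
        b = (np.einsum("eiJ,eaJ->eai", JFinvT, self.G)
             * self.V0[:, None, None]).reshape(-1)
        Gp = sparse.coo_matrix((b, (self._prow, self._pcol)),
                               shape=(self.n_patch, self.n_dof)).tocsr()
        K = K + Gp.T @ sparse.diags(2.0 / (self.d_patch * self.Vp)) @ Gp
        if shell_K is not None:
            K = K + sparse.coo_matrix(
                (shell_K.ravel(), (self._sh_rows, self._sh_cols)),
                shape=(self.n_dof, self.n_dof)).tocsr()
        return f, K


def assemble_internal(mesh: LabelledTetMesh, materials: dict, u: np.ndarray):
    """Internal force vector and consistent tangent at displacement u.

    With no external load the residual is this internal force; callers
    subtract their load vector.  Convenience wrapper over :class:`FEModel`.
    """
    return FEModel(mesh, materials).assemble(np.asarray(u, float).ravel())


# -- Dirichlet bookkeeping -------------------------------------------------

def _prescribed_dofs(mesh, bcs: BoundaryConditions):
    """Sorted prescribed DOF indices and a map t -> values.

    Driven (torso base) nodes are prescribed in X, Y (trajectory) and Z
    (zero).  Symmetry-plane x-DOFs are tied to the driven X value so the
    sagittal plane translates with the torso.
    """
    drv = bcs.driven_nodes
    sym = np.setdiff1d(bcs.symmetry_nodes, drv)
    dofs = [3 * drv, 3 * drv + 1, 3 * drv + 2, 3 * sym]
    kinds = [np.full(drv.size, 0), np.full(drv.size, 1), np.full(drv.size, 2),
             np.full(sym.size, 0 if bcs.drive_symmetry_x else 3)]
    dofs = np.concatenate(dofs)
    kinds = np.concatenate(kinds)
    order = np.argsort(dofs)
    dofs, kinds = dofs[order], kinds[order]

    def values(base_disp):
        """base_disp: (3,) displacement of the rigid torso at this time."""
        out = np.zeros(dofs.size)
        out[kinds == 0] = base_disp[0]
        out[kinds == 1] = base_disp[1]
        # kind 2 (z) and kind 3 (fixed symmetry) stay zero
        return out

    return dofs, values


def _newton(model: FEModel, u, pdofs, pvals, residual_fn, diag_add, atol,
            max_iter, log, label, cache=None):
    """Newton-Raphson on the free DOFs with lazy tangent refresh.

    residual_fn(u, f_int) must return the full residual vector; diag_add is
    added to the tangent diagonal (dynamic mass term).  The factorized
    tangent is reused — within the iteration and, via *cache* (a dict
    carried across calls), between time steps — and refreshed whenever the
    residual reduction stalls, which restores the full-Newton quadratic
    tail near the solution.  A backtracking line search on the residual
    norm globalizes the iteration through locally indefinite states (e.g.
    skin-membrane wrinkling at peak load).
    """
    free = np.setdiff1d(np.arange(model.n_dof), pdofs)
    u = u.copy()
    u[pdofs] = pvals
    cache = cache if cache is not None else {}
    rn_prev, stalled = np.inf, False
    f_int = None
    for it in range(1, max_iter + 1):
        # refresh when stalled, and periodically: slow linear contraction
        # (ratio ~0.2-0.3) would otherwise never trigger a refresh yet
        # needs many iterations from the large predictor residuals
        refresh = cache.get("fact") is None or stalled or it % 6 == 0
        if refresh or f_int is None:
            f_int, K = model.assemble(u, tangent=refresh)
        r = residual_fn(u, f_int)
        rn = np.linalg.norm(r[free])
        log.append({"label": label, "iteration": it, "residual": float(rn),
                    "tangent_refresh": bool(refresh)})
        if rn <= atol:
            return u, it, rn
        stalled = rn > 0.33 * rn_prev
        rn_prev = rn
        if refresh:
            if diag_add is not None:
                K = K + sparse.diags(diag_add)
            cache["fact"] = splu(K[free][:, free].tocsc())
        du = cache["fact"].solve(-r[free])

        # backtracking line search: accept the first residual decrease.
        # If none is found with a STALE tangent, refresh and retry the
        # iteration; with a FRESH tangent, trust the plain Newton step
        # (the tangent can be locally indefinite — e.g. membrane
        # wrinkling — where Newton still converges without descent).
        accepted = None
        fallback = None          # largest-scale non-inverted trial
        scale = 1.0
        while scale >= 1.0 / 16.0:
            u_try = u.copy()
            u_try[free] += scale * du
            try:
                f_try, _ = model.assemble(u_try, tangent=False)
                rn_try = np.linalg.norm(residual_fn(u_try, f_try)[free])
            except InvertedElementError:
                scale *= 0.5
                continue
            if fallback is None:
                fallback = (u_try, f_try)
            if rn_try < rn:
                accepted = (u_try, f_try)
                break
            scale *= 0.5
        if accepted is None:
            if not refresh:
                cache["fact"] = None   # stale direction: refresh, retry
                f_int = None
                continue
            if fallback is None:
                raise ConvergenceError(
                    f"line search hit inverted elements ({label})", log)
            accepted = fallback
        u, f_int = accepted
    raise ConvergenceError(
        f"Newton failed to converge ({label}): residual {rn:.3e} > {atol:.3e}",
        log)


def solve_static(mesh: LabelledTetMesh, materials: dict, bcs: BoundaryConditions,
                 load_scale_steps: int = 4, rtol: float = 1e-6,
                 max_newton: int = 25, u0: np.ndarray | None = None,
                 model: FEModel | None = None) -> SimulationResult:
    """Equilibrium under gravity by incremental loading + Newton-Raphson.

    Converged when the free-DOF residual norm drops below
    ``rtol * max(1, |f_ext|)``.  Failed increments are bisected (up to 4
    cuts).  Returns a single-frame :class:`SimulationResult`.
    """
    model = model or FEModel(mesh, materials)
    pdofs, pval_fn = _prescribed_dofs(mesh, bcs)
    pvals = pval_fn(np.zeros(3))
    f_grav = model.gravity_forces(bcs)
    fnorm = np.linalg.norm(f_grav)
    atol = rtol * max(1.0, fnorm)
    log = []
    u = np.zeros(model.n_dof) if u0 is None else np.asarray(u0, float).ravel().copy()

    lam, lam_step, cuts = 0.0, 1.0 / max(1, load_scale_steps), 0
    cache = {}
    while lam < 1.0 - 1e-12:
        lam_try = min(1.0, lam + lam_step)
        try:
            u_new, _, _ = _newton(
                model, u, pdofs, pvals,
                lambda uu, fi: fi - lam_try * f_grav, None,
                max(atol * lam_try, rtol), max_newton, log,
                f"static lam={lam_try:.3f}", cache=cache)
        except (ConvergenceError, InvertedElementError):
            cuts += 1
            lam_step *= 0.5
            if cuts > 6:
                raise ConvergenceError(
                    f"static solve failed near load factor {lam_try:.3f}", log)
            continue
        u, lam = u_new, lam_try

    vm = model.element_von_mises(u)[None, :]
    zeros = np.zeros((1, mesh.n_nodes, 3))
    f_int, _ = model.assemble(u, tangent=False)
    reac = (f_int - f_grav)[pdofs][None, :]
    return SimulationResult(
        times=np.zeros(1), nodal_displacement=u.reshape(1, -1, 3).copy(),
        nodal_velocity=zeros.copy(), nodal_acceleration=zeros.copy(),
        element_von_mises=vm, convergence_log=log,
        prescribed_dofs=pdofs, reaction_forces=reac)


def solve_dynamic(mesh: LabelledTetMesh, materials: dict, bcs: BoundaryConditions,
                  trajectory: Trajectory, dt: float = 0.005, n_steps: int = 600,
                  rtol: float = 1e-6, max_newton: int = 25,
                  newmark: tuple = (0.25, 0.5), rayleigh_alpha: float = 0.0,
                  static_prestate: SimulationResult | None = None,
                  max_cuts: int = 4,
                  model: FEModel | None = None) -> SimulationResult:
    """Implicit Newmark transient analysis with prescribed base motion.

    The gravity equilibrium (computed here if *static_prestate* is not
    given) is the initial condition; the driven node set follows the
    trajectory in X and Y.  Default time step 0.005 s; a non-converged step
    is bisected locally up to *max_cuts* times.  Optional mass-proportional
    Rayleigh damping (off by default).
    """
    if trajectory.duration + 1e-9 < n_steps * dt:
        raise ValueError("trajectory shorter than the requested simulation window")
    beta, gamma = newmark
    model = model or FEModel(mesh, materials)
    pdofs, pval_fn = _prescribed_dofs(mesh, bcs)
    f_grav = model.gravity_forces(bcs)
    atol = rtol * max(1.0, np.linalg.norm(f_grav))

    if static_prestate is None:
        static_prestate = solve_static(mesh, materials, bcs, model=model)
    u = static_prestate.nodal_displacement[-1].ravel().copy()
    v = np.zeros(model.n_dof)
    a = np.zeros(model.n_dof)
    mdiag = np.repeat(model.mass, 3)
    cdiag = rayleigh_alpha * mdiag

    n_frames = n_steps + 1
    times = np.arange(n_frames) * dt
    U = np.empty((n_frames, mesh.n_nodes, 3))
    V = np.empty_like(U)
    Acc = np.empty_like(U)
    VM = np.empty((n_frames, mesh.n_tets))
    R = np.empty((n_frames, pdofs.size))
    KEd = np.zeros(n_frames)
    log = []

    U[0], V[0], Acc[0] = (x.reshape(-1, 3) for x in (u, v, a))
    VM[0] = static_prestate.element_von_mises[-1]
    f_int0, _ = model.assemble(u, tangent=False)
    R[0] = (f_int0 - f_grav)[pdofs]

    def base_disp(t):
        return trajectory.resample(np.array([t]), kind="cubic")[0]

    def prescribed_kinematics(t, h):
        """u, v, a of the prescribed DOFs from the trajectory itself
        (central differences).  These physical values are what the result
        arrays report for driven DOFs; the solver's internal Newmark
        recursion (whose weakly stable (-1)^n mode can pollute prescribed
        accelerations) is kept only where discrete consistency matters —
        the reaction forces, so the energy balance closes."""
        um, u0, up = (pval_fn(base_disp(t + s)) for s in (-h, 0.0, h))
        return u0, (up - um) / (2.0 * h), (up - 2.0 * u0 + um) / (h * h)

    cache = {}
    for step in range(1, n_frames):
        t_goal = step * dt
        t_now = (step - 1) * dt
        h = dt
        cuts = 0
        while t_now < t_goal - 1e-12:
            h = min(h, t_goal - t_now)
            t_new = t_now + h
            c0, c1 = 1.0 / (beta * h * h), 1.0 / (beta * h)
            pvals = pval_fn(base_disp(t_new))

            def newmark_acc(uu):
                return c0 * (uu - u) - c1 * v - (0.5 / beta - 1.0) * a

            def residual(uu, fi):
                an = newmark_acc(uu)
                vn = v + h * ((1.0 - gamma) * a + gamma * an)
                return mdiag * an + cdiag * vn + fi - f_grav

            diag = mdiag * c0 + cdiag * (gamma * c1)
            if cache.get("h") != h:      # mass term changed: stale tangent
                cache.clear()
                cache["h"] = h
            # start Newton from the previous converged state: explicit
            # displacement predictors overshoot the stiff modes here
            try:
                u_new, _, _ = _newton(model, u, pdofs, pvals, residual,
                                      diag, atol, max_newton, log,
                                      f"dyn t={t_new:.4f}", cache=cache)
            except (ConvergenceError, InvertedElementError):
                cuts += 1
                if cuts > max_cuts:
                    raise ConvergenceError(
                        f"dynamic step at t={t_new:.4f} s failed after "
                        f"{max_cuts} bisections", log)
                h *= 0.5
                continue
            a_new = newmark_acc(u_new)
            v = v + h * ((1.0 - gamma) * a + gamma * a_new)
            u, a, t_now = u_new, a_new, t_new

        # reactions and kinetic energy from the discrete (recursion) state
        # so the Newmark energy identity closes; reported kinematics of
        # prescribed DOFs from the physical trajectory derivatives
        f_int, _ = model.assemble(u, tangent=False)
        R[step] = (mdiag * a + cdiag * v + f_int - f_grav)[pdofs]
        KEd[step] = 0.5 * float(mdiag @ (v * v))
        v_out, a_out = v.copy(), a.copy()
        _, v_out[pdofs], a_out[pdofs] = prescribed_kinematics(step * dt, dt)
        U[step], V[step], Acc[step] = (x.reshape(-1, 3)
                                       for x in (u, v_out, a_out))
        VM[step] = model.element_von_mises(u)

    return SimulationResult(times=times, nodal_displacement=U, nodal_velocity=V,
                            nodal_acceleration=Acc, element_von_mises=VM,
                            convergence_log=log, prescribed_dofs=pdofs,
                            reaction_forces=R,
                            discrete_kinetic_energy=KEd)


def external_work(result: SimulationResult, model: FEModel,
                  bcs: BoundaryConditions) -> float:
    """Work done on the body by gravity and the driven supports over the
    run (trapezoidal quadrature), for energy-balance checks."""
    f_grav = model.gravity_forces(bcs)
    U = result.nodal_displacement.reshape(result.n_frames, -1)
    w = 0.0
    for k in range(1, result.n_frames):
        du = U[k] - U[k - 1]
        w += float(f_grav @ du)
        rbar = 0.5 * (result.reaction_forces[k] + result.reaction_forces[k - 1])
        w += float(rbar @ du[result.prescribed_dofs])
    return w
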