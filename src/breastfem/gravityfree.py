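"""Gravity-free (unloaded) reference-configuration estimation.

A scanned breast surface is observed under gravity; the stress-free
geometry that sags into it is found by fixed-point iteration.  The
initial guess applies reversed (upward) gravity to the loaded geometry;
each subsequent iterate is corrected by the mismatch between the target
shape and the current reference deformed under downward gravity:

    X_ref^0     = deform(X_loaded, +g)
    X_ref^{k+1} = X_ref^k + alpha * (X_target - deform(X_ref^k, -g))

until the largest nodal mismatch over the breast-surface node set falls
below the tolerance.  Only node positions change; mesh topology is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constitutive import InvertedElementError
from .fesolve import (BoundaryConditions, ConvergenceError, FEModel,
                      solve_static)
from .mesh import LabelledTetMesh


@dataclass
class InverseSettings:
    """Stopping rule and relaxation for the fixed-point iteration."""

    tol: float = 0.1          # mm, max nodal surface mismatch
    max_iter: int = 30
    relaxation: float = 1.0   # step factor alpha in (0, 1]

    def __post_init__(self):
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.relaxation <= 1.0:
            raise ValueError("relaxation must lie in (0, 1]")


class InverseDivergenceError(RuntimeError):
    """Residual grew three iterations in a row; carries the history."""

    def __init__(self, message, history):
        super().__init__(message)
        self.history = history


def _deform(mesh, materials, bcs, u_warm=None, **solve_kw):
    res = solve_static(mesh, materials, bcs, u0=u_warm, **solve_kw)
    u = res.nodal_displacement[0]
    return mesh.nodes + u, u


def estimate_unloaded(mesh_loaded: LabelledTetMesh, materials: dict,
                      settings: InverseSettings | None = None,
                      bcs: BoundaryConditions | None = None,
                      surface_set: str = "breast_surface",
                      verbose: bool = False, **solve_kw):
    """Estimate the unloaded reference mesh for a gravity-loaded shape.

    Parameters
    ----------
    mesh_loaded : the observed (gravity-loaded) geometry; also the target.
    materials : component -> ConstitutiveModel.
    settings : tolerance / iteration cap / relaxation (defaults: 0.1 mm,
        30 iterations, alpha = 1).
    surface_set : node set over which the mismatch is measured (only the
        scanned surface is observable, so the default is the breast
        surface).
    solve_kw : forwarded to :func:`solve_static` (e.g. load_scale_steps).

    Returns
    -------
    (mesh_unloaded, n_iterations, residual_history);
    ``mesh_unloaded.node_sets`` and element arrays are shared with the
    input, only node positions differ.  If the residual never reaches the
    tolerance within ``max_iter``, the best iterate is returned and the
    history carries the non-convergence (its last entry exceeds tol).
    Raises :class:`InverseDivergenceError` after three consecutive
    residual increases.
    """
    settings = settings or InverseSettings()
    if bcs is None:
        bcs = BoundaryConditions.from_mesh(mesh_loaded)
    surf = mesh_loaded.node_sets[surface_set]
    target = mesh_loaded.nodes
    if np.linalg.norm(bcs.gravity) == 0.0:
        return mesh_loaded, 1, [0.0]

    up = replace(bcs, gravity=-bcs.gravity)

    # initializer: the loaded shape pushed up by reversed gravity
    model = FEModel(mesh_loaded, materials)
    x_ref, u_warm = _deform(mesh_loaded, materials, up, model=model, **solve_kw)

    alpha = settings.relaxation
    history = []
    best = (np.inf, x_ref)
    grow = 0
    x_prev_res = np.inf
    for k in range(1, settings.max_iter + 1):
        mesh_k = replace(mesh_loaded, nodes=x_ref)
        model_k = FEModel(mesh_k, materials)
        x_down, u_warm = _deform(mesh_k, materials, bcs, u_warm=u_warm,
                                 model=model_k, **solve_kw)
        mismatch = target - x_down
        res = float(np.linalg.norm(mismatch[surf], axis=1).max())
        history.append(res)
        if verbose:
            print(f"  inverse iteration {k}: max surface mismatch {res:.4f} mm")
        if res < best[0]:
            best = (res, x_ref)
        if res < settings.tol:
            return replace(mesh_loaded, nodes=x_ref), k, history
        grow = grow + 1 if res > x_prev_res else 0
        if grow >= 3:
            raise InverseDivergenceError(
                f"residual grew 3 consecutive iterations (last {res:.3f} mm)",
                history)
        x_prev_res = res

        # relaxed fixed-point update; halve alpha if it inverts elements
        a = alpha
        while True:
            x_try = x_ref + a * mismatch
            try:
                replace(mesh_loaded, nodes=x_try).validate()
                break
            except Exception:
                a *= 0.5
                if a < 1e-3:
                    raise InverseDivergenceError(
                        "update inverts elements even at tiny step", history)
        x_ref = x_try

    return replace(mesh_loaded, nodes=best[1]), settings.max_iter, history
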