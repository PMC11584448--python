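"""Parametric synthetic breast anatomy and synthetic running trajectories.

Stands in for a subject's 4D-scan-derived geometry: a half torso (the
sagittal plane is the symmetry plane) carrying one left breast, built as a
single conforming tetrahedral mesh with per-element component labels:

* curved chest-wall plate (the glued interface to the rigid torso),
* pectoralis slab, thick in the middle and tapering towards the edges,
* 25 mm subcutaneous soft-tissue layer outside the breast footprint,
* breast dome of adipose tissue containing a glandular sub-model
  (lobes in a double circular array, tapering ducts, a circular body near
  the nipple) and a suspensory ligament network (8 radial septa plus
  anterior and posterior sheets),
* skin as triangular membrane shells on the outer surface.

The mesh is produced by splitting a graded rectilinear grid into six
tetrahedra per cell (Freudenthal decomposition, identical in every cell,
hence conforming) and mapping the vertical coordinate from the chest wall
to the outer surface.  Component interfaces therefore share nodes by
construction.  Sub-structures much thinner than the element size (ducts,
ligament septa) are captured by labelling the elements their centerlines
pass through, so every sub-structure is addressable at desk-scale meshes.

Axes: X mediolateral (0 at the sagittal plane), Y vertical,
Z anteroposterior (out of the chest).  Lengths mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .mesh import LabelledTetMesh, MeshError, freudenthal_tets
from .trajectory import Trajectory


class AnatomyError(ValueError):
    """Infeasible anatomy parameters."""


@dataclass(frozen=True)
class AnatomyParams:
    """Dimensions of the synthetic anatomy (all lengths mm)."""

    breast_base_radius: float = 55.0
    breast_protrusion: float = 45.0
    soft_layer_thickness: float = 25.0
    skin_thickness: float = 1.5
    n_lobes: int = 18
    lobe_diameter_range: tuple = (15.0, 18.0)
    duct_diameter_range: tuple = (2.0, 4.0)
    pec_center_thickness: float = 12.0
    pec_edge_thickness: float = 4.0
    ligament_shell_thickness: float = 3.0
    mesh_size_fine: float = 10.0
    mesh_size_coarse: float = 16.0
    chest_wall_radius: float = 200.0
    torso_margin_factor: float = 0.35
    seed: int = 0

    def __post_init__(self):
        lengths = {
            "breast_base_radius": self.breast_base_radius,
            "breast_protrusion": self.breast_protrusion,
            "soft_layer_thickness": self.soft_layer_thickness,
            "skin_thickness": self.skin_thickness,
            "pec_center_thickness": self.pec_center_thickness,
            "pec_edge_thickness": self.pec_edge_thickness,
            "ligament_shell_thickness": self.ligament_shell_thickness,
            "mesh_size_fine": self.mesh_size_fine,
            "mesh_size_coarse": self.mesh_size_coarse,
            "chest_wall_radius": self.chest_wall_radius,
        }
        for name, v in lengths.items():
            if not v > 0:
                raise AnatomyError(f"{name} must be positive, got {v}")
        if self.n_lobes < 1:
            raise AnatomyError("n_lobes must be >= 1")
        if self.mesh_size_fine > self.mesh_size_coarse:
            raise AnatomyError("fine mesh size must not exceed coarse mesh size")
        lo, hi = self.lobe_diameter_range
        if not (0 < lo <= hi):
            raise AnatomyError("invalid lobe_diameter_range")
        lo, hi = self.duct_diameter_range
        if not (0 < lo <= hi):
            raise AnatomyError("invalid duct_diameter_range")

    # derived geometry ----------------------------------------------------

    @property
    def breast_center(self) -> tuple:
        """(x, y) of the breast/nipple axis on the chest."""
        return (self.breast_base_radius + 5.0, 0.0)

    @property
    def torso_extent(self) -> tuple:
        """(x_max, y_half) of the half-torso plate."""
        r = self.breast_base_radius
        return (self.breast_center[0] + r * (1.0 + self.torso_margin_factor),
                r * (1.0 + self.torso_margin_factor))

    def scaled(self, factor: float) -> "AnatomyParams":
        """Geometrically similar parameters with every length scaled."""
        return replace(
            self,
            breast_base_radius=self.breast_base_radius * factor,
            breast_protrusion=self.breast_protrusion * factor,
            soft_layer_thickness=self.soft_layer_thickness * factor,
            skin_thickness=self.skin_thickness * factor,
            lobe_diameter_range=tuple(v * factor for v in self.lobe_diameter_range),
            duct_diameter_range=tuple(v * factor for v in self.duct_diameter_range),
            pec_center_thickness=self.pec_center_thickness * factor,
            pec_edge_thickness=self.pec_edge_thickness * factor,
            ligament_shell_thickness=self.ligament_shell_thickness * factor,
            mesh_size_fine=self.mesh_size_fine * factor,
            mesh_size_coarse=self.mesh_size_coarse * factor,
            chest_wall_radius=self.chest_wall_radius * factor,
        )

    # continuous surfaces -------------------------------------------------

    def z_wall(self, x):
        """Chest-wall surface (convex outward, max at the sternum)."""
        rc = self.chest_wall_radius
        return np.sqrt(np.clip(rc * rc - np.asarray(x, float) ** 2, 0.0, None)) - rc

    def pec_thickness(self, rho):
        """Pectoralis thickness as a function of distance from the
        breast axis: centre value tapering quadratically to the edge."""
        r_ext = 1.6 * self.breast_base_radius
        taper = np.clip(1.0 - (np.asarray(rho, float) / r_ext) ** 2, 0.0, None)
        return self.pec_edge_thickness + (
            self.pec_center_thickness - self.pec_edge_thickness) * taper

    def dome_height(self, rho):
        """Breast dome height above the soft-tissue layer (ellipsoidal cap)."""
        r = np.asarray(rho, float) / self.breast_base_radius
        return self.breast_protrusion * np.sqrt(np.clip(1.0 - r * r, 0.0, None))

    def column_height(self, x, y):
        xb, yb = self.breast_center
        rho = np.hypot(np.asarray(x, float) - xb, np.asarray(y, float) - yb)
        return self.pec_thickness(rho) + self.soft_layer_thickness + self.dome_height(rho)


# -- lobe layout ----------------------------------------------------------

def _lobe_layout(params: AnatomyParams, rng: np.random.Generator):
    """Centers (x, y) and radii of the lobes in a double circular array
    around the nipple axis.  Raises AnatomyError if the lobes cannot be
    placed without intersecting or leaving the breast."""
    n = params.n_lobes
    d_lo, d_hi = params.lobe_diameter_range
    radii = rng.uniform(d_lo, d_hi, size=n) / 2.0
    n_in = max(1, int(round(n / 3))) if n > 2 else n
    n_out = n - n_in
    xb, yb = params.breast_center

    def ring_radius(m):
        # minimum circle radius so that m spheres of max diameter fit
        return 0.0 if m <= 1 else 1.1 * d_hi / (2.0 * math.sin(math.pi / m))

    r_in = max(ring_radius(n_in), 0.30 * params.breast_base_radius)
    r_out = max(ring_radius(n_out), r_in + 1.05 * d_hi) if n_out else r_in
    if r_out + radii.max() > 0.95 * params.breast_base_radius:
        raise AnatomyError(
            f"{n} lobes of diameter {d_hi} mm do not fit inside a breast of "
            f"base radius {params.breast_base_radius} mm")
    centers = []
    for m, r_ring, offset in ((n_in, r_in, 0.0), (n_out, r_out, math.pi / n_out if n_out else 0.0)):
        for j in range(m):
            th = 2.0 * math.pi * j / m + offset
            centers.append((xb + r_ring * math.cos(th), yb + r_ring * math.sin(th)))
    centers = np.asarray(centers)
    # pairwise feasibility (same-ring spacing is guaranteed by construction,
    # this also guards the inner/outer gap for unusual parameter choices)
    dd = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    need = radii[:, None] + radii[None, :]
    np.fill_diagonal(dd, np.inf)
    if (dd < need).any():
        raise AnatomyError("lobe spheres intersect; reduce n_lobes or diameters")
    return centers, radii


# -- mesh construction -----------------------------------------------------

def _graded_axis(breaks, sizes):
    pts = [float(breaks[0])]
    for (a, b), s in zip(zip(breaks[:-1], breaks[1:]), sizes):
        span = b - a
        if span <= 1e-9:
            continue
        ncell = max(1, int(round(span / s)))
        pts.extend(np.linspace(a, b, ncell + 1)[1:])
    return np.asarray(pts)


def build_anatomy(params: AnatomyParams | None = None) -> LabelledTetMesh:
    """Generate the labelled multi-component breast mesh.

    Returns a conforming :class:`LabelledTetMesh` with components
    ``soft_layer, adipose, pectoralis, ligament, gland`` plus skin shells,
    and node sets ``nipple, clavicle, symmetry_plane, torso_base,
    breast_surface``.  Deterministic for a given seed.
    """
    p = params if params is not None else AnatomyParams()
    rng = np.random.default_rng(p.seed)
    xb, yb = p.breast_center
    R = p.breast_base_radius
    x_max, y_half = p.torso_extent

    x_axis = _graded_axis([0.0, xb + R, x_max], [p.mesh_size_fine, p.mesh_size_coarse])
    y_axis = _graded_axis([-y_half, -R, R, y_half],
                          [p.mesh_size_coarse, p.mesh_size_fine, p.mesh_size_coarse])
    h_max = p.pec_center_thickness + p.soft_layer_thickness + p.breast_protrusion
    n_lay = max(4, int(math.ceil(h_max / p.mesh_size_fine)))
    sigma = np.linspace(0.0, 1.0, n_lay + 1)

    nx, ny, nk = x_axis.size, y_axis.size, sigma.size
    X, Y = np.meshgrid(x_axis, y_axis, indexing="ij")        # (nx, ny)
    H = p.column_height(X, Y)
    ZW = np.broadcast_to(p.z_wall(X), X.shape)
    nodes = np.empty((nx, ny, nk, 3))
    nodes[..., 0] = X[:, :, None]
    nodes[..., 1] = Y[:, :, None]
    nodes[..., 2] = ZW[:, :, None] + sigma[None, None, :] * H[:, :, None]
    node_id = np.arange(nx * ny * nk).reshape(nx, ny, nk)
    nodes_flat = nodes.reshape(-1, 3)

    # hexes -> 6 tets each
    oi, oj, ok = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), np.arange(nk - 1),
                             indexing="ij")
    origin = np.stack([oi.ravel(), oj.ravel(), ok.ravel()], axis=1)  # (n_hex, 3)
    offs = freudenthal_tets()                                         # (6, 4, 3)
    corner = origin[:, None, None, :] + offs[None, :, :, :]           # (n_hex, 6, 4, 3)
    tets = node_id[corner[..., 0], corner[..., 1], corner[..., 2]].reshape(-1, 4)

    # positive orientation
    a, b, c, d = (nodes_flat[tets[:, i]] for i in range(4))
    vol6 = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
    flip = vol6 < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()

    # ---- component labelling by centroid --------------------------------
    cen = nodes_flat[tets].mean(axis=1)
    cx, cy, cz = cen.T
    zl = cz - p.z_wall(cx)                        # height above chest wall
    rho = np.hypot(cx - xb, cy - yb)
    tpec = p.pec_thickness(rho)
    dome = p.dome_height(rho)
    h_col = tpec + p.soft_layer_thickness + dome
    dz_loc = h_col / n_lay
    inside = rho < R

    comp = np.where(zl <= tpec, "pectoralis",
                    np.where(inside, "adipose", "soft_layer")).astype("<U16")
    region = np.full(tets.shape[0], "", dtype="<U16")
    breast = inside & (comp == "adipose")

    lig_t = p.ligament_shell_thickness
    cap_sheet = np.maximum(lig_t, 0.30 * dz_loc)
    post = breast & (zl - tpec <= cap_sheet) & (cy >= yb - R / 3.0)
    ant = breast & (h_col - zl <= cap_sheet)
    comp[post] = "ligament"
    region[post] = "lig_posterior"
    comp[ant] = "ligament"
    region[ant] = "lig_anterior"

    theta = np.arctan2(cy - yb, cx - xb)
    half_w = max(lig_t, 0.35 * p.mesh_size_fine) / 2.0
    r_cb = 0.15 * R
    for k in range(8):
        phi = k * math.pi / 4.0
        band = breast & (rho >= r_cb) & (rho * np.abs(np.sin(theta - phi)) <= half_w) \
            & (np.cos(theta - phi) > 0)
        comp[band] = "ligament"
        region[band] = f"septum_L{k + 1}"

    # glandular sub-model (priority over ligament inside the breast)
    apex_zl = tpec + p.soft_layer_thickness + dome          # local top surface
    top0 = p.pec_thickness(0.0) + p.soft_layer_thickness + p.dome_height(0.0)
    body = inside & (comp != "pectoralis") & (rho <= r_cb) & (zl >= top0 - 0.35 * R) \
        & (zl <= apex_zl)
    comp[body] = "gland"
    region[body] = "circular_body"

    centers, radii = _lobe_layout(p, rng)
    z_lobe = p.pec_thickness(np.hypot(centers[:, 0] - xb, centers[:, 1] - yb)) \
        + 0.5 * (p.soft_layer_thickness
                 + p.dome_height(np.hypot(centers[:, 0] - xb, centers[:, 1] - yb)))
    lobe_xyz = np.column_stack([centers, np.zeros(len(radii))])
    lobe_xyz[:, 2] = p.z_wall(centers[:, 0]) + z_lobe
    for i, (ctr, r_l) in enumerate(zip(lobe_xyz, radii)):
        hit = np.linalg.norm(cen - ctr, axis=1) <= r_l
        hit &= comp != "pectoralis"
        if not hit.any():
            # guarantee one element per lobe at coarse mesh sizes
            order = np.argsort(np.linalg.norm(cen - ctr, axis=1))
            hit = np.zeros_like(hit)
            hit[next(j for j in order if comp[j] != "pectoralis")] = True
        comp[hit] = "gland"
        region[hit] = f"lobe_{i + 1:02d}"

    # ducts: tapering tubes from each lobe to the circular body near the
    # nipple, captured along their centerline
    cb_target = np.array([xb, yb, p.z_wall(xb) + top0 - 0.18 * R])
    d_lo, d_hi = p.duct_diameter_range
    tree_cap = max(0.5 * d_hi, 0.30 * p.mesh_size_fine)
    for i, ctr in enumerate(lobe_xyz):
        seg = cb_target - ctr
        for s in np.linspace(0.15, 0.9, 12):
            pt = ctr + s * seg
            r_duct = max((d_hi * (1 - s) + d_lo * s) / 2.0, tree_cap)
            dist = np.linalg.norm(cen - pt, axis=1)
            j = int(np.argmin(dist))
            if dist[j] <= max(r_duct, 0.8 * p.mesh_size_fine) and comp[j] == "adipose":
                comp[j] = "gland"
                region[j] = f"duct_{i + 1:02d}"

    # guarantee each septum is a populated region
    for k in range(8):
        name = f"septum_L{k + 1}"
        phi = k * math.pi / 4.0
        for r_s in np.linspace(r_cb + 2.0, 0.85 * R, 8):
            pt_xy = np.array([xb + r_s * math.cos(phi), yb + r_s * math.sin(phi)])
            h_pt = p.column_height(pt_xy[0], pt_xy[1])
            pt = np.array([pt_xy[0], pt_xy[1], p.z_wall(pt_xy[0]) + 0.55 * h_pt])
            j = int(np.argmin(np.linalg.norm(cen - pt, axis=1)))
            if comp[j] == "adipose":
                comp[j] = "ligament"
                region[j] = name

    # ---- skin shells on the outer (top) surface --------------------------
    top_nodes = node_id[:, :, -1].ravel()
    is_top = np.zeros(nodes_flat.shape[0], dtype=bool)
    is_top[top_nodes] = True
    mesh = LabelledTetMesh(
        nodes=nodes_flat, tets=tets,
        shells=np.empty((0, 3), int), shell_thickness=np.empty(0),
        element_component=comp, element_region=region, node_sets={},
        element_patch=np.repeat(np.arange(tets.shape[0] // 6), 6))
    boundary = mesh.surface_triangles()
    skin = boundary[is_top[boundary].all(axis=1)]
    # orient skin triangles with outward (+z-ish) normals
    n0, n1, n2 = (nodes_flat[skin[:, i]] for i in range(3))
    nrm = np.cross(n1 - n0, n2 - n0)
    swap = nrm[:, 2] < 0
    skin[swap, 1], skin[swap, 2] = skin[swap, 2].copy(), skin[swap, 1].copy()
    mesh.shells = skin
    mesh.shell_thickness = np.full(skin.shape[0], p.skin_thickness)

    # ---- node sets -------------------------------------------------------
    xf, yf = nodes_flat[:, 0], nodes_flat[:, 1]
    rho_n = np.hypot(xf - xb, yf - yb)
    top_mask = is_top
    breast_surface = np.flatnonzero(top_mask & (rho_n < R))
    nipple_pool = breast_surface if breast_surface.size else np.flatnonzero(top_mask)
    nipple = nipple_pool[np.argmin(np.hypot(xf[nipple_pool] - xb, yf[nipple_pool] - yb))]
    base_nodes = node_id[:, :, 0].ravel()
    clav_target = np.array([min(15.0, 0.15 * x_max), y_half])
    clav = base_nodes[np.argmin(
        np.hypot(xf[base_nodes] - clav_target[0], yf[base_nodes] - clav_target[1]))]
    mesh.node_sets = {
        "nipple": np.array([nipple]),
        "clavicle": np.array([clav]),
        "symmetry_plane": node_id[0, :, :].ravel(),
        "torso_base": np.sort(base_nodes),
        "breast_surface": np.sort(breast_surface),
    }

    try:
        mesh.validate()
    except MeshError as exc:
        raise MeshError(f"anatomy generation produced an invalid mesh: {exc}") from exc
    return mesh


def mesh_summary(mesh: LabelledTetMesh) -> dict:
    """Element and volume counts per component (for logging)."""
    out = {}
    vols = mesh.tet_volumes()
    for compname in np.unique(mesh.element_component):
        idx = mesh.element_component == compname
        out[str(compname)] = {"n_elements": int(idx.sum()),
                              "volume_mm3": float(vols[idx].sum())}
    out["skin"] = {"n_elements": int(mesh.shells.shape[0]),
                   "volume_mm3": float((mesh.shell_areas() * mesh.shell_thickness).sum())}
    out["n_nodes"] = mesh.n_nodes
    return out


# -- synthetic gait trajectory ---------------------------------------------

def build_synthetic_gait(duration: float = 3.0, sample_rate: float = 120.0,
                         half_cycle: float = 0.38, amp_y: float = 30.0,
                         amp_x: float = 10.0, noise_sd: float = 0.0,
                         seed: int = 0, ramp_cycles: float = 0.0) -> Trajectory:
    """Clavicle-like base-point displacement during running.

    The vertical (Y) component oscillates with period ``half_cycle`` so each
    half gait cycle contains one maximum (the t2 analogue) and one minimum
    (t4); the mediolateral (X) component oscillates at half that frequency
    (one sway per full gait cycle).  The t1/t3 analogues are the mid-phase
    zero crossings of the vertical waveform.  Optional additive Gaussian
    noise emulates marker jitter; ``ramp_cycles`` applies a smooth
    amplitude ramp over the first so-many half-cycles (a standing start,
    so an undamped simulation reaches near-steady cycling before the
    analysed half-cycle).
    """
    if duration <= 0 or half_cycle <= 0:
        raise ValueError("duration and half_cycle must be positive")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    disp = np.zeros((n, 3))
    disp[:, 1] = amp_y * np.sin(2.0 * math.pi * t / half_cycle)
    disp[:, 0] = amp_x * np.sin(math.pi * t / half_cycle)
    if ramp_cycles > 0:
        t_ramp = ramp_cycles * half_cycle
        env = np.where(t < t_ramp, 0.5 - 0.5 * np.cos(math.pi * t / t_ramp), 1.0)
        disp *= env[:, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        disp += rng.normal(0.0, noise_sd, size=disp.shape)
    return Trajectory(times=t, displacement=disp, sample_rate=sample_rate)
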