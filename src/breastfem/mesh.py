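"""Labelled tetrahedral + shell mesh container, validation and I/O.

The whole anatomy is a single conforming mesh: components (soft_layer,
adipose, pectoralis, ligament, gland) are per-tet labels on one node array,
so glued interfaces are shared nodes by construction.  Skin is a set of
triangular shell (membrane) elements on the outer surface with a thickness.
All lengths are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TET_COMPONENTS = ("soft_layer", "adipose", "pectoralis", "ligament", "gland")
ALL_COMPONENTS = TET_COMPONENTS + ("skin",)


class MeshError(ValueError):
    """Invalid or degenerate mesh."""


@dataclass
class LabelledTetMesh:
    """Conforming tetra + shell mesh with per-element component labels.

    Attributes
    ----------
    nodes : (n_node, 3) float array, mm
    tets : (n_tet, 4) int array, positively oriented
    shells : (n_shell, 3) int array (skin membrane triangles)
    shell_thickness : (n_shell,) float array, mm
    element_component : (n_tet,) str array, one of ``TET_COMPONENTS``
    element_region : (n_tet,) str array, finer sub-structure labels
        (``lobe_01``.., ``duct_01``.., ``circular_body``, ``septum_L1``..,
        ``lig_anterior``, ``lig_posterior``) or ``""``
    node_sets : dict of named node-index arrays
        (``nipple``, ``clavicle``, ``symmetry_plane``, ``torso_base``,
        ``breast_surface``)
    element_patch : optional (n_tet,) int array grouping tets into
        mean-dilatation patches (the solver averages the volumetric strain
        over each patch to avoid locking at nu = 0.49); -1 or None means
        each tet is its own patch
    """

    nodes: np.ndarray
    tets: np.ndarray
    shells: np.ndarray
    shell_thickness: np.ndarray
    element_component: np.ndarray
    element_region: np.ndarray
    node_sets: dict = field(default_factory=dict)
    element_patch: np.ndarray | None = None

    # -- basic quantities -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def tet_volumes(self, nodes: np.ndarray | None = None) -> np.ndarray:
        """Signed volumes of all tets (positive for a valid mesh)."""
        x = self.nodes if nodes is None else nodes
        a, b, c, d = (x[self.tets[:, i]] for i in range(4))
        return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0

    def shell_areas(self, nodes: np.ndarray | None = None) -> np.ndarray:
        x = self.nodes if nodes is None else nodes
        a, b, c = (x[self.shells[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def component_elements(self, component: str) -> np.ndarray:
        """Indices of tets carrying the given component label."""
        return np.flatnonzero(self.element_component == component)

    def component_volume(self, component: str) -> float:
        return float(self.tet_volumes()[self.component_elements(component)].sum())

    def total_volume(self) -> float:
        return float(self.tet_volumes().sum())

    # -- surfaces ---------------------------------------------------------

    def surface_triangles(self, node_set: str | None = None) -> np.ndarray:
        """Boundary triangles of the tet mesh (outward orientation not
        guaranteed).  If *node_set* is given, keep only triangles whose
        three vertices all belong to that set."""
        faces = self.tets[:, [[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]]].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        tri = faces[idx[counts == 1]]
        if node_set is not None:
            members = np.zeros(self.n_nodes, dtype=bool)
            members[self.node_sets[node_set]] = True
            tri = tri[members[tri].all(axis=1)]
        return tri

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`MeshError` on inverted tets, out-of-range indices
        or inconsistent label arrays."""
        if self.tets.size and self.tets.max() >= self.n_nodes:
            raise MeshError("tet connectivity references missing nodes")
        if self.shells.size and self.shells.max() >= self.n_nodes:
            raise MeshError("shell connectivity references missing nodes")
        vol = self.tet_volumes()
        if vol.size and vol.min() <= 0.0:
            bad = int(np.argmin(vol))
            raise MeshError(f"inverted tet {bad} (signed volume {vol[bad]:.3g} mm^3)")
        if self.element_component.shape[0] != self.n_tets:
            raise MeshError("one component label per tet required")
        unknown = set(np.unique(self.element_component)) - set(TET_COMPONENTS)
        if unknown:
            raise MeshError(f"unknown component labels: {sorted(unknown)}")
        if self.shell_thickness.shape[0] != self.shells.shape[0]:
            raise MeshError("one thickness per shell element required")
        if self.shells.size and self.shell_thickness.min() <= 0:
            raise MeshError("shell thickness must be positive")
        for name, idx in self.node_sets.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise MeshError(f"node set {name!r} out of range")

    # -- I/O ---------------------------------------------------------------

    def save_vtu(self, path, point_data: dict | None = None,
                 cell_data: dict | None = None) -> None:
        """Write the mesh (tets + shells) as an ASCII VTK XML unstructured
        grid.  The component label is always written as integer cell data
        ``component_id`` (indexing ``ALL_COMPONENTS``)."""
        comp_id = np.array([TET_COMPONENTS.index(c) for c in self.element_component],
                           dtype=int)
        skin_id = np.full(self.shells.shape[0], ALL_COMPONENTS.index("skin"), dtype=int)
        cdata = {"component_id": np.concatenate([comp_id, skin_id])}
        if cell_data:
            cdata.update(cell_data)
        write_vtu(path, self.nodes, [(10, self.tets), (5, self.shells)],
                  point_data=point_data, cell_data=cdata)

    def export_surface(self, path, node_set: str = "breast_surface") -> None:
        """Export a boundary surface (default: the breast) as STL/OBJ."""
        import trimesh

        tri = self.surface_triangles(node_set)
        trimesh.Trimesh(vertices=self.nodes, faces=tri, process=False).export(path)


_FREUDENTHAL_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def freudenthal_tets() -> np.ndarray:
    """The six tetrahedra of the unit hexahedron as (i, j, k) corner
    offsets (Freudenthal/Kuhn decomposition; identical in every cell of a
    grid, hence conforming across cell faces)."""
    tets = []
    for p in _FREUDENTHAL_PERMS:
        v = [np.zeros(3, int)]
        for ax in p:
            nxt = v[-1].copy()
            nxt[ax] = 1
            v.append(nxt)
        tets.append(np.stack(v))
    return np.stack(tets)  # (6, 4, 3)


def box_mesh(nx: int, ny: int, nz: int, lengths=(20.0, 20.0, 20.0),
             component: str = "adipose") -> LabelledTetMesh:
    """Structured tetrahedral box (single component), mainly for solver
    verification.  Node sets: ``torso_base`` (z = 0 face), ``symmetry_plane``
    (empty), ``top`` (z = Lz face)."""
    xs = np.linspace(0.0, lengths[0], nx + 1)
    ys = np.linspace(0.0, lengths[1], ny + 1)
    zs = np.linspace(0.0, lengths[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    nid = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    oi, oj, ok = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    origin = np.stack([oi.ravel(), oj.ravel(), ok.ravel()], axis=1)
    corner = origin[:, None, None, :] + freudenthal_tets()[None]
    tets = nid[corner[..., 0], corner[..., 1], corner[..., 2]].reshape(-1, 4)
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    flip = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2].copy(), tets[flip, 1].copy()
    mesh = LabelledTetMesh(
        nodes=nodes, tets=tets, shells=np.empty((0, 3), int),
        shell_thickness=np.empty(0),
        element_component=np.full(tets.shape[0], component, dtype="<U16"),
        element_region=np.full(tets.shape[0], "", dtype="<U16"),
        node_sets={"torso_base": np.flatnonzero(nodes[:, 2] < 1e-9),
                   "symmetry_plane": np.empty(0, int),
                   "top": np.flatnonzero(nodes[:, 2] > lengths[2] - 1e-9)},
        element_patch=np.repeat(np.arange(tets.shape[0] // 6), 6))
    mesh.validate()
    return mesh


def write_vtu(path, points, cells, point_data=None, cell_data=None) -> None:
    """Minimal ASCII VTU writer.

    *cells* is a list of ``(vtk_cell_type, connectivity)`` pairs
    (10 = tetra, 5 = triangle).  Data arrays may be (n,) or (n, k).
    """

    def fmt(a):
        a = np.asarray(a)
        if np.issubdtype(a.dtype, np.integer):
            return " ".join(map(str, a.ravel()))
        return " ".join(f"{v:.9g}" for v in a.ravel())

    points = np.asarray(points, dtype=float)
    conn, offs, types = [], [], []
    total = 0
    for ctype, c in cells:
        c = np.asarray(c, dtype=int)
        if c.size == 0:
            continue
        conn.append(c.ravel())
        total_prev = total
        total += c.shape[0] * c.shape[1]
        offs.append(np.arange(total_prev + c.shape[1], total + 1, c.shape[1]))
        types.append(np.full(c.shape[0], ctype, dtype=int))
    conn = np.concatenate(conn) if conn else np.empty(0, int)
    offs = np.concatenate(offs) if offs else np.empty(0, int)
    types = np.concatenate(types) if types else np.empty(0, int)

    def data_arrays(data, out):
        for name, arr in (data or {}).items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            dtype = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
            out.append(f'<DataArray type="{dtype}" Name="{name}" '
                       f'NumberOfComponents="{ncomp}" format="ascii">')
            out.append(fmt(arr))
            out.append("</DataArray>")

    out = ['<?xml version="1.0"?>',
           '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
           "<UnstructuredGrid>",
           f'<Piece NumberOfPoints="{points.shape[0]}" NumberOfCells="{types.size}">',
           "<Points>",
           '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
           fmt(points), "</DataArray>", "</Points>", "<Cells>",
           '<DataArray type="Int64" Name="connectivity" format="ascii">', fmt(conn),
           "</DataArray>",
           '<DataArray type="Int64" Name="offsets" format="ascii">', fmt(offs),
           "</DataArray>",
           '<DataArray type="UInt8" Name="types" format="ascii">', fmt(types),
           "</DataArray>", "</Cells>"]
    out.append("<PointData>")
    data_arrays(point_data, out)
    out.append("</PointData>")
    out.append("<CellData>")
    data_arrays(cell_data, out)
    out.append("</CellData>")
    out += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(out))
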