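"""Tetrahedral box meshes with fiber-tip-aware grading and dual-mesh interpolation.

Interstitial tomography solves the light-transport forward problem on a fine
"forward" mesh and the ill-posed inverse update on a coarser "reconstruction"
mesh.  This module builds graded Delaunay meshes over box domains (denser near
the optical-fiber tips, where fluence varies fastest), computes the lumped
nodal volumes that discretize volume integrals, and provides barycentric
point location / field interpolation between the two resolutions.

Coordinates are millimetres externally; nodal volumes are stored in cm^3
because optical coefficients are per cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix
from scipy.spatial import Delaunay, cKDTree

__all__ = [
    "TetMesh",
    "FiberConfig",
    "OutOfDomainError",
    "build_box_mesh",
    "nodal_volumes",
    "locate_point",
    "barycentric_coordinates",
    "interpolation_matrix",
    "interpolate_field",
    "table2_fibers",
    "table3_fibers",
    "read_fiber_csv",
    "write_fiber_csv",
    "read_vtk",
    "write_vtk",
]

MM3_PER_CM3 = 1000.0


class OutOfDomainError(ValueError):
    """Raised when a query point lies outside the mesh hull."""


@dataclass
class FiberConfig:
    """Fiber-tip coordinates (mm), one row per fiber."""

    tip_coords: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        self.tip_coords = np.asarray(self.tip_coords, dtype=float).reshape(-1, 3)
        if self.n_fibers >= 2:
            d = cKDTree(self.tip_coords).query(self.tip_coords, k=2)[0][:, 1]
            if d.min() <= 0:
                raise ValueError("fiber tips must be pairwise distinct")

    @property
    def n_fibers(self) -> int:
        return len(self.tip_coords)


@dataclass
class TetMesh:
    """Conforming tetrahedral mesh of a box domain.

    Attributes
    ----------
    node_coords : (Nn, 3) float array, mm
    elements : (Ne, 4) int array of node indices
    boundary_faces : (Nb, 3) int array (surface triangles)
    """

    node_coords: np.ndarray
    elements: np.ndarray
    boundary_faces: np.ndarray = field(default=None)
    _element_volumes_mm3: np.ndarray = field(default=None, repr=False)
    _nodal_volume_cm3: np.ndarray = field(default=None, repr=False)
    _adjacency: csr_matrix = field(default=None, repr=False)
    _node_tree: cKDTree = field(default=None, repr=False)
    _node_elements: list = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.boundary_faces is None:
            self.boundary_faces = _boundary_faces(self.elements)
        vols = element_volumes_mm3(self.node_coords, self.elements)
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(f"degenerate element {bad} with volume {vols[bad]:g} mm^3")
        self._element_volumes_mm3 = vols

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_volumes_mm3(self) -> np.ndarray:
        return self._element_volumes_mm3

    @property
    def total_volume_cm3(self) -> float:
        return float(self._element_volumes_mm3.sum()) / MM3_PER_CM3

    @property
    def nodal_volume(self) -> np.ndarray:
        """Lumped nodal volume (cm^3): one quarter of incident element volumes."""
        if self._nodal_volume_cm3 is None:
            self._nodal_volume_cm3 = nodal_volumes(self)
        return self._nodal_volume_cm3

    @property
    def node_adjacency(self) -> csr_matrix:
        """Symmetric boolean adjacency: nodes co-occurring in an element."""
        if self._adjacency is None:
            self._adjacency = _node_adjacency(self.n_nodes, self.elements)
        return self._adjacency

    def adjacent_nodes(self, i: int) -> np.ndarray:
        adj = self.node_adjacency
        return adj.indices[adj.indptr[i] : adj.indptr[i + 1]]

    # -- point location ----------------------------------------------------

    def _ensure_locator(self) -> None:
        if self._node_tree is None:
            self._node_tree = cKDTree(self.node_coords)
            incid = [[] for _ in range(self.n_nodes)]
            for e, tet in enumerate(self.elements):
                for n in tet:
                    incid[n].append(e)
            self._node_elements = [np.array(v, dtype=np.int64) for v in incid]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.node_coords.min(axis=0), self.node_coords.max(axis=0)


def element_volumes_mm3(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = nodes[elements]  # (Ne, 4, 3)
    m = p[:, 1:] - p[:, :1]
    return np.abs(np.linalg.det(m)) / 6.0


def nodal_volumes(mesh: TetMesh) -> np.ndarray:
    """Lumped nodal volumes in cm^3 (quarter of incident tet volumes)."""
    vols = np.zeros(mesh.n_nodes)
    np.add.at(vols, mesh.elements.ravel(), np.repeat(mesh.element_volumes_mm3 / 4.0, 4))
    return vols / MM3_PER_CM3


def _boundary_faces(elements: np.ndarray) -> np.ndarray:
    faces = elements[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _node_adjacency(n_nodes: int, elements: np.ndarray) -> csr_matrix:
    pairs_i, pairs_j = [], []
    idx = [(a, b) for a in range(4) for b in range(4) if a != b]
    for a, b in idx:
        pairs_i.append(elements[:, a])
        pairs_j.append(elements[:, b])
    i = np.concatenate(pairs_i)
    j = np.concatenate(pairs_j)
    adj = coo_matrix((np.ones(len(i), bool), (i, j)), shape=(n_nodes, n_nodes))
    adj = adj.tocsr()
    adj.data[:] = True
    return adj


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------


def _bcc_lattice(extent: np.ndarray, h: float) -> np.ndarray:
    """Body-centered-cubic point lattice over the box (corner + cell-center points).

    BCC Delaunay tetrahedra are near-regular, which keeps the linear-FEM
    interpolation error of steeply decaying fluence fields low; a jittered
    cubic lattice produces slivers that dominate the solution error.
    """
    axes = [np.linspace(0.0, e, max(2, int(round(e / h)) + 1)) for e in extent]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    c_axes = [(a[:-1] + a[1:]) / 2.0 for a in axes]
    centers = np.stack(np.meshgrid(*c_axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return np.vstack([grid, centers])


def _bcc_ball(radius: float, spacing: float) -> np.ndarray:
    m = int(np.ceil(radius / spacing))
    offs = np.arange(-m, m + 1) * spacing
    loc = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
    cen = np.stack(
        np.meshgrid(*[(offs[:-1] + offs[1:]) / 2.0] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    loc = np.vstack([loc, cen])
    return loc[np.linalg.norm(loc, axis=1) <= radius]


def graded_box_mesh(
    extent,
    centers=None,
    shells=None,
    h_background: float = 4.0,
    seed: int = 0,
    include_centers_as_nodes: bool = True,
) -> TetMesh:
    """Delaunay mesh of a box from a BCC lattice, refined in balls around ``centers``.

    ``shells`` is a list of (radius_mm, spacing_mm) pairs, innermost first;
    around every center the background lattice is replaced by BCC lattices of
    the given spacings.  A 5% jitter breaks co-spherical ties deterministically.
    """
    extent = np.asarray(extent, dtype=float)
    if np.any(extent <= 0):
        raise ValueError("box extent must be positive")
    rng = np.random.default_rng(seed)
    pts = _bcc_lattice(extent, h_background)
    jit = (rng.random(pts.shape) - 0.5) * 0.05 * h_background
    interior = (pts > 1e-9) & (pts < extent - 1e-9)
    clouds = [pts + jit * interior]
    if centers is not None and shells:
        centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        r_out = shells[-1][0]
        dmin = cKDTree(centers).query(clouds[0])[0]
        clouds[0] = clouds[0][dmin > r_out]
        if include_centers_as_nodes:
            clouds.append(centers)
        for c in centers:
            prev = 0.0
            for rad, sp in shells:
                loc = _bcc_ball(rad, sp)
                rr = np.linalg.norm(loc, axis=1)
                loc = loc[(rr > max(prev, 0.25 * sp))]
                cloud = c + loc + (rng.random((len(loc), 3)) - 0.5) * 0.05 * sp
                keep = np.all((cloud > 0.25 * sp) & (cloud < extent - 0.25 * sp), axis=1)
                # a ball may also clip into a neighboring center's finer shell
                dother = cKDTree(centers).query(cloud)[0] if len(centers) > 1 else None
                if dother is not None:
                    keep &= np.linalg.norm(cloud - c, axis=1) <= dother + 1e-9
                clouds.append(cloud[keep])
                prev = rad
    pts = np.unique(np.round(np.vstack(clouds), 9), axis=0)
    tri = Delaunay(pts, qhull_options="Qbb Qc Qz")
    vols = element_volumes_mm3(tri.points, tri.simplices)
    elements = tri.simplices[vols > 1e-9 * np.median(vols)]
    return TetMesh(tri.points.copy(), elements)


def build_box_mesh(
    extent,
    fiber_cfg: FiberConfig | None = None,
    target_nodes: int = 3000,
    refine_radius: float = 3.0,
    seed: int = 0,
) -> TetMesh:
    """Graded mesh of a box ``[0,ex] x [0,ey] x [0,ez]`` (mm) for a fiber layout.

    A BCC background lattice fills the box; within ``refine_radius`` of every
    fiber tip it is replaced by a lattice of half the spacing, and the tip
    coordinates themselves become mesh nodes so point sources land exactly on
    a node.  The background spacing is iterated so the final node count lands
    within a few percent of ``target_nodes``.  Deterministic for a given seed.
    """
    extent = np.asarray(extent, dtype=float)
    if np.any(extent <= 0):
        raise ValueError("box extent must be positive")
    if target_nodes < 200:
        raise ValueError("target_nodes must be >= 200")
    tips = None
    if fiber_cfg is not None and fiber_cfg.n_fibers > 0:
        tips = fiber_cfg.tip_coords
        if np.any(tips <= 0) or np.any(tips >= extent):
            bad = np.where(np.any((tips <= 0) | (tips >= extent), axis=1))[0]
            raise ValueError(
                f"fiber tip(s) {bad.tolist()} lie outside the box interior {extent.tolist()} mm"
            )

    def count(h: float) -> int:
        n = len(_bcc_lattice(extent, h))
        if tips is None:
            return n
        ball_fine = len(_bcc_ball(refine_radius, h / 2.0))
        ball_coarse = len(_bcc_ball(refine_radius, h))
        return n + len(tips) * max(ball_fine - ball_coarse, 0)

    h = (2.0 * extent.prod() / target_nodes) ** (1.0 / 3.0)
    for _ in range(6):
        n = count(h)
        if abs(n - target_nodes) / target_nodes < 0.03:
            break
        h *= (n / target_nodes) ** (1.0 / 3.0)

    shells = [(refine_radius, h / 2.0)] if tips is not None else None
    return graded_box_mesh(extent, tips, shells, h_background=h, seed=seed)


# ---------------------------------------------------------------------------
# barycentric location and interpolation
# ---------------------------------------------------------------------------


def barycentric_coordinates(tet_coords: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Weights w (sum 1) with ``w @ tet_coords == p`` for a single tetrahedron."""
    a = np.vstack([tet_coords.T, np.ones(4)])
    b = np.append(np.asarray(p, float), 1.0)
    return np.linalg.solve(a, b)


def locate_point(mesh: TetMesh, p, tol: float = 1e-9):
    """Element index and barycentric weights of point ``p`` (mm).

    Searches the elements incident to the nearest mesh nodes; raises
    :class:`OutOfDomainError` if no containing element is found.
    """
    p = np.asarray(p, dtype=float)
    mesh._ensure_locator()
    k = min(8, mesh.n_nodes)
    _, nearest = mesh._node_tree.query(p, k=k)
    nearest = np.atleast_1d(nearest)
    seen: set[int] = set()
    best = None
    for node in nearest:
        for e in mesh._node_elements[int(node)]:
            if e in seen:
                continue
            seen.add(int(e))
            w = barycentric_coordinates(mesh.node_coords[mesh.elements[e]], p)
            worst = w.min()
            if best is None or worst > best[2]:
                best = (int(e), w, worst)
            if worst >= -tol:
                return int(e), w
    # fall back to a full scan before declaring the point outside
    if best is not None and best[2] >= -1e-6:
        return best[0], best[1]
    for e in range(mesh.n_elements):
        if e in seen:
            continue
        w = barycentric_coordinates(mesh.node_coords[mesh.elements[e]], p)
        if w.min() >= -tol:
            return e, w
    raise OutOfDomainError(f"point {p.tolist()} mm is outside the mesh")


def interpolation_matrix(src_mesh: TetMesh, dst_points: np.ndarray) -> csr_matrix:
    """Sparse (Ndst x Nsrc) barycentric interpolation operator.

    Rows for points outside the source hull carry a single 1 on the nearest
    source node (constant extrapolation).
    """
    dst_points = np.asarray(dst_points, dtype=float).reshape(-1, 3)
    src_mesh._ensure_locator()
    rows, cols, vals = [], [], []
    for i, p in enumerate(dst_points):
        try:
            e, w = locate_point(src_mesh, p)
        except OutOfDomainError:
            j = int(src_mesh._node_tree.query(p)[1])
            rows.append(i)
            cols.append(j)
            vals.append(1.0)
            continue
        for j, wj in zip(src_mesh.elements[e], w):
            rows.append(i)
            cols.append(int(j))
            vals.append(float(wj))
    return csr_matrix(
        (vals, (rows, cols)), shape=(len(dst_points), src_mesh.n_nodes)
    )


def interpolate_field(src_mesh: TetMesh, values: np.ndarray, dst_points) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if len(values) != src_mesh.n_nodes:
        raise ValueError(
            f"field has {len(values)} values for a {src_mesh.n_nodes}-node mesh"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("field values must be finite")
    return interpolation_matrix(src_mesh, dst_points) @ values


# ---------------------------------------------------------------------------
# fiber tables and file formats
# ---------------------------------------------------------------------------


def read_fiber_csv(path) -> FiberConfig:
    df = pd.read_csv(path)
    return FiberConfig(df[["x_mm", "y_mm", "z_mm"]].to_numpy(float))


def write_fiber_csv(cfg: FiberConfig, path) -> None:
    df = pd.DataFrame(cfg.tip_coords, columns=["x_mm", "y_mm", "z_mm"])
    df.insert(0, "fiber", np.arange(1, cfg.n_fibers + 1))
    df.to_csv(path, index=False)


def _packaged_fibers(name: str) -> FiberConfig:
    with resources.files("dftomo.data").joinpath(name).open() as fh:
        return read_fiber_csv(fh)


def table2_fibers() -> FiberConfig:
    """The 13-fiber clinical configuration used in the simulation studies."""
    return _packaged_fibers("fibers_13.csv")


def table3_fibers() -> FiberConfig:
    """The 12-fiber configuration used in the cut-off study and experiments."""
    return _packaged_fibers("fibers_12.csv")


# -- legacy ASCII VTK unstructured grid -------------------------------------


def write_vtk(path, mesh: TetMesh, point_data: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ndftomo mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.node_coords:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {5 * ne}\n")
        for tet in mesh.elements:
            fh.write(f"4 {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("\n".join(["10"] * ne) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.12g}" for v in arr) + "\n")


def read_vtk(path) -> tuple[TetMesh, dict]:
    with open(path) as fh:
        tokens = fh.read().split()
    def find(word):
        return tokens.index(word)

    i = find("POINTS")
    n_pts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i = find("CELLS")
    n_cells = int(tokens[i + 1])
    raw = np.array(tokens[i + 3 : i + 3 + 5 * n_cells], dtype=np.int64).reshape(n_cells, 5)
    if np.any(raw[:, 0] != 4):
        raise ValueError("only tetrahedral cells are supported")
    mesh = TetMesh(pts, raw[:, 1:])
    data: dict[str, np.ndarray] = {}
    j = 0
    while True:
        try:
            j = tokens.index("SCALARS", j)
        except ValueError:
            break
        name = tokens[j + 1]
        start = tokens.index("default", j) + 1
        data[name] = np.array(tokens[start : start + n_pts], dtype=float)
        j = start
    return mesh, data
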