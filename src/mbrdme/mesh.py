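"""Discretized simulation domains and mesoscopic diffusion jump rates.

Two voxelization conventions are used, following the common practice for
reaction-diffusion master equation (RDME) solvers:

* 1D interval meshes are **cell-centered**: each voxel is one interval cell of
  width ``h`` and the voxel center is the cell midpoint.
* 3D tetrahedral meshes are **vertex-centered**: each voxel is the dual volume
  of a mesh vertex, with volume given by the lumped (row-sum) finite-element
  mass matrix.  Diffusion jump propensities between voxels are obtained from
  the piecewise-linear finite-element stiffness matrix.

All coordinates are lengths in μm; volumes are μm^d for a d-dimensional mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

INTERIOR = "interior"
BOUNDARY = "boundary"

#: raw circumradius-to-inradius ratio of the regular tetrahedron; the 3D
#: aspect metric reported by :func:`quality_check` is normalized by this, so a
#: regular tetrahedron scores exactly 1.0.
_REGULAR_TET_RADIUS_RATIO = 3.0


class MeshQualityError(RuntimeError):
    """Raised when a mesh is degenerate (inverted or zero-volume cells)."""


@dataclass
class QualityReport:
    min_volume: float
    max_volume: float
    worst_aspect: float
    worst_cell: int
    flagged: bool
    threshold: float


@dataclass
class JumpMatrix:
    """Per-species diffusion jump propensity coefficients.

    ``rates[i, j]`` is the propensity (1/s) for one molecule to jump from
    voxel ``i`` to voxel ``j``; entries are nonnegative, the diagonal is zero,
    and the sparsity pattern follows the mesh connectivity (restricted to a
    subdomain for restricted species).  ``n_clipped`` counts positive
    off-diagonal stiffness entries (non-Delaunay configurations) that were
    clipped to zero to keep propensities nonnegative.
    """

    rates: sp.csr_matrix
    subdomain: str = "all"
    n_clipped: int = 0

    @property
    def out_rates(self) -> np.ndarray:
        """Total outbound jump propensity per voxel (row sums)."""
        return np.asarray(self.rates.sum(axis=1)).ravel()


@dataclass
class Mesh:
    """A discretized domain Ω with K voxels.

    ``vertex_coords`` has shape (n_vertices, dim); ``cells`` are 2-tuples of
    vertex indices in 1D and 4-tuples in 3D.  ``boundary_facets`` (3D only)
    are surface triangles with outward unit ``facet_normals``.
    """

    dimension: int
    vertex_coords: np.ndarray
    cells: np.ndarray
    voxel_volumes: np.ndarray = field(default=None)  # type: ignore[assignment]
    voxel_centers: np.ndarray = field(default=None)  # type: ignore[assignment]
    subdomain_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    boundary_facets: np.ndarray | None = None
    facet_normals: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_volumes)

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Sorted indices of vertices on the domain boundary."""
        if self.dimension == 1:
            order = np.argsort(self.vertex_coords[:, 0])
            return np.sort(np.array([order[0], order[-1]]))
        return np.unique(self.boundary_facets)

    def voxels_in(self, subdomain: str) -> np.ndarray:
        """Indices of voxels carrying ``subdomain`` ('all' admits every voxel)."""
        if subdomain == "all":
            return np.arange(self.n_voxels)
        return np.flatnonzero(self.subdomain_labels == subdomain)

    def total_volume(self) -> float:
        return float(self.voxel_volumes.sum())

    def copy(self) -> "Mesh":
        return Mesh(
            dimension=self.dimension,
            vertex_coords=self.vertex_coords.copy(),
            cells=self.cells.copy(),
            voxel_volumes=self.voxel_volumes.copy(),
            voxel_centers=self.voxel_centers.copy(),
            subdomain_labels=self.subdomain_labels.copy(),
            boundary_facets=None if self.boundary_facets is None else self.boundary_facets.copy(),
            facet_normals=None if self.facet_normals is None else self.facet_normals.copy(),
        )


# ---------------------------------------------------------------------------
# geometry helpers


def _tet_volumes(verts: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Signed tetrahedron volumes, one per cell."""
    p = verts[cells]
    e = p[:, 1:] - p[:, :1]
    return np.linalg.det(e) / 6.0


def _tri_areas_normals(verts: np.ndarray, tris: np.ndarray):
    p = verts[tris]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    a2 = np.linalg.norm(n, axis=1)
    areas = 0.5 * a2
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = n / a2[:, None]
    return areas, normals


def _recompute_geometry(mesh: Mesh) -> None:
    """Refresh voxel volumes/centers (and facet normals) from vertex coords."""
    if mesh.dimension == 1:
        x = mesh.vertex_coords[:, 0]
        a = x[mesh.cells[:, 0]]
        b = x[mesh.cells[:, 1]]
        widths = b - a
        if np.any(widths <= 0):
            worst = int(np.argmin(widths))
            raise MeshQualityError(
                f"inverted or degenerate interval cell {worst} (width {widths[worst]:.3e})"
            )
        mesh.voxel_volumes = widths
        mesh.voxel_centers = (0.5 * (a + b))[:, None]
    else:
        vols = _tet_volumes(mesh.vertex_coords, mesh.cells)
        if np.any(vols <= 0):
            worst = int(np.argmin(vols))
            raise MeshQualityError(
                f"inverted or degenerate tetrahedron (cell {worst}, "
                f"signed volume {vols[worst]:.3e})"
            )
        lumped = np.zeros(mesh.n_vertices)
        np.add.at(lumped, mesh.cells.ravel(), np.repeat(vols / 4.0, 4))
        mesh.voxel_volumes = lumped
        mesh.voxel_centers = mesh.vertex_coords.copy()
        if mesh.boundary_facets is not None:
            _, normals = _tri_areas_normals(mesh.vertex_coords, mesh.boundary_facets)
            # orient outward: away from the facet-adjacent region's centroid
            centroid = mesh.vertex_coords.mean(axis=0)
            fc = mesh.vertex_coords[mesh.boundary_facets].mean(axis=1)
            flip = np.einsum("ij,ij->i", normals, fc - centroid) < 0
            normals[flip] *= -1.0
            mesh.facet_normals = normals


# ---------------------------------------------------------------------------
# builders


def build_interval_mesh(left: float, right: float, n_vox: int) -> Mesh:
    """Uniform cell-centered 1D mesh of ``[left, right]`` with ``n_vox`` voxels.

    Voxel 0 (the leftmost) is labeled ``boundary`` — it is the reactive end of
    the domain; all other voxels are ``interior``.
    """
    if n_vox < 1:
        raise ValueError(f"n_vox must be >= 1, got {n_vox}")
    if not right > left:
        raise ValueError(f"need right > left, got [{left}, {right}]")
    x = np.linspace(left, right, n_vox + 1)
    cells = np.column_stack([np.arange(n_vox), np.arange(1, n_vox + 1)])
    labels = np.full(n_vox, INTERIOR, dtype=object)
    labels[0] = BOUNDARY
    mesh = Mesh(
        dimension=1,
        vertex_coords=x[:, None],
        cells=cells,
        subdomain_labels=labels,
    )
    _recompute_geometry(mesh)
    return mesh


def _icosphere(n_subdiv: int):
    """Triangulated unit sphere: subdivided icosahedron, vertices normalized."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(n_subdiv):
        verts_list = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                p = verts_list[i] + verts_list[j]
                verts_list.append(p / np.linalg.norm(p))
                midpoint[key] = len(verts_list) - 1
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return verts, faces


def _split_prism(bot: np.ndarray, top: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Split a triangular prism into 3 tetrahedra with index-consistent
    quad diagonals (Dompierre et al. rule), so adjacent prisms conform."""
    v = [bot[0], bot[1], bot[2], top[0], top[1], top[2]]
    # rotate so the globally smallest index is v[0]
    imin = int(np.argmin(v))
    rot = {0: (0, 1, 2, 3, 4, 5), 1: (1, 2, 0, 4, 5, 3), 2: (2, 0, 1, 5, 3, 4),
           3: (3, 5, 4, 0, 2, 1), 4: (4, 3, 5, 1, 0, 2), 5: (5, 4, 3, 2, 1, 0)}[imin]
    w = [v[i] for i in rot]
    if min(w[1], w[5]) < min(w[2], w[4]):
        tets = [(w[0], w[1], w[2], w[5]), (w[0], w[1], w[5], w[4]), (w[0], w[4], w[5], w[3])]
    else:
        tets = [(w[0], w[1], w[2], w[4]), (w[0], w[4], w[2], w[5]), (w[0], w[4], w[5], w[3])]
    return tets


def build_ball_mesh(radius: float, resolution: int) -> Mesh:
    """Deterministic tetrahedral mesh of a ball.

    Constructed from ``resolution`` icosahedral subdivisions of the sphere and
    ``resolution + 1`` concentric shells (plus the center vertex); the layer
    between consecutive shells is filled with prisms split into tetrahedra.
    Vertices on the outer surface are labeled ``boundary``.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if resolution < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    sv, faces = _icosphere(resolution)
    n_sv = len(sv)
    n_layers = resolution + 1
    verts = [np.zeros((1, 3))]
    for k in range(1, n_layers + 1):
        verts.append(sv * (radius * k / n_layers))
    verts = np.vstack(verts)

    def shell_idx(k: int) -> np.ndarray:  # k = 1..n_layers
        return 1 + (k - 1) * n_sv + np.arange(n_sv)

    tets: list[tuple[int, int, int, int]] = []
    s1 = shell_idx(1)
    for a, b, c in faces:
        tets.append((0, s1[a], s1[b], s1[c]))
    for k in range(1, n_layers):
        lo, hi = shell_idx(k), shell_idx(k + 1)
        for a, b, c in faces:
            tets += _split_prism(np.array([lo[a], lo[b], lo[c]]), np.array([hi[a], hi[b], hi[c]]))
    cells = np.array(tets, dtype=np.int64)

    # enforce positive orientation
    vols = _tet_volumes(verts, cells)
    neg = vols < 0
    cells[neg, 1], cells[neg, 2] = cells[neg, 2].copy(), cells[neg, 1].copy()
    vols = _tet_volumes(verts, cells)
    if np.any(vols <= 0):
        raise MeshQualityError("degenerate tetrahedron produced by ball construction")

    outer = shell_idx(n_layers)
    boundary_facets = outer[faces]
    labels = np.full(len(verts), INTERIOR, dtype=object)
    labels[outer] = BOUNDARY
    mesh = Mesh(
        dimension=3,
        vertex_coords=verts,
        cells=cells,
        subdomain_labels=labels,
        boundary_facets=boundary_facets,
    )
    _recompute_geometry(mesh)
    return mesh


# ---------------------------------------------------------------------------
# jump-rate assembly


def _stiffness_tet(verts: np.ndarray, cells: np.ndarray) -> sp.csr_matrix:
    """P1 finite-element stiffness matrix on a tetrahedral mesh."""
    p = verts[cells]
    e = (p[:, 1:] - p[:, :1]).transpose(0, 2, 1)  # (n, 3, 3) columns = edges
    vols = np.abs(np.linalg.det(e)) / 6.0
    einv = np.linalg.inv(e)  # rows are gradients of barycentric coords 1..3
    g = np.empty((len(cells), 4, 3))
    g[:, 1:, :] = einv
    g[:, 0, :] = -einv.sum(axis=1)
    ke = np.einsum("nid,njd,n->nij", g, g, vols)
    rows = np.repeat(cells, 4, axis=1).ravel()
    cols = np.tile(cells, (1, 4)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(len(verts),) * 2).tocsr()


def _stiffness_tri_surface(verts: np.ndarray, tris: np.ndarray, n_verts: int) -> sp.csr_matrix:
    """P1 stiffness matrix on a triangulated surface embedded in 3D."""
    p = verts[tris]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    # orthonormal in-plane basis
    u = e1 / np.linalg.norm(e1, axis=1)[:, None]
    w = e2 - np.einsum("ij,ij->i", e2, u)[:, None] * u
    w /= np.linalg.norm(w, axis=1)[:, None]
    # 2D coords of the three corners
    x = np.zeros((len(tris), 3, 2))
    x[:, 1, 0] = np.einsum("ij,ij->i", e1, u)
    x[:, 2, 0] = np.einsum("ij,ij->i", e2, u)
    x[:, 2, 1] = np.einsum("ij,ij->i", e2, w)
    j = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)
    areas = np.abs(np.linalg.det(j)) / 2.0
    jinv = np.linalg.inv(j)
    g = np.empty((len(tris), 3, 2))
    g[:, 1:, :] = jinv
    g[:, 0, :] = -jinv.sum(axis=1)
    ke = np.einsum("nid,njd,n->nij", g, g, areas)
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_verts,) * 2).tocsr()


def _rates_from_stiffness(stiff: sp.csr_matrix, lumped: np.ndarray, diffusion: float) -> tuple[sp.csr_matrix, int]:
    s = stiff.tocoo()
    off = s.row != s.col
    rows, cols, vals = s.row[off], s.col[off], s.data[off]
    clipped = int(np.count_nonzero(vals > 1e-12 * np.abs(vals).max())) if len(vals) else 0
    rates = np.maximum(-vals, 0.0) * diffusion
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = rates / lumped[rows]
    keep = rates > 0
    mat = sp.coo_matrix((rates[keep], (rows[keep], cols[keep])), shape=stiff.shape).tocsr()
    mat.sum_duplicates()
    return mat, clipped


def assemble_jump_rates(mesh: Mesh, diffusion_constant: float, subdomain: str = "all") -> JumpMatrix:
    """Assemble the diffusion jump propensity matrix for one species.

    1D uniform meshes reduce to the classical nearest-neighbor rate D/h²; on
    nonuniform 1D meshes the two-point finite-volume rate 2D/(h_i (h_i+h_j))
    is used.  3D interior diffusion comes from the P1 stiffness matrix with
    lumped mass: rate(i→j) = D·max(−S_ij, 0)/V_i, positive off-diagonal
    entries clipped (count reported).  ``subdomain='boundary'`` on a 3D mesh
    assembles surface diffusion on the boundary triangulation with lumped
    surface areas.
    """
    if diffusion_constant < 0:
        raise ValueError(f"diffusion constant must be >= 0, got {diffusion_constant}")
    if np.any(mesh.voxel_volumes <= 0):
        raise MeshQualityError("mesh has a zero-volume voxel")
    K = mesh.n_voxels
    if diffusion_constant == 0:
        return JumpMatrix(sp.csr_matrix((K, K)), subdomain=subdomain)

    if mesh.dimension == 1:
        order = np.argsort(mesh.voxel_centers[:, 0])
        admissible = (
            np.ones(K, dtype=bool)
            if subdomain == "all"
            else mesh.subdomain_labels == subdomain
        )
        h = mesh.voxel_volumes
        rows, cols, vals = [], [], []
        for a, b in zip(order[:-1], order[1:]):
            if not (admissible[a] and admissible[b]):
                continue
            d = h[a] + h[b]
            rows += [a, b]
            cols += [b, a]
            vals += [2.0 * diffusion_constant / (h[a] * d), 2.0 * diffusion_constant / (h[b] * d)]
        return JumpMatrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(K, K)).tocsr(), subdomain=subdomain
        )

    if subdomain == "all":
        stiff = _stiffness_tet(mesh.vertex_coords, mesh.cells)
        mat, clipped = _rates_from_stiffness(stiff, mesh.voxel_volumes, diffusion_constant)
        return JumpMatrix(mat, subdomain=subdomain, n_clipped=clipped)
    if subdomain == BOUNDARY:
        if mesh.boundary_facets is None:
            raise ValueError("mesh has no boundary facets for surface diffusion")
        stiff = _stiffness_tri_surface(mesh.vertex_coords, mesh.boundary_facets, mesh.n_vertices)
        areas, _ = _tri_areas_normals(mesh.vertex_coords, mesh.boundary_facets)
        lumped = np.zeros(mesh.n_vertices)
        np.add.at(lumped, mesh.boundary_facets.ravel(), np.repeat(areas / 3.0, 3))
        lumped[lumped == 0] = np.inf  # non-boundary vertices: no surface volume
        mat, clipped = _rates_from_stiffness(stiff, lumped, diffusion_constant)
        return JumpMatrix(mat, subdomain=subdomain, n_clipped=clipped)
    # a generic interior-restricted species: volume assembly masked to the label
    stiff = _stiffness_tet(mesh.vertex_coords, mesh.cells)
    mat, clipped = _rates_from_stiffness(stiff, mesh.voxel_volumes, diffusion_constant)
    mask = (mesh.subdomain_labels == subdomain).astype(float)
    mat = sp.diags(mask) @ mat @ sp.diags(mask)
    mat.eliminate_zeros()
    return JumpMatrix(mat.tocsr(), subdomain=subdomain, n_clipped=clipped)


# ---------------------------------------------------------------------------
# motion, quality, queries


def move_mesh(mesh: Mesh, vertex_velocities: np.ndarray, tau: float) -> Mesh:
    """Forward-Euler mesh motion: every vertex displaced by velocity·tau.

    Connectivity and subdomain labels are unchanged; voxel volumes, centers
    and facet normals are recomputed.  Raises :class:`MeshQualityError` if a
    cell inverts or degenerates.
    """
    v = np.asarray(vertex_velocities, dtype=float)
    if v.shape != mesh.vertex_coords.shape:
        raise ValueError(
            f"velocity field shape {v.shape} does not match vertices {mesh.vertex_coords.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity field contains non-finite values")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    new = mesh.copy()
    new.vertex_coords = mesh.vertex_coords + tau * v
    _recompute_geometry(new)
    if np.any(new.voxel_volumes <= 0):
        worst = int(np.argmin(new.voxel_volumes))
        raise MeshQualityError(f"voxel {worst} has nonpositive volume after motion")
    return new


def _tet_aspect(verts: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Circumradius-to-inradius ratio per tet, normalized to 1 for the
    regular tetrahedron."""
    p = verts[cells]
    a = 2.0 * (p[:, 1:] - p[:, :1])
    rhs = np.einsum("nij,nij->ni", p[:, 1:], p[:, 1:]) - np.einsum(
        "nj,nj->n", p[:, 0], p[:, 0]
    )[:, None]
    center = np.linalg.solve(a, rhs[..., None])[..., 0]
    circum = np.linalg.norm(center - p[:, 0], axis=1)
    vols = np.abs(_tet_volumes(verts, cells))
    face_ids = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    total_area = np.zeros(len(cells))
    for i, j, k in face_ids:
        total_area += 0.5 * np.linalg.norm(
            np.cross(p[:, j] - p[:, i], p[:, k] - p[:, i]), axis=1
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        inradius = 3.0 * vols / total_area
        ratio = circum / inradius
    ratio[~np.isfinite(ratio)] = np.inf
    return ratio / _REGULAR_TET_RADIUS_RATIO


def quality_check(mesh: Mesh, aspect_threshold: float = 10.0) -> QualityReport:
    """Report cell-volume extrema and the worst aspect ratio.

    1D aspect = max/min voxel width (1 for a uniform mesh).  3D aspect =
    circumradius/inradius per tetrahedron normalized by the regular-simplex
    value, so a regular tetrahedron scores 1.0.  The report is flagged when
    the worst aspect exceeds ``aspect_threshold`` or any volume is <= 0; the
    caller decides whether to abort.
    """
    if mesh.dimension == 1:
        w = mesh.voxel_volumes
        vols = w
        worst = float(w.max() / w.min()) if np.all(w > 0) else np.inf
        worst_cell = int(np.argmin(w))
        aspect = worst
    else:
        vols = _tet_volumes(mesh.vertex_coords, mesh.cells)
        if np.any(vols <= 0):
            aspect = np.inf
            worst_cell = int(np.argmin(vols))
        else:
            ratios = _tet_aspect(mesh.vertex_coords, mesh.cells)
            worst_cell = int(np.argmax(ratios))
            aspect = float(ratios[worst_cell])
    flagged = bool(aspect > aspect_threshold or np.any(vols <= 0))
    return QualityReport(
        min_volume=float(np.min(vols)),
        max_volume=float(np.max(vols)),
        worst_aspect=float(aspect),
        worst_cell=worst_cell,
        flagged=flagged,
        threshold=aspect_threshold,
    )


def nearest_voxel(mesh: Mesh, point: np.ndarray, restrict_to: str = "all") -> int:
    """Index of the admissible voxel whose center is closest to ``point``.

    Ties are broken toward the lowest voxel index.  Points outside the domain
    are still assigned to the closest admissible voxel.
    """
    admissible = mesh.voxels_in(restrict_to)
    if len(admissible) == 0:
        raise ValueError(f"no voxel carries subdomain label {restrict_to!r}")
    p = np.atleast_1d(np.asarray(point, dtype=float)).reshape(-1)
    d2 = np.sum((mesh.voxel_centers[admissible] - p[None, :]) ** 2, axis=1)
    return int(admissible[int(np.argmin(d2))])
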