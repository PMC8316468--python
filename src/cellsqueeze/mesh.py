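"""Triangulated closed membrane meshes.

Cell membranes are represented as closed, outward-oriented triangle meshes
obtained by recursive subdivision of an icosahedron ("icospheres").  The mesh
stores both the current vertex positions ``X`` and the stress-free reference
positions ``X_ref`` (cells are taken to be spherical when undeformed), plus
the adjacency structure needed by the membrane finite elements:

* per-vertex one-rings (ordered, counter-clockwise seen from outside),
* per-face neighbours across each edge,
* the 12-control-vertex Loop subdivision patch of every regular element.

Geometric measures (area, enclosed volume, outward normals, discrete mean
curvature) are evaluated with standard discrete-differential-geometry
operators: divergence-theorem volume, cotangent Laplace--Beltrami mean
curvature with barycentric vertex areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriangleMesh",
    "LoopPatch",
    "make_icosphere",
    "mesh_measures",
    "loop_patch",
]


def scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """out[idx] += vals with repeated indices, via bincount (fast path)."""
    n = out.shape[0]
    if vals.ndim == 1:
        out += np.bincount(idx, weights=vals, minlength=n)
        return
    for c in range(vals.shape[1]):
        out[:, c] += np.bincount(idx, weights=vals[:, c], minlength=n)


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Closed orientable triangle mesh with a stress-free reference shape.

    Parameters
    ----------
    X : (V, 3) float array
        Current vertex positions [m].
    faces : (F, 3) int array
        Vertex index triples, counter-clockwise seen from outside.
    X_ref : (V, 3) float array, optional
        Reference (undeformed) vertex positions; defaults to a copy of ``X``.
    """

    X: np.ndarray
    faces: np.ndarray
    X_ref: np.ndarray = None  # type: ignore[assignment]
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.X_ref is None:
            self.X_ref = self.X.copy()
        else:
            self.X_ref = np.ascontiguousarray(self.X_ref, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != 3:
            raise ValueError("X must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")

    # -- counts ------------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.X.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    # -- connectivity (computed once, independent of X) --------------------

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) unique undirected edges, sorted pairs."""
        if "edges" not in self._cache:
            f = self.faces
            e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
            e = np.sort(e, axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    @property
    def valence(self) -> np.ndarray:
        """Per-vertex valence (number of incident edges)."""
        if "valence" not in self._cache:
            v = np.bincount(self.edges.ravel(),
                            minlength=self.n_vertices).astype(np.int64)
            self._cache["valence"] = v
        return self._cache["valence"]

    @property
    def face_adjacency(self) -> np.ndarray:
        """(F, 3) neighbouring face ids; entry j is across the edge opposite
        local vertex j (i.e. the edge (v_{j+1}, v_{j+2}))."""
        if "face_adjacency" not in self._cache:
            self._cache["face_adjacency"] = _face_adjacency(self.faces)
        return self._cache["face_adjacency"]

    @property
    def vertex_rings(self) -> list:
        """Ordered one-ring vertex ids per vertex (CCW from outside)."""
        if "rings" not in self._cache:
            self._cache["rings"] = _ordered_one_rings(self.faces, self.n_vertices)
        return self._cache["rings"]

    def check_manifold(self) -> None:
        """Raise ``ValueError`` if the mesh is not a closed 2-manifold."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("mesh is not a closed 2-manifold "
                             "(every edge must border exactly two faces)")

    # -- geometry (current configuration) ----------------------------------

    def face_normals(self, reference: bool = False) -> np.ndarray:
        """(F, 3) unit outward normals."""
        n = self.face_vector_areas(reference)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def face_vector_areas(self, reference: bool = False) -> np.ndarray:
        X = self.X_ref if reference else self.X
        p = X[self.faces]
        return 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def face_areas(self, reference: bool = False) -> np.ndarray:
        return np.linalg.norm(self.face_vector_areas(reference), axis=1)

    def face_centroids(self, reference: bool = False) -> np.ndarray:
        X = self.X_ref if reference else self.X
        return X[self.faces].mean(axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of incident face areas."""
        fa = self.face_areas()
        va = np.zeros(self.n_vertices)
        scatter_add(va, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return va

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit)."""
        fn = self.face_vector_areas()
        vn = np.zeros_like(self.X)
        scatter_add(vn, self.faces.ravel(), np.repeat(fn, 3, axis=0))
        return vn / np.linalg.norm(vn, axis=1, keepdims=True)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def volume(self) -> float:
        """Enclosed volume by the divergence theorem (positive when the
        orientation is outward)."""
        p = self.X[self.faces]
        return float(np.einsum("ij,ij->", p[:, 0],
                               np.cross(p[:, 1], p[:, 2])) / 6.0)

    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid."""
        fa = self.face_areas()
        return (self.face_centroids() * fa[:, None]).sum(axis=0) / fa.sum()

    def mean_curvature(self) -> np.ndarray:
        """Per-vertex signed mean curvature κ [1/m] (positive for a sphere
        with outward orientation), via the cotangent Laplacian."""
        m = cotan_mean_curvature_vector(self.X, self.faces)
        va = self.vertex_areas()
        kappa = np.linalg.norm(m, axis=1) / (2.0 * va)
        sign = np.sign(np.einsum("ij,ij->i", m, self.vertex_normals()))
        sign[sign == 0.0] = 1.0
        return kappa * sign

    def copy(self) -> "TriangleMesh":
        m = TriangleMesh(self.X.copy(), self.faces, self.X_ref.copy())
        m._cache = self._cache  # connectivity is X-independent
        return m


@dataclass
class LoopPatch:
    """Loop-subdivision control stencil of one triangular element.

    For a *regular* element (all three corner vertices of valence 6) the
    limit surface over the element is controlled by exactly 12 mesh
    vertices; ``control`` lists them in the canonical Loop ordering
    (corners first, then the ring).  Elements touching an extraordinary
    vertex (valence != 6, e.g. the 12 valence-5 icosahedron vertices of an
    icosphere) are flagged ``irregular``.
    """

    element: int
    control: np.ndarray
    irregular: bool


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array([
    [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
    [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
    [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
], dtype=float)

_ICO_FACES = np.array([
    [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
    [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
    [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
    [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
], dtype=np.int64)


def make_icosphere(radius: float, level: int, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Icosphere with ``20 * 4**level`` faces and all vertices at ``radius``.

    Each subdivision level splits every triangle in four, projecting the new
    edge-midpoint vertices back onto the sphere.  Level 5 gives the 20,480
    triangles used to discretise each membrane at full production
    resolution.

    Parameters
    ----------
    radius : float
        Sphere radius [m].
    level : int
        Number of subdivision rounds (>= 0; level 0 is the icosahedron).
    center : 3-sequence
        Sphere centre [m].
    """
    if level < 0:
        raise ValueError("subdivision level must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    V = _ICO_VERTS / np.linalg.norm(_ICO_VERTS[0])
    F = _ICO_FACES
    for _ in range(int(level)):
        V, F = _subdivide(V, F)
        V /= np.linalg.norm(V, axis=1, keepdims=True)
    X = radius * V + np.asarray(center, dtype=float)
    return TriangleMesh(X, F)


def _subdivide(V: np.ndarray, F: np.ndarray):
    """One 1:4 triangle subdivision (midpoint insertion)."""
    e = np.sort(np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]]), axis=1)
    edges, inv = np.unique(e, axis=0, return_inverse=True)
    mid = 0.5 * (V[edges[:, 0]] + V[edges[:, 1]])
    mid_idx = len(V) + np.arange(len(edges))
    m01, m12, m20 = (mid_idx[inv[i * len(F):(i + 1) * len(F)]] for i in range(3))
    newF = np.vstack([
        np.column_stack([F[:, 0], m01, m20]),
        np.column_stack([F[:, 1], m12, m01]),
        np.column_stack([F[:, 2], m20, m12]),
        np.column_stack([m01, m12, m20]),
    ])
    return np.vstack([V, mid]), newF


# ---------------------------------------------------------------------------
# connectivity helpers
# ---------------------------------------------------------------------------


def _face_adjacency(faces: np.ndarray) -> np.ndarray:
    F = faces.shape[0]
    # edge opposite local vertex j is (v_{j+1}, v_{j+2})
    adj = np.full((F, 3), -1, dtype=np.int64)
    edge_map: dict = {}
    for fi in range(F):
        for j in range(3):
            a, b = faces[fi, (j + 1) % 3], faces[fi, (j + 2) % 3]
            key = (min(a, b), max(a, b))
            if key in edge_map:
                fo, jo = edge_map.pop(key)
                adj[fi, j] = fo
                adj[fo, jo] = fi
            else:
                edge_map[key] = (fi, j)
    if edge_map:
        raise ValueError("mesh is not closed")
    return adj


def _ordered_one_rings(faces: np.ndarray, n_vertices: int) -> list:
    """Per-vertex ordered (CCW) one-ring vertex lists."""
    # successor map: around vertex v, in face (v, a, b), b follows a
    succ = [dict() for _ in range(n_vertices)]
    for tri in faces:
        for j in range(3):
            v, a, b = tri[j], tri[(j + 1) % 3], tri[(j + 2) % 3]
            succ[v][a] = b
    rings = []
    for v in range(n_vertices):
        s = succ[v]
        start = next(iter(s))
        ring = [start]
        nxt = s[start]
        while nxt != start:
            ring.append(nxt)
            nxt = s[nxt]
        rings.append(np.array(ring, dtype=np.int64))
    return rings


# ---------------------------------------------------------------------------
# discrete operators
# ---------------------------------------------------------------------------


def cotan_mean_curvature_vector(X: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Integrated mean-curvature vector m_v = 0.5 * Σ_j (cot α + cot β)(x_v − x_j).

    ``m_v / (2 A_v)`` is the discrete mean-curvature normal κ n.
    """
    m = np.zeros_like(X)
    p = X[faces]
    for k in range(3):
        # angle at corner k, opposite edge (k+1, k+2)
        i, j = (k + 1) % 3, (k + 2) % 3
        u = p[:, i] - p[:, k]
        v = p[:, j] - p[:, k]
        cot = np.einsum("ij,ij->i", u, v) / np.linalg.norm(np.cross(u, v), axis=1)
        d = X[faces[:, i]] - X[faces[:, j]]
        w = 0.5 * cot[:, None] * d
        scatter_add(m, faces[:, i], w)
        scatter_add(m, faces[:, j], -w)
    return m


# ---------------------------------------------------------------------------
# measures / Loop patches
# ---------------------------------------------------------------------------


def mesh_measures(mesh: TriangleMesh):
    """Return ``(area, volume, mean_curvature)`` of a closed mesh.

    Raises ``ValueError`` for non-manifold input.
    """
    mesh.check_manifold()
    return mesh.area(), mesh.volume(), mesh.mean_curvature()


def loop_patch(mesh: TriangleMesh, element: int) -> LoopPatch:
    """Loop-subdivision control stencil of ``element``.

    A regular element returns 12 control vertices in canonical order:
    the three element corners ``(v0, v1, v2)`` followed by the ring
    vertices: the vertex opposite edge (v1,v2), opposite (v2,v0),
    opposite (v0,v1), then the remaining six outer-ring vertices in CCW
    order starting from v0's ring.  Elements with an extraordinary corner
    vertex are flagged irregular (their ``control`` holds corners plus the
    full surrounding ring, whatever its size).
    """
    if not (0 <= element < mesh.n_faces):
        raise IndexError(f"element id {element} out of range")
    tri = mesh.faces[element]
    regular = bool(np.all(mesh.valence[tri] == 6))
    corners = list(tri)
    ring: list = []
    for j in range(3):
        # one-ring of corner j, excluding the other two corners
        r = mesh.vertex_rings[tri[j]]
        r = [int(x) for x in r if x not in corners]
        ring.append(r)
    if not regular:
        outer = sorted(set(x for r in ring for x in r))
        control = np.array(corners + outer, dtype=np.int64)
        return LoopPatch(element, control, True)
    # the three vertices opposite the element edges (shared by two rings)
    opp = []
    for j in range(3):
        a, b = (j + 1) % 3, (j + 2) % 3
        shared = [x for x in ring[a] if x in ring[b]]
        assert len(shared) == 1
        opp.append(shared[0])
    outer = sorted(set(x for r in ring for x in r) - set(opp))
    assert len(outer) == 6
    control = np.array(corners + opp + outer, dtype=np.int64)
    assert control.size == 12 and len(set(control.tolist())) == 12
    return LoopPatch(element, control, False)
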