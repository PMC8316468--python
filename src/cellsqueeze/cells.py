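"""Cell assemblies: single-membrane, nucleated, and spring-augmented models.

A cell is one closed membrane (plasma membrane) optionally enclosing a
second, stiffer membrane (the nucleus).  Two dimensionless numbers place a
cell line in parameter space: the stiffness ratio α = G_s,nuc / G_s,outer
and the karyoplasmic ratio φ = nucleus volume / cell volume (so the nucleus
radius is r φ^{1/3}).

The spring-augmented model adds a Hookean cyto- and nucleoskeleton: one
spring per outer-membrane element connecting its centroid to the nucleus
(or, after reconnection, to another outer element), and one spring per
nucleus element connecting to the opposing side of the nucleus.  Each
spring obeys F = k dL with k = E A / L0, where E is a common Young's
modulus, A the source element reference area and L0 the rest length.  When
membranes turn locally concave, springs are re-anchored by casting a ray
from the source centroid along the inward surface normal and connecting to
the first element hit, which keeps every spring inside the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriangleMesh, make_icosphere, scatter_add
from .membrane import MembraneMaterial, NodalForceSet

__all__ = [
    "NucleatedCell",
    "SpringNetwork",
    "build_cell",
    "init_spring_network",
    "spring_forces",
    "adapt_springs",
]

OUTER, NUCLEUS = 0, 1


@dataclass
class NucleatedCell:
    """One cell: outer membrane, optional nucleus, optional spring network."""

    outer: TriangleMesh
    outer_material: MembraneMaterial
    radius: float
    nucleus: TriangleMesh | None = None
    nucleus_material: MembraneMaterial | None = None
    phi: float | None = None
    springs: "SpringNetwork | None" = None

    @property
    def alpha(self) -> float | None:
        """Stiffness ratio G_s,nuc / G_s,outer."""
        if self.nucleus_material is None:
            return None
        return self.nucleus_material.G_s / self.outer_material.G_s

    @property
    def meshes(self):
        return [self.outer] if self.nucleus is None else [self.outer, self.nucleus]

    def mesh(self, tag: int) -> TriangleMesh:
        return self.outer if tag == OUTER else self.nucleus

    def volume(self) -> float:
        return self.outer.volume()

    def centroid(self) -> np.ndarray:
        return self.outer.centroid()

    def translate(self, d) -> None:
        for m in self.meshes:
            m.X = m.X + np.asarray(d, dtype=float)


@dataclass
class SpringNetwork:
    """Cyto- and nucleoskeleton springs anchored at element centroids.

    Arrays are parallel over springs; ``src_mem``/``tgt_mem`` hold the
    membrane tag (OUTER/NUCLEUS), ``src``/``tgt`` the element ids.  k is
    kept at E A_ref(src) / L0 whenever L0 is reassigned.
    """

    E: float
    src_mem: np.ndarray
    src: np.ndarray
    tgt_mem: np.ndarray
    tgt: np.ndarray
    L0: np.ndarray
    k: np.ndarray
    src_area: np.ndarray
    n_cyto: int = 0
    tension_preserving_reset: bool = True

    @property
    def n_springs(self) -> int:
        return self.src.size

    def endpoints(self, cell: NucleatedCell):
        cen = [cell.outer.face_centroids(),
               cell.nucleus.face_centroids() if cell.nucleus is not None else None]
        P0 = np.where((self.src_mem == OUTER)[:, None], cen[OUTER][self.src],
                      cen[NUCLEUS][self.src] if cen[NUCLEUS] is not None else 0.0)
        P1 = np.where((self.tgt_mem == OUTER)[:, None], cen[OUTER][self.tgt],
                      cen[NUCLEUS][self.tgt] if cen[NUCLEUS] is not None else 0.0)
        return P0, P1


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_cell(radius: float, model: str = "nucleated", phi: float = 0.38,
               outer_material: MembraneMaterial | None = None,
               nucleus_material: MembraneMaterial | None = None,
               level: int = 3, center=(0.0, 0.0, 0.0)) -> NucleatedCell:
    """Assemble a cell of the given model at a concentric initial state.

    ``model`` is 'single' (plasma membrane only) or 'nucleated'; the
    spring skeleton is attached separately by :func:`init_spring_network`.
    For a nucleated cell the nucleus radius is radius·φ^{1/3} (e.g. a
    15.6 μm cell at φ = 0.38 carries an 11.3 μm nucleus).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if outer_material is None:
        outer_material = MembraneMaterial(G_s=5e-5)
    outer = make_icosphere(radius, level, center)
    if model == "single":
        return NucleatedCell(outer, outer_material, radius)
    if model != "nucleated":
        raise ValueError(f"unknown cell model {model!r}")
    if not 0.0 < phi < 1.0:
        raise ValueError("karyoplasmic ratio must lie in (0, 1)")
    if nucleus_material is None:
        nucleus_material = MembraneMaterial(G_s=outer_material.G_s,
                                            C=outer_material.C,
                                            E_b=outer_material.E_b)
    r_nuc = radius * phi ** (1.0 / 3.0)
    nucleus = make_icosphere(r_nuc, level, center)
    return NucleatedCell(outer, outer_material, radius, nucleus,
                         nucleus_material, phi)


# ---------------------------------------------------------------------------
# ray casting (Möller–Trumbore, KD-tree candidate pruning)
# ---------------------------------------------------------------------------


def _ray_hits(origins, dirs, X, faces, t_min, exclude=None):
    """First-hit face id and distance for each ray; -1 where no hit.

    Brute-force Möller–Trumbore in ray chunks; ``exclude`` optionally masks
    one face per ray (the source element itself).
    """
    p = X[faces]
    v0, e1, e2 = p[:, 0], p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    n_rays = len(origins)
    hit = np.full(n_rays, -1, dtype=np.int64)
    t_hit = np.full(n_rays, np.inf)
    chunk = max(1, int(4e6 // max(len(faces), 1)))
    for s in range(0, n_rays, chunk):
        o = origins[s:s + chunk, None, :]
        d = dirs[s:s + chunk, None, :]
        pv = np.cross(d, e2[None])
        det = np.einsum("rfi,fi->rf", pv, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            tv = o - v0[None]
            u = np.einsum("rfi,rfi->rf", tv, pv) * inv
            qv = np.cross(tv, e1[None])
            v = np.einsum("rfi,rfi->rf", qv, d) * inv
            t = np.einsum("rfi,fi->rf", qv, e2) * inv
        eps = 1e-9
        ok = (np.abs(det) > 1e-300) & (u >= -eps) & (v >= -eps) \
            & (u + v <= 1.0 + eps) & (t > t_min[s:s + chunk, None])
        if exclude is not None:
            ok[np.arange(len(o)), exclude[s:s + chunk]] = False
        t = np.where(ok, t, np.inf)
        j = np.argmin(t, axis=1)
        tbest = t[np.arange(len(o)), j]
        found = np.isfinite(tbest)
        hit[s:s + chunk][found] = j[found]
        t_hit[s:s + chunk][found] = tbest[found]
    return hit, t_hit


def _project_to_mesh(origins, dirs, mesh: TriangleMesh, t_min,
                     guess_points=None, k=16):
    """First intersection on ``mesh``; uses a KD-tree of face centroids
    around ``guess_points`` to prune candidates, falling back to the full
    face set for rays that miss all candidates."""
    faces = mesh.faces
    if guess_points is not None and len(faces) > 4 * k:
        tree = cKDTree(mesh.face_centroids())
        _, cand = tree.query(guess_points, k=k)
        hit = np.full(len(origins), -1, dtype=np.int64)
        t_hit = np.full(len(origins), np.inf)
        # per-ray candidate subset, vectorised by treating each ray alone
        sub_faces = faces[cand]                       # (R, k, 3)
        p = mesh.X[sub_faces]                          # (R, k, 3, 3)
        v0, e1, e2 = p[:, :, 0], p[:, :, 1] - p[:, :, 0], p[:, :, 2] - p[:, :, 0]
        d = dirs[:, None, :]
        pv = np.cross(d, e2)
        det = np.einsum("rki,rki->rk", pv, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            tv = origins[:, None, :] - v0
            u = np.einsum("rki,rki->rk", tv, pv) * inv
            qv = np.cross(tv, e1)
            v = np.einsum("rki,rki->rk", qv, d) * inv
            t = np.einsum("rki,rki->rk", qv, e2) * inv
        eps = 1e-9
        ok = (np.abs(det) > 1e-300) & (u >= -eps) & (v >= -eps) \
            & (u + v <= 1.0 + eps) & (t > t_min[:, None])
        t = np.where(ok, t, np.inf)
        j = np.argmin(t, axis=1)
        tbest = t[np.arange(len(origins)), j]
        found = np.isfinite(tbest)
        hit[found] = cand[np.arange(len(origins)), j][found]
        t_hit[found] = tbest[found]
        miss = ~found
        if np.any(miss):
            h2, t2 = _ray_hits(origins[miss], dirs[miss], mesh.X, faces, t_min[miss])
            hit[miss] = h2
            t_hit[miss] = t2
        return hit, t_hit
    return _ray_hits(origins, dirs, mesh.X, faces, t_min)


# ---------------------------------------------------------------------------
# spring network
# ---------------------------------------------------------------------------


def init_spring_network(cell: NucleatedCell, E: float,
                        tension_preserving_reset: bool = True) -> SpringNetwork:
    """Initialise cyto- and nucleoskeleton springs on a concentric cell.

    Cytoskeleton: each outer-membrane element centroid is projected along
    the inward element normal onto the nucleus.  Nucleoskeleton: each
    nucleus element centroid is projected inward onto the opposing side of
    the nucleus.  Spring counts therefore equal the element counts of the
    two membranes; rest lengths are the initial lengths and
    k = E A_ref / L0.
    """
    if cell.nucleus is None:
        raise ValueError("spring network requires a nucleated cell")
    outer, nuc = cell.outer, cell.nucleus
    co = outer.face_centroids()
    no = outer.face_normals()
    eps_o = np.sqrt(outer.face_areas())
    # cytoskeleton rays: inward from the outer membrane
    guess = _radial_guess(co, nuc, +1.0)
    tgt, t = _project_to_mesh(co, -no, nuc, 1e-6 * eps_o, guess_points=guess)
    if np.any(tgt < 0):
        raise RuntimeError("cytoskeleton projection missed the nucleus "
                           f"for {int((tgt < 0).sum())} elements")
    cn = nuc.face_centroids()
    nn = nuc.face_normals()
    eps_n = np.sqrt(nuc.face_areas())
    guess_n = _radial_guess(cn, nuc, -1.0)
    tgt_n, t_n = _project_to_mesh(cn, -nn, nuc, 0.5 * eps_n, guess_points=guess_n)
    if np.any(tgt_n < 0):
        raise RuntimeError("nucleoskeleton projection missed the opposing side")

    n_out, n_nuc = outer.n_faces, nuc.n_faces
    src_mem = np.concatenate([np.full(n_out, OUTER), np.full(n_nuc, NUCLEUS)])
    src = np.concatenate([np.arange(n_out), np.arange(n_nuc)])
    tgt_mem = np.concatenate([np.full(n_out, NUCLEUS), np.full(n_nuc, NUCLEUS)])
    tgt_all = np.concatenate([tgt, tgt_n])
    # rest lengths from the actual centroid-to-centroid distances
    P1 = cn[np.concatenate([tgt, tgt_n])]
    P0 = np.concatenate([co, cn])
    L0 = np.linalg.norm(P1 - P0, axis=1)
    area = np.concatenate([outer.face_areas(reference=True),
                           nuc.face_areas(reference=True)])
    net = SpringNetwork(E=E, src_mem=src_mem, src=src, tgt_mem=tgt_mem,
                        tgt=tgt_all, L0=L0, k=E * area / L0, src_area=area,
                        n_cyto=n_out,
                        tension_preserving_reset=tension_preserving_reset)
    cell.springs = net
    return net


def _radial_guess(points, inner_mesh, sign: float):
    """Points on the inner mesh's mean sphere along (+1) or opposite (−1)
    the radial direction of ``points`` (KD-tree candidate seeds)."""
    c = inner_mesh.centroid()
    r = np.linalg.norm(inner_mesh.X - c, axis=1).mean()
    d = points - c
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return c + sign * r * d


def spring_forces(network: SpringNetwork, cell: NucleatedCell):
    """Spring force contributions on both membranes.

    Each spring pulls its two anchor elements together along the spring
    axis when stretched (F = k (L − L0)); the endpoint force is shared
    equally by the three vertices of the anchor element.  Returns
    ``(outer_force_set, nucleus_force_set)``.
    """
    P0, P1 = network.endpoints(cell)
    d = P1 - P0
    L = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(L[:, None] > 0, d / np.maximum(L, 1e-300)[:, None], 0.0)
    Fmag = network.k * (L - network.L0)
    F = Fmag[:, None] * axis          # on the source endpoint, toward target
    Go = np.zeros_like(cell.outer.X)
    Gn = np.zeros_like(cell.nucleus.X) if cell.nucleus is not None else None
    for mem_arr, elem_arr, sign in ((network.src_mem, network.src, 1.0),
                                    (network.tgt_mem, network.tgt, -1.0)):
        for mem, G, mesh_ in ((OUTER, Go, cell.outer), (NUCLEUS, Gn, cell.nucleus)):
            if G is None:
                continue
            sel = mem_arr == mem
            if not np.any(sel):
                continue
            tris = mesh_.faces[elem_arr[sel]]
            contrib = (sign / 3.0) * F[sel]
            for corner in range(3):
                scatter_add(G, tris[:, corner], contrib)
    return (NodalForceSet(Go), NodalForceSet(Gn) if Gn is not None else None)


def adapt_springs(network: SpringNetwork, cell: NucleatedCell) -> SpringNetwork:
    """Re-anchor springs to the instantaneous membrane shapes.

    Every spring's ray starts at its source element centroid and runs along
    the inward element normal; the new target is the first element hit —
    the nucleus or the outer membrane itself for cytoskeleton springs, the
    opposing nucleus side for nucleoskeleton springs.  Rays that miss
    (numerically) keep their previous connection with a warning.  Rest
    lengths are reassigned to preserve each spring's instantaneous tension
    (L0 ← L_new · L0_old / L_old), and k is recomputed as E A / L0.
    """
    if cell.nucleus is None:
        raise ValueError("spring network requires a nucleated cell")
    outer, nuc = cell.outer, cell.nucleus
    P0_old, P1_old = network.endpoints(cell)
    L_old = np.linalg.norm(P1_old - P0_old, axis=1)

    nc = network.n_cyto
    new_tgt_mem = network.tgt_mem.copy()
    new_tgt = network.tgt.copy()

    # cytoskeleton: first hit among nucleus + other outer elements
    co = outer.face_centroids()[network.src[:nc]]
    no = outer.face_normals()[network.src[:nc]]
    eps = 1e-3 * np.sqrt(outer.face_areas()[network.src[:nc]])
    Xc = np.vstack([nuc.X, outer.X])
    faces_c = np.vstack([nuc.faces, outer.faces + nuc.n_vertices])
    hit, _ = _ray_hits(co, -no, Xc, faces_c, eps,
                       exclude=nuc.n_faces + network.src[:nc])
    ok = hit >= 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} cytoskeleton rays missed; "
                      "keeping previous connections", RuntimeWarning)
    on_nuc = hit < nuc.n_faces
    new_tgt_mem[:nc][ok] = np.where(on_nuc[ok], NUCLEUS, OUTER)
    new_tgt[:nc][ok] = np.where(on_nuc[ok], hit[ok], hit[ok] - nuc.n_faces)

    # nucleoskeleton: first hit on the nucleus itself
    cn = nuc.face_centroids()[network.src[nc:]]
    nn = nuc.face_normals()[network.src[nc:]]
    eps_n = 0.5 * np.sqrt(nuc.face_areas()[network.src[nc:]])
    hit_n, _ = _ray_hits(cn, -nn, nuc.X, nuc.faces, eps_n,
                         exclude=network.src[nc:])
    ok_n = hit_n >= 0
    if not ok_n.all():
        warnings.warn(f"{int((~ok_n).sum())} nucleoskeleton rays missed; "
                      "keeping previous connections", RuntimeWarning)
    new_tgt[nc:][ok_n] = hit_n[ok_n]

    network.tgt_mem = new_tgt_mem
    network.tgt = new_tgt
    P0, P1 = network.endpoints(cell)
    L_new = np.linalg.norm(P1 - P0, axis=1)
    if network.tension_preserving_reset:
        stretch = np.where(L_old > 0, L_old / np.maximum(network.L0, 1e-300), 1.0)
        network.L0 = L_new / np.maximum(stretch, 1e-300)
    else:
        network.L0 = L_new.copy()
    network.k = network.E * network.src_area / network.L0
    return network
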