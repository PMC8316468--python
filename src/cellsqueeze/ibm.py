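"""Immersed-boundary coupling between Lagrangian membranes and the lattice.

Velocity interpolation and force spreading use the smoothed 3D Dirac delta

    δ(x − X) = (1/64 δx³) Π_i [1 + cos(π (x_i − X_i) / 2δx)]

whose support spans four Eulerian lattice points per axis.  The discrete
lattice sum of the kernel is exactly one for any membrane position
(partition of unity), so spreading conserves the total membrane force
exactly.  Near walls the part of the support that falls on solid nodes can
be dropped and the remaining weights renormalised, preserving the partition
of unity for membranes squeezing through narrow gaps.

Lattice nodes sit at voxel centres x = (i + 1/2) δx.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .lattice import FluidLattice, WALL

__all__ = [
    "DeltaKernel",
    "kernel_weight",
    "interpolate_velocity",
    "spread_forces",
    "advect_vertices",
]


@dataclass
class DeltaKernel:
    """Cosine-smoothed Dirac delta on a lattice of spacing ``dx`` [m]."""

    dx: float

    def phi(self, r):
        """Per-axis kernel (dimensionless), argument in units of δx."""
        r = np.asarray(r, dtype=float)
        return np.where(np.abs(r) < 2.0,
                        0.25 * (1.0 + np.cos(np.pi * r / 2.0)), 0.0)

    def weight(self, offset):
        """3D kernel value [1/m³] for physical offset x − X, shape (..., 3)."""
        offset = np.asarray(offset, dtype=float)
        return np.prod(self.phi(offset / self.dx), axis=-1) / self.dx**3


def kernel_weight(offset, dx: float):
    """δ(x − X) of the cosine kernel [1/m³]; zero beyond 2δx per axis."""
    return DeltaKernel(dx).weight(offset)


@njit(cache=True, fastmath=True)
def _stencil_kernel(Xs, mask_flat, ny, nz, nx, renorm):
    """Per-vertex flat node ids (V,64) and combined weights (V,64).

    ``Xs`` is X/δx (dimensionless).  Out-of-domain and (when ``renorm``)
    solid nodes get zero weight; weights are renormalised to unit sum when
    ``renorm`` is set.  Returns (flat, W, ok) where ok=False flags a vertex
    whose support left the domain with renormalisation disabled, or whose
    support carries no fluid weight at all.
    """
    V = Xs.shape[0]
    flat = np.zeros((V, 64), dtype=np.int64)
    W = np.zeros((V, 64))
    ok = np.ones(V, dtype=np.bool_)
    wa = np.empty((3, 4))
    ia = np.empty((3, 4), dtype=np.int64)
    dims = (nx, ny, nz)
    for vtx in range(V):
        for ax in range(3):
            s = Xs[vtx, ax] - 0.5
            base = int(np.floor(s)) - 1
            for j in range(4):
                i = base + j
                r = i - s
                if -2.0 < r < 2.0:
                    w = 0.25 * (1.0 + np.cos(0.5 * np.pi * r))
                else:
                    w = 0.0
                if i < 0 or i >= dims[ax]:
                    w = 0.0
                    if not renorm:
                        ok[vtx] = False
                    i = 0
                wa[ax, j] = w
                ia[ax, j] = i
        tot = 0.0
        m = 0
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    fid = (ia[0, a] * ny + ia[1, b]) * nz + ia[2, c]
                    w = wa[0, a] * wa[1, b] * wa[2, c]
                    if renorm and mask_flat[fid] == 0:
                        w = 0.0
                    flat[vtx, m] = fid
                    W[vtx, m] = w
                    tot += w
                    m += 1
        if renorm:
            if tot <= 0.0:
                ok[vtx] = False
            else:
                for m in range(64):
                    W[vtx, m] /= tot
    return flat, W, ok


@njit(cache=True, fastmath=True)
def _interp_kernel(vflat, flat, W):
    V = flat.shape[0]
    out = np.zeros((V, 3))
    for vtx in range(V):
        for m in range(64):
            w = W[vtx, m]
            if w != 0.0:
                n = flat[vtx, m]
                out[vtx, 0] += w * vflat[n, 0]
                out[vtx, 1] += w * vflat[n, 1]
                out[vtx, 2] += w * vflat[n, 2]
    return out


@njit(cache=True, fastmath=True)
def _spread_kernel(gflat, G, flat, W, inv_dx3):
    V = flat.shape[0]
    for vtx in range(V):
        for m in range(64):
            w = W[vtx, m] * inv_dx3
            if w != 0.0:
                n = flat[vtx, m]
                gflat[n, 0] += w * G[vtx, 0]
                gflat[n, 1] += w * G[vtx, 1]
                gflat[n, 2] += w * G[vtx, 2]


def _stencil(lattice: FluidLattice, X: np.ndarray, kernel: DeltaKernel,
             renormalize: bool):
    nx, ny, nz = lattice.shape
    flat, W, ok = _stencil_kernel(np.ascontiguousarray(X) / kernel.dx,
                                  lattice.mask.ravel(), ny, nz, nx,
                                  renormalize)
    if not ok.all():
        if not renormalize:
            raise ValueError("membrane vertex within kernel support of the "
                             "domain boundary (clearance error)")
        # a vertex pressed so deep into the wall that no fluid node is in
        # its support: it gets zero weights (no interpolated velocity, no
        # spread force) and the membrane tension pulls it back out
        import warnings
        warnings.warn(f"{int((~ok).sum())} vertices with kernel support "
                      "entirely inside walls", RuntimeWarning)
    return flat, W


def interpolate_velocity(lattice: FluidLattice, v: np.ndarray, X: np.ndarray,
                         kernel: DeltaKernel,
                         renormalize: bool = True) -> np.ndarray:
    """Interpolate the Eulerian velocity field to membrane vertices.

    Parameters
    ----------
    v : (nx, ny, nz, 3) array
        Eulerian velocity (any units; returned in the same units).
    X : (V, 3) array
        Vertex positions [m].
    renormalize : bool
        Drop solid-node weights and renormalise (near-wall handling);
        if False, a vertex too close to the domain edge is an error.
    """
    flat, W = _stencil(lattice, X, kernel, renormalize)
    return _interp_kernel(np.ascontiguousarray(v).reshape(-1, 3), flat, W)


def spread_forces(lattice: FluidLattice, G: np.ndarray, X: np.ndarray,
                  kernel: DeltaKernel, renormalize: bool = True,
                  out: np.ndarray | None = None) -> np.ndarray:
    """Spread nodal forces G [N] to an Eulerian body-force density [N/m³].

    The discrete sum Σ_nodes g δx³ equals Σ_vertices G exactly (partition
    of unity; preserved by near-wall renormalisation).
    """
    flat, W = _stencil(lattice, X, kernel, renormalize)
    if out is None:
        out = np.zeros(lattice.shape + (3,), dtype=np.float64)
    _spread_kernel(out.reshape(-1, 3), np.ascontiguousarray(G), flat, W,
                   1.0 / kernel.dx**3)
    return out


def advect_vertices(X: np.ndarray, V: np.ndarray, dt: float,
                    max_step: float | None = None) -> np.ndarray:
    """Forward-Euler Lagrangian update X ← X + V δt.

    Returns the new positions; if ``max_step`` (typically δx/2) is given and
    any displacement exceeds it, a ``RuntimeWarning`` is emitted.
    """
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane velocities")
    disp = V * dt
    if max_step is not None:
        dmax = float(np.linalg.norm(disp, axis=1).max())
        if dmax > max_step:
            import warnings
            warnings.warn(f"membrane displacement {dmax:.3g} m per step "
                          f"exceeds {max_step:.3g} m", RuntimeWarning)
    return X + disp
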