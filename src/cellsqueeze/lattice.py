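"""D3Q19 lattice Boltzmann solver with BGK collision and Guo forcing.

The fluid is evolved by

    f_i(x + c_i δt, t + δt) = f_i(x, t) − (1/τ)(f_i − f_i^eq) + h_i δt

with the second-order polynomial equilibrium, the forcing populations

    h_i = (1 − 1/2τ) w_i [ (c_i − v)/c_s² + (c_i·v)/c_s⁴ c_i ] · g

and the half-force-corrected macroscopic velocity

    v = (1/ρ) Σ_i c_i f_i + (δt/2ρ) g.

Walls are halfway bounce-back; open faces impose a constant density
(pressure) by an equilibrium reconstruction that copies the non-equilibrium
part from the adjacent interior node.  All lattice arithmetic is in lattice
units (δx = δt = 1, ρ0 = 1); :class:`LBMParams` maps to and from SI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "CS2", "VELOCITIES", "WEIGHTS", "OPPOSITE",
    "FLUID", "WALL", "INLET", "OUTLET",
    "LBMParams", "FluidLattice", "FluidState",
    "equilibrium", "forcing_populations", "moments",
    "collide_stream", "apply_pressure_boundaries",
]

# ---------------------------------------------------------------------------
# D3Q19 scheme
# ---------------------------------------------------------------------------

CS2 = 1.0 / 3.0  # lattice sound speed squared

VELOCITIES = np.array([
    [0, 0, 0],
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
    [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
    [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
], dtype=np.int64)

WEIGHTS = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12, dtype=np.float64)

OPPOSITE = np.array([np.nonzero((VELOCITIES == -c).all(axis=1))[0][0]
                     for c in VELOCITIES], dtype=np.int64)

# node mask codes
WALL, FLUID, INLET, OUTLET = 0, 1, 2, 3


@dataclass
class LBMParams:
    """Physical <-> lattice unit mapping.

    δt is derived from the target relaxation time via
    ν = c_s² (τ − 1/2) δx² / δt, so the lattice viscosity lands at the
    requested τ (kept in the stable working band 0.6–1.2 by default).
    """

    dx: float          # lattice spacing [m]
    dt: float          # time step [s]
    rho0: float        # physical density [kg/m^3]
    nu: float          # kinematic viscosity [m^2/s]
    tau: float         # BGK relaxation time [lattice units]

    def __post_init__(self):
        if self.tau <= 0.5:
            raise ValueError("tau must exceed 1/2")
        nu_check = CS2 * (self.tau - 0.5) * self.dx**2 / self.dt
        if abs(nu_check - self.nu) > 1e-9 * self.nu:
            raise ValueError("inconsistent (dx, dt, nu, tau)")

    @classmethod
    def from_physical(cls, dx: float, nu: float, rho0: float,
                      tau: float = 1.0) -> "LBMParams":
        dt = CS2 * (tau - 0.5) * dx**2 / nu
        return cls(dx=dx, dt=dt, rho0=rho0, nu=nu, tau=tau)

    # -- conversions -------------------------------------------------------

    @property
    def velocity_unit(self) -> float:
        """m/s per lattice velocity unit."""
        return self.dx / self.dt

    @property
    def pressure_unit(self) -> float:
        """Pa per unit of lattice c_s² ρ (i.e. p_phys = cs² Δρ_lat · this)."""
        return self.rho0 * self.dx**2 / self.dt**2

    @property
    def force_density_unit(self) -> float:
        """N/m³ per lattice force-density unit."""
        return self.rho0 * self.dx / self.dt**2

    def pressure_to_density(self, p: float) -> float:
        """Lattice density whose lattice pressure equals physical ``p`` [Pa]
        (gauge: p = 0 at ρ_lat = 1)."""
        return 1.0 + p / (CS2 * self.pressure_unit)


@dataclass
class FluidState:
    """Macroscopic density [lattice] and velocity [lattice] per node."""

    rho: np.ndarray
    v: np.ndarray


class FluidLattice:
    """Distribution functions on a masked uniform grid.

    Parameters
    ----------
    mask : (nx, ny, nz) uint8 array
        Node classification (WALL/FLUID/INLET/OUTLET).
    params : LBMParams
    periodic : 3-tuple of bool
        Per-axis periodicity of the lattice.
    """

    def __init__(self, mask: np.ndarray, params: LBMParams,
                 periodic=(False, False, False)):
        self.mask = np.ascontiguousarray(mask, dtype=np.uint8)
        self.params = params
        self.periodic = tuple(bool(p) for p in periodic)
        self.f = np.empty(mask.shape + (19,), dtype=np.float64)
        self.f[:] = WEIGHTS  # equilibrium at rho=1, v=0
        self._scratch = np.empty_like(self.f)
        self._fluid_ids = np.nonzero(self.mask.ravel() != WALL)[0]
        self._nbr = _neighbour_map(self.mask, self.periodic)

    @property
    def shape(self):
        return self.mask.shape

    def total_mass(self) -> float:
        """Σ over non-wall nodes of Σ_i f_i."""
        return float(self.f[self.mask != WALL].sum())

    def macroscopic(self, g: np.ndarray | None = None) -> FluidState:
        return moments(self, g)

    def step(self, g: np.ndarray | None = None) -> None:
        collide_stream(self, g)


# ---------------------------------------------------------------------------
# reference (vectorised numpy) operations — also used by the boundary update
# ---------------------------------------------------------------------------


def equilibrium(rho, v) -> np.ndarray:
    """Second-order Maxwell–Boltzmann equilibrium populations.

    ``rho`` has shape S, ``v`` shape S+(3,); returns S+(19,).  Satisfies
    Σ_i f_i^eq = ρ and Σ_i c_i f_i^eq = ρ v identically.
    """
    rho = np.asarray(rho, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if not (np.all(np.isfinite(rho)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite density or velocity")
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    cv = v @ VELOCITIES.T.astype(np.float64)          # S+(19,)
    vv = np.einsum("...i,...i->...", v, v)[..., None]
    return WEIGHTS * rho[..., None] * (
        1.0 + cv / CS2 + 0.5 * cv**2 / CS2**2 - 0.5 * vv / CS2)


def forcing_populations(v, g, tau: float) -> np.ndarray:
    """Guo forcing populations h_i(v, g); Σ_i h_i = 0 and
    Σ_i c_i h_i = (1 − 1/2τ) g."""
    if tau <= 0.5:
        raise ValueError("invalid relaxation time (tau must exceed 1/2)")
    v = np.asarray(v, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(g))):
        raise ValueError("non-finite input")
    c = VELOCITIES.astype(np.float64)                  # (19,3)
    cv = v @ c.T                                       # S+(19,)
    # [ (c_i − v)/cs² + (c_i·v)/cs⁴ c_i ] · g
    cg = g @ c.T
    vg = np.einsum("...i,...i->...", v, g)[..., None]
    bracket = (cg - vg) / CS2 + cv * cg / CS2**2
    return (1.0 - 0.5 / tau) * WEIGHTS * bracket


def moments(lattice: FluidLattice, g: np.ndarray | None = None) -> FluidState:
    """Density and half-force-corrected velocity (lattice units, δt = 1)."""
    f = lattice.f
    rho = f.sum(axis=-1)
    mom = f @ VELOCITIES.astype(np.float64)
    if g is not None:
        mom = mom + 0.5 * g
    fluidish = lattice.mask != WALL
    if np.any(rho[fluidish] <= 0) or not np.all(np.isfinite(rho[fluidish])):
        raise FloatingPointError("non-positive or non-finite density "
                                 "(numerical blow-up)")
    v = np.zeros_like(mom)
    v[fluidish] = mom[fluidish] / rho[fluidish][..., None]
    return FluidState(rho, v)


# ---------------------------------------------------------------------------
# numba hot loops
# ---------------------------------------------------------------------------

_CX = np.ascontiguousarray(VELOCITIES[:, 0])
_CY = np.ascontiguousarray(VELOCITIES[:, 1])
_CZ = np.ascontiguousarray(VELOCITIES[:, 2])


def _neighbour_map(mask: np.ndarray, periodic) -> np.ndarray:
    """(N, 19) flat target-node index per population, or −1 for bounce-back
    (wall neighbour or closed domain edge)."""
    shape = mask.shape
    N = mask.size
    idx = np.arange(N, dtype=np.int64).reshape(shape)
    coords = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    nbr = np.empty((N, 19), dtype=np.int64)
    for q, c in enumerate(VELOCITIES):
        ok = np.ones(shape, dtype=bool)
        tc = []
        for ax in range(3):
            cc = coords[ax] + c[ax]
            if periodic[ax]:
                cc = cc % shape[ax]
            else:
                ok &= (cc >= 0) & (cc < shape[ax])
                cc = np.clip(cc, 0, shape[ax] - 1)
            tc.append(cc)
        tgt = idx[tuple(tc)]
        ok &= mask.ravel()[tgt.ravel()].reshape(shape) != WALL
        nbr[:, q] = np.where(ok, tgt, -1).ravel()
    return nbr


@njit(cache=True, fastmath=True)
def _collide_stream_kernel(f, fnew, g, fluid, nbr, tau, w, cx, cy, cz, opp):
    """Fused BGK collision + push streaming with halfway bounce-back,
    over flattened (N, 19) populations."""
    nq = 19
    pref = 1.0 - 0.5 / tau
    inv_tau = 1.0 / tau
    post = np.empty(nq)
    for ii in range(fluid.size):
        n = fluid[ii]
        rho = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for q in range(nq):
            fq = f[n, q]
            rho += fq
            mx += cx[q] * fq
            my += cy[q] * fq
            mz += cz[q] * fq
        gx = g[n, 0]
        gy = g[n, 1]
        gz = g[n, 2]
        vx = (mx + 0.5 * gx) / rho
        vy = (my + 0.5 * gy) / rho
        vz = (mz + 0.5 * gz) / rho
        vv = vx * vx + vy * vy + vz * vz
        vg = vx * gx + vy * gy + vz * gz
        for q in range(nq):
            cvq = cx[q] * vx + cy[q] * vy + cz[q] * vz
            feq = w[q] * rho * (1.0 + 3.0 * cvq + 4.5 * cvq * cvq - 1.5 * vv)
            cgq = cx[q] * gx + cy[q] * gy + cz[q] * gz
            h = pref * w[q] * (3.0 * (cgq - vg) + 9.0 * cvq * cgq)
            post[q] = f[n, q] - (f[n, q] - feq) * inv_tau + h
        for q in range(nq):
            t = nbr[n, q]
            if t >= 0:
                fnew[t, q] = post[q]
            else:
                fnew[n, opp[q]] = post[q]


@njit(cache=True, fastmath=True)
def _moments_kernel(f, g, fluid, v_out, scale, cx, cy, cz):
    """Half-force-corrected velocity into ``v_out`` (scaled by ``scale``);
    returns (max |v|_lattice, min density) over fluid nodes."""
    vmax2 = 0.0
    rho_min = 1e300
    for ii in range(fluid.size):
        n = fluid[ii]
        rho = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for q in range(19):
            fq = f[n, q]
            rho += fq
            mx += cx[q] * fq
            my += cy[q] * fq
            mz += cz[q] * fq
        vx = (mx + 0.5 * g[n, 0]) / rho
        vy = (my + 0.5 * g[n, 1]) / rho
        vz = (mz + 0.5 * g[n, 2]) / rho
        if rho < rho_min:
            rho_min = rho
        vv = vx * vx + vy * vy + vz * vz
        if vv > vmax2:
            vmax2 = vv
        v_out[n, 0] = vx * scale
        v_out[n, 1] = vy * scale
        v_out[n, 2] = vz * scale
    return np.sqrt(vmax2), rho_min


def moments_into(lattice: FluidLattice, g: np.ndarray, v_out: np.ndarray,
                 scale: float = 1.0):
    """Fast path: write (scaled) velocity into ``v_out`` over fluid nodes;
    returns (max lattice speed, min density) for health checks."""
    N = lattice.mask.size
    return _moments_kernel(lattice.f.reshape(N, 19), g.reshape(N, 3),
                           lattice._fluid_ids, v_out.reshape(N, 3),
                           scale, _CX, _CY, _CZ)


_ZERO_G: dict = {}


def _zero_g(shape):
    if shape not in _ZERO_G:
        _ZERO_G[shape] = np.zeros(shape + (3,), dtype=np.float64)
    return _ZERO_G[shape]


def collide_stream(lattice: FluidLattice, g: np.ndarray | None = None) -> None:
    """One BGK collision + streaming step (in place).

    ``g`` is the lattice-unit body-force density field, shape (nx,ny,nz,3).
    Raises ``FloatingPointError`` on non-finite populations.
    """
    if g is None:
        g = _zero_g(lattice.shape)
    N = lattice.mask.size
    _collide_stream_kernel(lattice.f.reshape(N, 19),
                           lattice._scratch.reshape(N, 19),
                           g.reshape(N, 3), lattice._fluid_ids, lattice._nbr,
                           lattice.params.tau, WEIGHTS, _CX, _CY, _CZ,
                           OPPOSITE)
    lattice.f, lattice._scratch = lattice._scratch, lattice.f


def apply_pressure_boundaries(lattice: FluidLattice,
                              rho_in: float, rho_out: float,
                              axis: int = 0) -> None:
    """Constant-density inlet/outlet along ``axis``.

    Boundary-layer nodes (mask INLET/OUTLET) are rebuilt as
    f = f^eq(ρ_bc, v_adj) + [f_adj − f^eq(ρ_adj, v_adj)], copying the
    non-equilibrium part from the adjacent interior node.
    """
    for code, rho_bc, off in ((INLET, rho_in, 1), (OUTLET, rho_out, -1)):
        sel = np.nonzero(lattice.mask == code)
        if sel[0].size == 0:
            raise ValueError("mask has no inlet/outlet nodes")
        adj = list(sel)
        adj[axis] = adj[axis] + off
        adj = tuple(adj)
        if np.any(lattice.mask[adj] == WALL):
            raise ValueError("inlet/outlet face intersects the wall mask")
        f_adj = lattice.f[adj]
        rho_adj = f_adj.sum(axis=-1)
        v_adj = (f_adj @ VELOCITIES.astype(np.float64)) / rho_adj[:, None]
        feq_adj = equilibrium(rho_adj, v_adj)
        feq_bc = equilibrium(np.full(rho_adj.shape, rho_bc), v_adj)
        lattice.f[sel] = feq_bc + (f_adj - feq_adj)
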