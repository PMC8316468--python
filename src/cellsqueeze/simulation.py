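"""Coupled fluid–membrane time stepping.

One :class:`Simulation` owns a masked D3Q19 lattice, any number of cells,
and a boundary driving mode: a constant body force (periodic duct bench),
fixed inlet/outlet pressures, or pressure coupling to the lumped-parameter
channel model through the PI controller.

The step sequence is the classic explicit IBM loop:

1. membrane + spring forces at the current vertex positions [N],
2. spread to the Eulerian body-force density and convert to lattice units,
3. LBM collide + stream with Guo forcing; re-impose pressure boundaries,
4. macroscopic velocity, interpolate to vertices, forward-Euler advection,
5. measure the inlet-plane flow rate and let the PI controller set the
   next inlet pressure from the lumped pressure drops.

All cell state is kept in SI units; only the lattice works in lattice
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import (FluidLattice, LBMParams, CS2, WALL,
                      apply_pressure_boundaries, moments_into)
from .ibm import DeltaKernel, interpolate_velocity, spread_forces, advect_vertices
from .membrane import membrane_forces
from .cells import NucleatedCell, spring_forces, adapt_springs
from .lumped import CoupledBoundaryState, update_inlet_pressure

__all__ = ["Simulation", "SimulationDiagnostics"]


@dataclass
class SimulationDiagnostics:
    step: int = 0
    time: float = 0.0
    max_mach: float = 0.0
    cell_volume_drift: list = field(default_factory=list)
    inlet_pressure: float = float("nan")
    flow_rate: float = float("nan")


class Simulation:
    """Immersed-boundary LBM simulation of cells in a device.

    Parameters
    ----------
    mask : (nx, ny, nz) uint8
        Node classification.
    params : LBMParams
        Unit mapping (δx, δt, τ, ρ0, ν).
    cells : list[NucleatedCell]
        Cells with meshes in physical coordinates (metres, same frame as
        the mask voxels: node centres at (i+1/2) δx).
    body_force : (3,) array, optional
        Constant physical body-force density [N/m³] on all fluid nodes.
    pressures : (p_in, p_out) tuple, optional
        Fixed gauge pressures [Pa] at the inlet/outlet faces.
    coupling : CoupledBoundaryState, optional
        Lumped-model coupling; overrides fixed pressures for the inlet.
    """

    def __init__(self, mask, params: LBMParams, cells=(),
                 periodic=(False, False, False), body_force=None,
                 pressures=None, coupling: CoupledBoundaryState | None = None,
                 renormalize_kernel: bool = True, adapt_every: int = 100,
                 flow_plane: int = 2, low_mach_limit: float = 0.1,
                 check_every: int = 25, ramp_steps: int = 2000):
        self.lattice = FluidLattice(mask, params, periodic)
        self.params = params
        self.cells = list(cells)
        self.kernel = DeltaKernel(params.dx)
        self.renormalize = renormalize_kernel
        self.adapt_every = adapt_every
        self.flow_plane = flow_plane
        self.low_mach_limit = low_mach_limit
        self.check_every = check_every
        self.coupling = coupling
        self.pressures = pressures
        self.ramp_steps = int(ramp_steps)
        if coupling is not None:
            self._p_res_in_base = coupling.p_reservoir_in
        elif pressures is not None:
            self._p_base = tuple(pressures)
        self.body_force = None if body_force is None else np.asarray(body_force)
        self.diag = SimulationDiagnostics()
        self._g_phys = np.zeros(mask.shape + (3,))
        self._g_lat = np.zeros(mask.shape + (3,))
        self._v_phys = np.zeros(mask.shape + (3,))
        self._cell_volume0 = [c.volume() for c in self.cells]
        if coupling is not None:
            self._rho_out = params.pressure_to_density(coupling.p_outlet)
        elif pressures is not None:
            self._rho_in = params.pressure_to_density(pressures[0])
            self._rho_out = params.pressure_to_density(pressures[1])

    # -- forces ------------------------------------------------------------

    def _cell_forces(self):
        """Per-cell, per-membrane nodal forces [N] at current positions."""
        out = []
        for cell in self.cells:
            fo = membrane_forces(cell.outer, cell.outer_material)
            fn = None
            if cell.nucleus is not None:
                fn = membrane_forces(cell.nucleus, cell.nucleus_material)
            if cell.springs is not None:
                so, sn = spring_forces(cell.springs, cell)
                fo = fo + so
                if fn is not None and sn is not None:
                    fn = fn + sn
            out.append((fo, fn))
        return out

    # -- stepping ----------------------------------------------------------

    def step(self, n: int = 1) -> None:
        for _ in range(n):
            self._step_once()

    def _step_once(self) -> None:
        p = self.params
        lat = self.lattice
        g = self._g_phys
        g[:] = 0.0
        if self.body_force is not None:
            g[lat.mask != WALL] = self.body_force
        for cell, (fo, fn) in zip(self.cells, self._cell_forces()):
            spread_forces(lat, fo.G, cell.outer.X, self.kernel,
                          self.renormalize, out=g)
            if fn is not None:
                spread_forces(lat, fn.G, cell.nucleus.X, self.kernel,
                              self.renormalize, out=g)
        g_lat = np.divide(g, p.force_density_unit, out=self._g_lat)
        lat.step(g_lat)
        # soft start: ramp the driving pressure over the first steps
        # (pressure-driven modes only)
        if self.ramp_steps > 0 and (self.coupling is not None
                                    or self.pressures is not None):
            ramp = min(1.0, (self.diag.step + 1) / self.ramp_steps)
        else:
            ramp = 1.0
        if self.coupling is not None:
            c = self.coupling
            # the controller tracks the ramped reservoir; p_inlet follows
            c.p_reservoir_in = c.p_reservoir_out \
                + ramp * (self._p_res_in_base - c.p_reservoir_out)
            apply_pressure_boundaries(
                lat, p.pressure_to_density(c.p_inlet), self._rho_out)
        elif self.pressures is not None:
            p_in = self._p_base[1] + ramp * (self._p_base[0] - self._p_base[1])
            apply_pressure_boundaries(lat, p.pressure_to_density(p_in),
                                      self._rho_out)

        vmax_lat, rho_min = moments_into(lat, g_lat, self._v_phys,
                                         scale=p.velocity_unit)
        # cells are held in place (acting as obstacles) until the driving
        # pressure has finished ramping, then released into developed flow
        advect = ramp >= 1.0
        for cell in self.cells if advect else ():
            for mesh_ in cell.meshes:
                V = interpolate_velocity(lat, self._v_phys, mesh_.X,
                                         self.kernel, self.renormalize)
                mesh_.X = advect_vertices(mesh_.X, V, p.dt)
            if (cell.springs is not None and self.adapt_every
                    and (self.diag.step + 1) % self.adapt_every == 0):
                adapt_springs(cell.springs, cell)

        if self.coupling is not None:
            Q = self.flow_rate()
            update_inlet_pressure(self.coupling, Q)
            self.diag.inlet_pressure = self.coupling.p_inlet
            self.diag.flow_rate = Q

        self.diag.step += 1
        self.diag.time = self.diag.step * p.dt
        if self.diag.step % self.check_every == 0:
            self._health_check(vmax_lat, rho_min)

    def flow_rate(self) -> float:
        """Volumetric flow rate [m³/s] through the reference cross plane
        (from the velocity field of the current step)."""
        ux = self._v_phys[self.flow_plane, :, :, 0]
        live = self.lattice.mask[self.flow_plane] != WALL
        return float(ux[live].sum()) * self.params.dx**2

    def _health_check(self, vmax_lat: float, rho_min: float) -> None:
        self.diag.max_mach = vmax_lat / np.sqrt(CS2)
        if not np.isfinite(vmax_lat) or rho_min <= 0.0:
            raise FloatingPointError(
                f"numerical blow-up at step {self.diag.step} "
                f"(min density {rho_min:.3g})")
        if self.diag.max_mach > self.low_mach_limit:
            raise FloatingPointError(
                f"low-Mach guard tripped at step {self.diag.step}: "
                f"max|v|/c_s = {self.diag.max_mach:.3f}")

    # -- measurements ------------------------------------------------------

    def cell_volume_drift(self, i: int = 0) -> float:
        """Relative enclosed-volume drift of cell ``i`` since t = 0."""
        return self.cells[i].volume() / self._cell_volume0[i] - 1.0

    def cell_extent(self, i: int = 0):
        """(leading, trailing, centroid) axial positions of cell ``i`` [m]."""
        x = self.cells[i].outer.X[:, 0]
        return float(x.max()), float(x.min()), float(x.mean())
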