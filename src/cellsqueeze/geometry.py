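"""Voxelised microfluidic device geometries.

Two devices are provided:

* the constriction device — a straight main channel (20 μm × 15 μm section)
  with a centred rectangular constriction (6 μm × 15 μm section).  Only the
  neighbourhood of the constriction is simulated in 3D (25 μm of
  constriction plus 50 μm of inlet/outlet); the remaining 950 μm of main
  channel and 25 μm of constriction are handed to the lumped model.
* the ratchet funnel — a channel whose width tapers linearly down to a pore
  of width w ∈ {6.9, 7.8, 8.8, 9.8} μm and opens again, used for
  threshold-pressure measurements.

Masks label nodes WALL/FLUID/INLET/OUTLET; the flow axis is x, the
channel width lies along y and the depth along z.  Node centres sit at
(i + 1/2) δx, and a channel of nominal width W is represented by the voxel
layers whose centres fall strictly inside it, so the halfway bounce-back
wall planes land on the nominal faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import WALL, FLUID, INLET, OUTLET

__all__ = [
    "ConstrictionDevice",
    "RatchetFunnel",
    "build_constriction_mask",
    "build_funnel_mask",
    "fluid_fraction",
    "check_watertight",
]

UM = 1e-6


@dataclass
class ConstrictionDevice:
    """Constriction-device geometry (all lengths in metres).

    Defaults reproduce the modeled portion of the microfluidic constriction
    device: 20 × 15 μm main channel, 6 × 15 μm constriction, 25 μm of
    constriction and 50 μm of inlet+outlet simulated in 3D; the full device
    carries 950 μm of main channel and another 25 μm of constriction in the
    lumped model.
    """

    main_width: float = 20 * UM        # y
    depth: float = 15 * UM             # z
    constriction_width: float = 6 * UM
    constriction_length: float = 25 * UM
    inlet_length: float = 25 * UM
    outlet_length: float = 25 * UM
    lumped_main_length: float = 950 * UM
    lumped_constriction_length: float = 25 * UM

    def __post_init__(self):
        if min(self.main_width, self.depth, self.constriction_width,
               self.constriction_length, self.inlet_length,
               self.outlet_length) <= 0:
            raise ValueError("all device dimensions must be positive")
        if self.constriction_width >= self.main_width:
            raise ValueError("constriction must be narrower than the main channel")

    @property
    def length(self) -> float:
        return self.inlet_length + self.constriction_length + self.outlet_length

    @property
    def entrance_x(self) -> float:
        """Axial position of the constriction entrance plane."""
        return self.inlet_length

    @property
    def exit_x(self) -> float:
        return self.inlet_length + self.constriction_length

    def width_at(self, x):
        """Channel width (y extent) at axial position x."""
        x = np.asarray(x, dtype=float)
        inside = (x >= self.entrance_x) & (x < self.exit_x)
        return np.where(inside, self.constriction_width, self.main_width)

    def analytic_fluid_volume(self) -> float:
        return self.depth * (self.main_width * (self.inlet_length
                                                + self.outlet_length)
                             + self.constriction_width * self.constriction_length)


@dataclass
class RatchetFunnel:
    """Funnel geometry: linear taper from the inlet width down to the pore.

    The taper half-angle and the depth are not dictated by the constriction
    device; defaults are a 10° half-angle and the 15 μm depth, both
    configurable.  Downstream of the pore throat the channel opens by the
    same taper back to the outlet width.
    """

    pore_width: float = 7.8 * UM
    inlet_width: float = 20 * UM
    depth: float = 15 * UM
    taper_half_angle_deg: float = 10.0          # gentle approach side
    outlet_taper_half_angle_deg: float = 45.0   # steep back side (ratchet)
    throat_length: float = 2 * UM
    inlet_length: float = 12 * UM
    outlet_length: float = 12 * UM

    def __post_init__(self):
        if self.pore_width <= 0:
            raise ValueError("pore width must be positive")
        if self.pore_width >= self.inlet_width:
            raise ValueError("pore must be narrower than the funnel inlet")

    @property
    def taper_length(self) -> float:
        half_gap = 0.5 * (self.inlet_width - self.pore_width)
        return half_gap / np.tan(np.deg2rad(self.taper_half_angle_deg))

    @property
    def outlet_taper_length(self) -> float:
        half_gap = 0.5 * (self.inlet_width - self.pore_width)
        return half_gap / np.tan(np.deg2rad(self.outlet_taper_half_angle_deg))

    @property
    def waist_x(self) -> float:
        """Axial position of the pore waist centre."""
        return self.inlet_length + self.taper_length + 0.5 * self.throat_length

    @property
    def length(self) -> float:
        return (self.inlet_length + self.taper_length + self.throat_length
                + self.outlet_taper_length + self.outlet_length)

    def padded(self, total_length: float) -> "RatchetFunnel":
        """Copy with inlet/outlet extended equally to ``total_length``
        (funnels with different pores compared on a common domain)."""
        extra = total_length - self.length
        if extra < -1e-15:
            raise ValueError("total_length shorter than the funnel")
        from dataclasses import replace
        return replace(self, inlet_length=self.inlet_length + extra / 2,
                       outlet_length=self.outlet_length + extra / 2)

    def width_at(self, x):
        x = np.asarray(x, dtype=float)
        x1 = self.inlet_length
        x2 = x1 + self.taper_length
        x3 = x2 + self.throat_length
        x4 = x3 + self.outlet_taper_length
        slope_in = np.tan(np.deg2rad(self.taper_half_angle_deg))
        slope_out = np.tan(np.deg2rad(self.outlet_taper_half_angle_deg))
        w = np.full(x.shape, self.inlet_width)
        w = np.where((x >= x1) & (x < x2),
                     self.inlet_width - 2 * slope_in * (x - x1), w)
        w = np.where((x >= x2) & (x < x3), self.pore_width, w)
        w = np.where((x >= x3) & (x < x4),
                     self.pore_width + 2 * slope_out * (x - x3), w)
        return np.clip(w, self.pore_width, self.inlet_width)


# ---------------------------------------------------------------------------
# voxelisation
# ---------------------------------------------------------------------------


def _channel_mask(length, width_fn, depth, dx, min_gap_nodes, open_ends=True):
    nx = int(round(length / dx))
    # even fluid-node counts centre the channel on a halfway plane, so
    # bounce-back walls land on the nominal channel faces
    wmax = np.max(width_fn(np.linspace(0, length, 256)))
    ny = 2 * int(np.ceil(wmax / dx / 2.0)) + 2
    nz = 2 * int(np.ceil(depth / dx / 2.0)) + 2
    mask = np.full((nx, ny, nz), WALL, dtype=np.uint8)
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dx - 0.5 * ny * dx   # centred on axis
    zc = (np.arange(nz) + 0.5) * dx - 0.5 * nz * dx
    w = width_fn(xc)
    inside_y = np.abs(yc[None, :]) < 0.5 * w[:, None] - 1e-12
    inside_z = np.abs(zc) < 0.5 * depth - 1e-12
    mask[inside_y[:, :, None] & inside_z[None, None, :]] = FLUID
    gap = inside_y.sum(axis=1).min()
    if gap < min_gap_nodes:
        import warnings
        warnings.warn(f"only {gap} nodes across the narrowest gap "
                      f"(< {min_gap_nodes}); resolution is marginal",
                      RuntimeWarning)
    if open_ends:
        mask[0][mask[0] == FLUID] = INLET
        mask[-1][mask[-1] == FLUID] = OUTLET
    return mask


def build_constriction_mask(device: ConstrictionDevice, dx: float,
                            min_gap_nodes: int = 8) -> np.ndarray:
    """Voxelise the constriction device on a lattice of spacing ``dx``.

    The mask is symmetric about the channel axis and its ends are labelled
    INLET/OUTLET across the main-channel cross-section.
    """
    return _channel_mask(device.length, device.width_at, device.depth, dx,
                         min_gap_nodes)


def build_funnel_mask(funnel: RatchetFunnel, dx: float,
                      min_gap_nodes: int = 8) -> np.ndarray:
    """Voxelise the ratchet funnel on a lattice of spacing ``dx``."""
    return _channel_mask(funnel.length, funnel.width_at, funnel.depth, dx,
                         min_gap_nodes)


def fluid_fraction(mask: np.ndarray) -> float:
    return float((mask != WALL).mean())


def check_watertight(mask: np.ndarray) -> bool:
    """True if no fluid node touches the domain exterior except through the
    inlet/outlet end faces (checked over the 6-neighbourhood)."""
    interior = mask[1:-1]
    for ax, n in ((1, mask.shape[1]), (2, mask.shape[2])):
        lo = np.take(interior, 0, axis=ax)
        hi = np.take(interior, n - 1, axis=ax)
        if np.any(lo != WALL) or np.any(hi != WALL):
            return False
    return True
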