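"""Lumped-parameter channels and PI-controlled pressure coupling.

Channel segments outside the 3D simulation box are reduced to Boussinesq's
series solution for pressure-driven flow through a rectangular duct of
cross-section h × l:

    G = Q [ h³l/(12μ) − (16h⁴/π⁵μ) Σ_n (1/(2n−1)⁵) (cosh(β_n l)−1)/sinh(β_n l) ]⁻¹

with β_n = (2n−1)π/h.  The (cosh−1)/sinh factor is evaluated as
tanh(β_n l/2), which is exact and overflow-free.  The pressure gradient is
strictly linear in the flow rate, so each segment is a hydraulic resistance
R = G·length/Q.

The 3D domain is driven by inlet/outlet pressures.  At every step the flow
rate measured in the 3D model sets the lumped pressure drops, and a
proportional–integral controller tracks the resulting target inlet pressure
to keep the coupling stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LumpedChannelSegment",
    "PIController",
    "CoupledBoundaryState",
    "boussinesq_coefficient",
    "boussinesq_gradient",
    "update_inlet_pressure",
]


def boussinesq_coefficient(h: float, l: float, mu: float,
                           n_terms: int = 120) -> float:
    """Q/G for a rectangular duct [m³/s per Pa/m].

    The series is truncated at ``n_terms``; terms fall off as (2n−1)⁻⁵, so
    the default 120 terms leave a tail below 1e-10 of the sum for any
    aspect ratio.
    """
    if h <= 0 or l <= 0 or mu <= 0:
        raise ValueError("h, l and mu must be positive")
    n = np.arange(1, n_terms + 1)
    beta = (2 * n - 1) * np.pi / h
    series = np.sum(np.tanh(beta * l / 2.0) / (2 * n - 1) ** 5)
    return h**3 * l / (12.0 * mu) - 16.0 * h**4 / (np.pi**5 * mu) * series


@dataclass
class LumpedChannelSegment:
    """One un-simulated rectangular channel segment.

    Parameters
    ----------
    h, l : float
        Cross-section dimensions [m] (β_n = (2n−1)π/h; either assignment of
        the physical width/depth gives the same flow rate).
    length : float
        Segment length [m].
    mu : float
        Dynamic viscosity [Pa s].
    """

    h: float
    l: float
    length: float
    mu: float
    n_terms: int = 120

    def __post_init__(self):
        if min(self.h, self.l, self.length, self.mu) <= 0:
            raise ValueError("segment dimensions and viscosity must be positive")
        self._coef = boussinesq_coefficient(self.h, self.l, self.mu,
                                            self.n_terms)

    def gradient(self, Q: float) -> float:
        """Pressure gradient G [Pa/m] sustaining flow rate Q [m³/s]."""
        return boussinesq_gradient(Q, self)

    def pressure_drop(self, Q: float) -> float:
        """ΔP = G · length [Pa]."""
        return self.gradient(Q) * self.length

    @property
    def resistance(self) -> float:
        """Hydraulic resistance ΔP/Q [Pa s/m³]."""
        return self.length / self._coef


def boussinesq_gradient(Q: float, segment: LumpedChannelSegment) -> float:
    """Pressure gradient G [Pa/m] for flow rate Q [m³/s] (linear in Q)."""
    if not np.isfinite(Q):
        raise ValueError("flow rate must be finite")
    return Q / segment._coef


@dataclass
class PIController:
    """Discrete proportional–integral tracker.

    ``update`` moves the held output toward the setpoint:
    out += K_p e + K_i Σe with e = setpoint − out.  With zero error history
    and K_p = 1 the output equals the feed-forward (setpoint) term.

    Default gains come from step-response measurements of the coupled
    loop on the constriction device: the 3D domain responds to pressure
    changes over its viscous relaxation time (hundreds of steps at desk
    scale) and the lumped-to-3D resistance ratio is ~3, so aggressive
    gains oscillate.  K_p = 1×10⁻³ per step settles the no-cell budget to
    <0.1 % within ~7×10³ steps with a well-damped transient.
    """

    K_p: float = 1e-3
    K_i: float = 1e-6
    integral: float = 0.0
    output: float = 0.0
    initialized: bool = False

    def reset(self, output: float = 0.0) -> None:
        self.integral = 0.0
        self.output = output
        self.initialized = True

    def update(self, setpoint: float) -> float:
        if not self.initialized:
            self.reset(setpoint)
            return self.output
        e = setpoint - self.output
        self.integral += e
        self.output += self.K_p * e + self.K_i * self.integral
        return self.output


@dataclass
class CoupledBoundaryState:
    """Reservoir pressures and the instantaneous 3D boundary pressures.

    The reservoir-to-reservoir difference (0.9 psi for the constriction
    device) is split between the lumped segments and the 3D domain; only
    the inlet is actively controlled, the outlet is pinned at the reservoir
    outlet pressure.
    """

    p_reservoir_in: float
    p_reservoir_out: float
    segments: list = field(default_factory=list)
    controller: PIController = field(default_factory=PIController)
    p_inlet: float = None  # type: ignore[assignment]
    p_outlet: float = None  # type: ignore[assignment]
    Q: float = 0.0
    q_alpha: float = 0.02   # EMA smoothing of the measured flow rate

    def __post_init__(self):
        if self.p_inlet is None:
            self.p_inlet = self.p_reservoir_in
        if self.p_outlet is None:
            self.p_outlet = self.p_reservoir_out
        if not self.controller.initialized:
            self.controller.reset(self.p_inlet)

    def initialize_feed_forward(self, R_3d: float) -> None:
        """Start the inlet pressure at the no-cell series-resistance split.

        ``R_3d`` is an estimate of the simulated region's hydraulic
        resistance [Pa s/m³]; avoids the start-up transient of applying the
        full reservoir difference across the 3D domain alone.
        """
        R_lumped = sum(seg.resistance for seg in self.segments)
        dp = self.p_reservoir_in - self.p_reservoir_out
        Q0 = dp / (R_lumped + R_3d)
        self.p_inlet = self.p_reservoir_out + R_3d * Q0
        self.Q = Q0
        self.controller.reset(self.p_inlet)


def update_inlet_pressure(state: CoupledBoundaryState, Q_measured: float) -> float:
    """Advance the coupled boundary one step.

    The target inlet pressure is the reservoir inlet pressure minus the
    lumped drops at the measured flow rate; the PI controller tracks it and
    the result is clamped between the outlet and reservoir-inlet pressures
    (a clamp is reported via the returned value only).
    """
    state.Q = (1.0 - state.q_alpha) * state.Q + state.q_alpha * Q_measured
    drop = sum(seg.pressure_drop(state.Q) for seg in state.segments)
    target = state.p_reservoir_in - drop
    p = state.controller.update(target)
    p_clamped = float(np.clip(p, state.p_outlet, state.p_reservoir_in))
    if p_clamped != p:
        # anti-windup: discard the integral accumulated while saturated
        state.controller.output = p_clamped
        state.controller.integral -= target - p
    state.p_inlet = p_clamped
    return state.p_inlet
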