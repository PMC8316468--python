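"""Experiment drivers: constriction passage, funnel threshold pressure,
stiffness sensitivity, and the α–φ calibration procedure.

Passage runs drive one cell through the constriction device under the
reservoir pressure difference (0.9 psi for the devices modelled here),
with the un-simulated channel lengths handled by the lumped model.  The
passage time τ_p through the constriction splits into an entry phase
(first contact of the leading vertex with the entrance plane until the
trailing vertex crosses it) and a transit phase (until the leading vertex
crosses the exit plane).

Threshold runs determine, by bisection over the applied pressure
difference, the minimum quasi-static ΔP for a cell to pass a funnel pore
of width w.

Calibration inverts passage-time data: for each stiffness ratio α, the
karyoplasmic ratio φ*(α) reproducing a target passage time is found by
monotone interpolation of log τ_p vs φ (passage time grows exponentially
with φ); loci from several cell sizes are then intersected in the (α, φ)
plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import LBMParams
from .membrane import MembraneMaterial
from .cells import NucleatedCell, build_cell, init_spring_network
from .geometry import (ConstrictionDevice, RatchetFunnel,
                       build_constriction_mask, build_funnel_mask)
from .lumped import LumpedChannelSegment, PIController, CoupledBoundaryState
from .simulation import Simulation

__all__ = [
    "PassageConfig", "PassageRecord", "run_passage",
    "SensitivityPoint", "sensitivity",
    "ThresholdConfig", "ThresholdResult", "run_threshold",
    "run_threshold_ramp", "desk_funnel",
    "fit_phi_for_alpha", "CalibrationResult", "calibrate",
    "PSI",
]

PSI = 6894.76  # Pa
UM = 1e-6


# ---------------------------------------------------------------------------
# passage through the constriction device
# ---------------------------------------------------------------------------


@dataclass
class PassageConfig:
    """One constriction passage run.

    The defaults are the desk-scale study conditions: the physical device
    geometry at δx = 0.75 μm (8 nodes across the 6 μm gap), level-3
    membrane meshes, outer membrane G_s = 5×10⁻⁵ N/m, and the 0.9 psi
    reservoir-to-reservoir pressure difference with the remaining channel
    lengths (950 μm main, 25 μm constriction) as lumped segments.
    """

    device: ConstrictionDevice = field(default_factory=ConstrictionDevice)
    dx: float = 0.75 * UM
    tau: float = 1.1
    rho0: float = 1060.0
    nu: float = 7.8e-7
    total_pressure: float = 0.9 * PSI
    cell_radius: float = 6.5 * UM
    model: str = "nucleated"
    phi: float = 0.38
    alpha: float = 15.5
    G_s_outer: float = 5e-5
    C: float = 50.0
    E_b: float = 1e-18
    spring_E: float | None = None
    mesh_level: int = 3
    start_gap: float = 2.0 * UM       # leading vertex to entrance plane
    max_steps: int = 200_000
    stall_window: int = 5000
    stall_speed_fraction: float = 1e-3
    adapt_every: int = 100
    record_every: int = 20
    pi_gains: tuple = (1e-3, 1e-6)
    ramp_steps: int = 3000

    @property
    def mu(self) -> float:
        return self.rho0 * self.nu


@dataclass
class PassageRecord:
    """Trajectory and event times of one passage run."""

    t: np.ndarray                 # s
    x_norm: np.ndarray            # centroid x / constriction length
    entry_time: float             # s
    transit_time: float           # s
    passage_time: float           # s (entry + transit)
    stuck: bool
    cell_radius: float
    params: dict = field(default_factory=dict)


def _make_cell(cfg: PassageConfig, center) -> NucleatedCell:
    outer_mat = MembraneMaterial(G_s=cfg.G_s_outer, C=cfg.C, E_b=cfg.E_b)
    if cfg.model == "single":
        cell = build_cell(cfg.cell_radius, "single", outer_material=outer_mat,
                          level=cfg.mesh_level, center=center)
    else:
        nuc_mat = MembraneMaterial(G_s=cfg.alpha * cfg.G_s_outer, C=cfg.C,
                                   E_b=cfg.E_b)
        cell = build_cell(cfg.cell_radius, "nucleated", phi=cfg.phi,
                          outer_material=outer_mat, nucleus_material=nuc_mat,
                          level=cfg.mesh_level, center=center)
        if cfg.spring_E is not None:
            init_spring_network(cell, cfg.spring_E)
    return cell


def estimate_3d_resistance(dev: ConstrictionDevice, mu: float) -> float:
    """Series Boussinesq estimate of the simulated region's resistance."""
    main = LumpedChannelSegment(h=dev.depth, l=dev.main_width,
                                length=dev.inlet_length + dev.outlet_length,
                                mu=mu)
    constr = LumpedChannelSegment(h=dev.depth, l=dev.constriction_width,
                                  length=dev.constriction_length, mu=mu)
    return main.resistance + constr.resistance


def _passage_simulation(cfg: PassageConfig):
    dev = cfg.device
    mask = build_constriction_mask(dev, cfg.dx)
    params = LBMParams.from_physical(cfg.dx, cfg.nu, cfg.rho0, cfg.tau)
    center = (dev.entrance_x - cfg.start_gap - cfg.cell_radius,
              0.5 * mask.shape[1] * cfg.dx, 0.5 * mask.shape[2] * cfg.dx)
    cell = _make_cell(cfg, center)
    segs = [
        LumpedChannelSegment(h=dev.depth, l=dev.main_width,
                             length=dev.lumped_main_length, mu=cfg.mu),
        LumpedChannelSegment(h=dev.depth, l=dev.constriction_width,
                             length=dev.lumped_constriction_length, mu=cfg.mu),
    ]
    coupling = CoupledBoundaryState(
        p_reservoir_in=cfg.total_pressure, p_reservoir_out=0.0,
        segments=segs,
        controller=PIController(K_p=cfg.pi_gains[0], K_i=cfg.pi_gains[1]))
    # the driving pressure is ramped by the Simulation; the controller
    # starts quiescent and tracks the ramped reservoir up
    coupling.p_inlet = coupling.p_reservoir_out
    coupling.controller.reset(coupling.p_inlet)
    sim = Simulation(mask, params, [cell], coupling=coupling,
                     adapt_every=cfg.adapt_every, ramp_steps=cfg.ramp_steps)
    return sim, cell


def run_passage(cfg: PassageConfig) -> PassageRecord:
    """Simulate one cell passing the constriction and time the events.

    Entry time runs from first contact of the leading vertex with the
    entrance plane until the trailing vertex crosses it; transit time from
    then until the leading vertex crosses the exit plane.  A cell whose
    centroid speed stays below ``stall_speed_fraction`` of the mean carrier
    speed over ``stall_window`` steps is declared stuck.
    """
    sim, cell = _passage_simulation(cfg)
    dev = cfg.device
    dt = sim.params.dt
    L = dev.constriction_length
    t_hist, x_hist = [], []
    t_contact = t_entered = t_exit = None
    stall_ref = None
    last_centroid = cell.centroid()[0]
    stall_count = 0
    for istep in range(cfg.max_steps):
        sim.step()
        lead, trail, centroid = sim.cell_extent()
        if istep % cfg.record_every == 0:
            t_hist.append(sim.diag.time)
            x_hist.append((centroid - dev.entrance_x) / L)
        if t_contact is None and lead >= dev.entrance_x:
            t_contact = sim.diag.time
        if t_entered is None and trail >= dev.entrance_x:
            t_entered = sim.diag.time
        if t_exit is None and lead >= dev.exit_x:
            t_exit = sim.diag.time
        # a strongly elongated cell can reach the exit before its tail
        # clears the entrance; wait for both events
        if t_exit is not None and t_entered is not None:
            break
        # stall detection on the centroid, referenced to the carrier speed
        if istep % 100 == 99:
            speed = abs(centroid - last_centroid) / (100 * dt)
            last_centroid = centroid
            if stall_ref is None:
                area = dev.main_width * dev.depth
                stall_ref = max(abs(sim.diag.flow_rate) / area, 1e-12)
            if speed < cfg.stall_speed_fraction * stall_ref:
                stall_count += 100
                if stall_count >= cfg.stall_window:
                    break
            else:
                stall_count = 0
    stuck = t_exit is None or t_entered is None
    meta = dict(alpha=cfg.alpha if cfg.model != "single" else None,
                phi=cfg.phi if cfg.model != "single" else None,
                G_s_outer=cfg.G_s_outer, model=cfg.model, dx=cfg.dx,
                steps=sim.diag.step)
    if stuck:
        return PassageRecord(np.asarray(t_hist), np.asarray(x_hist),
                             np.nan, np.nan, np.nan, True,
                             cfg.cell_radius, meta)
    entry = t_entered - t_contact
    transit = t_exit - t_entered
    return PassageRecord(np.asarray(t_hist), np.asarray(x_hist),
                         entry, transit, t_exit - t_contact, False,
                         cfg.cell_radius, meta)


# ---------------------------------------------------------------------------
# stiffness sensitivity (β, γ)
# ---------------------------------------------------------------------------


@dataclass
class SensitivityPoint:
    """β = G_s/G⁰_s against γ = τ_p/τ⁰_p for one run."""

    beta: float
    gamma: float
    G_s: float
    tau_p: float


def sensitivity(records, G_s_values, G0: float) -> list:
    """Map passage records at stiffnesses ``G_s_values`` to (β, γ) points.

    The reference record is the one with G_s equal to ``G0``; its point is
    (1, 1) by construction.
    """
    G_s_values = list(G_s_values)
    if G0 not in G_s_values:
        raise ValueError("reference stiffness G0 missing from the sweep")
    ref = records[G_s_values.index(G0)]
    if ref.stuck or not np.isfinite(ref.passage_time):
        raise ValueError("reference record has no passage time")
    out = []
    for rec, gs in zip(records, G_s_values):
        out.append(SensitivityPoint(beta=gs / G0,
                                    gamma=rec.passage_time / ref.passage_time,
                                    G_s=gs, tau_p=rec.passage_time))
    return out


# ---------------------------------------------------------------------------
# funnel threshold pressure
# ---------------------------------------------------------------------------


@dataclass
class ThresholdConfig:
    """Bisection for the threshold pressure of one funnel pore size."""

    funnel: RatchetFunnel = field(default_factory=RatchetFunnel)
    dx: float = 0.75 * UM
    tau: float = 1.1
    rho0: float = 1060.0
    nu: float = 7.8e-7
    cell_diameter: float = 15.6 * UM
    phi: float = 0.38                 # 11.3 μm nucleus at d = 15.6 μm
    alpha: float = 15.5
    G_s_outer: float = 5e-5
    C: float = 50.0
    E_b: float = 1e-18
    mesh_level: int = 3
    start_gap: float = 1.5 * UM
    p_low: float = 0.0                # known-stuck bound [Pa]
    p_high: float = 400.0             # known-pass cap [Pa]
    tol: float = 2.0                  # bracket width [Pa]
    max_steps_per_probe: int = 40_000
    stall_window: int = 4000
    stall_speed: float = 2e-6         # m/s, quasi-static stall threshold
    record_every: int = 50
    # staircase protocol (run_threshold_ramp)
    p_start: float = 50.0             # first pressure rung [Pa]
    p_step: float = 25.0              # pressure increment [Pa]
    dwell_steps: int = 1500           # steps held at each rung


@dataclass
class ThresholdResult:
    pore_width: float
    P_thresh: float
    bracket: tuple
    probes: list                      # (ΔP, verdict) pairs


def desk_funnel(pore_width: float) -> RatchetFunnel:
    """Compact funnel used by the desk-scale threshold sweeps: a 16 μm
    inlet (wide enough for the 12 μm test cell) and short straight
    sections keep the simulated domain small; taper angles and depth are
    the standard ones."""
    return RatchetFunnel(pore_width=pore_width, inlet_width=16e-6,
                         inlet_length=8e-6, outlet_length=6e-6)


def _threshold_simulation(cfg: ThresholdConfig, dP: float):
    fun = cfg.funnel
    mask = build_funnel_mask(fun, cfg.dx)
    params = LBMParams.from_physical(cfg.dx, cfg.nu, cfg.rho0, cfg.tau)
    r = 0.5 * cfg.cell_diameter
    # place the cell as close to the waist as it fits undeformed: its
    # leading edge must sit where the local funnel width still clears the
    # cell diameter (plus a small kernel margin)
    w_need = cfg.cell_diameter + 3 * cfg.dx
    slope = 2.0 * np.tan(np.deg2rad(fun.taper_half_angle_deg))
    if w_need < fun.inlet_width:
        x_fit = fun.inlet_length + (fun.inlet_width - w_need) / slope
    else:
        x_fit = fun.inlet_length
    x_lead = min(x_fit, fun.waist_x - cfg.start_gap)
    center = (max(x_lead - r, r + 3 * cfg.dx),
              0.5 * mask.shape[1] * cfg.dx, 0.5 * mask.shape[2] * cfg.dx)
    outer_mat = MembraneMaterial(G_s=cfg.G_s_outer, C=cfg.C, E_b=cfg.E_b)
    nuc_mat = MembraneMaterial(G_s=cfg.alpha * cfg.G_s_outer, C=cfg.C,
                               E_b=cfg.E_b)
    cell = build_cell(r, "nucleated", phi=cfg.phi, outer_material=outer_mat,
                      nucleus_material=nuc_mat, level=cfg.mesh_level,
                      center=center)
    sim = Simulation(mask, params, [cell], pressures=(dP, 0.0))
    return sim, cell


def run_threshold_ramp(cfg: ThresholdConfig) -> ThresholdResult:
    """Quasi-static staircase loading: the applied ΔP is raised by
    ``p_step`` every ``dwell_steps`` until the cell clears the pore waist;
    the rung at which it passes is reported as P_thresh (resolution =
    one rung).  This mirrors the gradual loading protocol of the
    threshold-pressure experiment in a single run per pore size.
    """
    sim, cell = _threshold_simulation(cfg, cfg.p_start)
    fun = cfg.funnel
    rungs = []
    p = cfg.p_start
    while p <= cfg.p_high + 1e-9:
        sim._p_base = (p, 0.0)
        sim._rho_in = sim.params.pressure_to_density(p)
        for _ in range(cfg.dwell_steps):
            sim.step()
            _, trail, _ = sim.cell_extent()
            if trail >= fun.waist_x:
                rungs.append((p, "pass"))
                return ThresholdResult(fun.pore_width, p,
                                       (p - cfg.p_step, p), rungs)
        rungs.append((p, "held"))
        p += cfg.p_step
    raise RuntimeError(f"no passing pressure below the cap {cfg.p_high} Pa "
                       "(unresolvable configuration)")


def _threshold_probe(cfg: ThresholdConfig, dP: float) -> str:
    fun = cfg.funnel
    sim, cell = _threshold_simulation(cfg, dP)
    params = sim.params
    last = cell.centroid()[0]
    stall = 0
    for istep in range(cfg.max_steps_per_probe):
        sim.step()
        lead, trail, centroid = sim.cell_extent()
        if trail >= fun.waist_x:
            return "pass"
        if istep % 100 == 99:
            speed = abs(centroid - last) / (100 * params.dt)
            last = centroid
            if speed < cfg.stall_speed:
                stall += 100
                if stall >= cfg.stall_window:
                    return "stuck"
            else:
                stall = 0
    return "stuck"


def run_threshold(cfg: ThresholdConfig) -> ThresholdResult:
    """Bisect the applied ΔP between a stuck and a passing value.

    A probe passes when leading and trailing vertices are both beyond the
    pore waist; it is stuck when the centroid quasi-statically stalls.
    Raises ``RuntimeError`` if the cap pressure cannot push the cell
    through.
    """
    probes = []
    lo, hi = cfg.p_low, cfg.p_high
    verdict_hi = _threshold_probe(cfg, hi)
    probes.append((hi, verdict_hi))
    if verdict_hi != "pass":
        raise RuntimeError(f"no passing pressure below the cap {hi} Pa "
                           "(unresolvable configuration)")
    while hi - lo > cfg.tol:
        mid = 0.5 * (lo + hi)
        verdict = _threshold_probe(cfg, mid)
        probes.append((mid, verdict))
        if verdict == "pass":
            hi = mid
        else:
            lo = mid
    return ThresholdResult(cfg.funnel.pore_width, hi, (lo, hi), probes)


# ---------------------------------------------------------------------------
# α–φ calibration
# ---------------------------------------------------------------------------


def fit_phi_for_alpha(samples, target_tau: float,
                      backend=None, alpha: float = None,
                      size: float = None, tol: float = 0.10) -> float:
    """Invert τ_p(φ) at fixed α for the φ* giving the target passage time.

    ``samples`` is a sequence of (φ, τ_p) pairs bracketing the target.
    Because τ_p grows exponentially in φ, interpolation is monotone linear
    in log τ_p.  If a simulator ``backend`` (callable (size, α, φ) → τ_p)
    is supplied, one confirmation evaluation is performed and φ* is
    accepted only within ``tol`` relative error of the target.
    """
    samples = sorted((float(p), float(t)) for p, t in samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 (phi, tau_p) samples")
    phis = np.array([s[0] for s in samples])
    taus = np.array([s[1] for s in samples])
    if np.any(np.diff(taus) <= 0):
        raise ValueError("tau_p samples must increase monotonically with phi")
    if not (taus[0] <= target_tau <= taus[-1]):
        raise ValueError("target passage time outside the sampled range "
                         "(extrapolation refused)")
    phi_star = float(np.interp(np.log(target_tau), np.log(taus), phis))
    if backend is not None:
        # confirmation run; if off target, refine once with the new sample
        tau_check = backend(size, alpha, phi_star)
        if abs(tau_check - target_tau) > tol * target_tau:
            taus = np.append(taus, tau_check)
            phis = np.append(phis, phi_star)
            order = np.argsort(phis)
            phis, taus = phis[order], taus[order]
            phi_star = float(np.interp(np.log(target_tau), np.log(taus), phis))
    return phi_star


@dataclass
class CalibrationResult:
    alpha_grid: np.ndarray
    loci: dict                    # size -> array of φ*(α)
    alpha_opt: float
    phi_opt: float
    objective: float
    targets: dict


def calibrate(targets: dict, alpha_grid, backend, phi_grid=None,
              n_refine: int = 400) -> CalibrationResult:
    """Find the (α, φ) pair jointly reproducing per-size passage times.

    Parameters
    ----------
    targets : dict
        Cell size [m] → target passage time [s]; at least two sizes.
    alpha_grid : sequence
        Stiffness ratios to sample (≥ 3 values).
    backend : callable
        (size, alpha, phi) → τ_p [s]; the simulator, or a surrogate.
    phi_grid : sequence, optional
        φ sample points per (size, α) curve (default 0.25…0.65).

    For every size, φ*(α) loci are assembled with
    :func:`fit_phi_for_alpha`; the optimum minimises the sum over sizes of
    squared normalised distances from (α, φ) to each piecewise-linear
    locus.
    """
    if len(targets) < 2:
        raise ValueError("need targets for at least two cell sizes")
    alpha_grid = np.asarray(sorted(alpha_grid), dtype=float)
    if alpha_grid.size < 3:
        raise ValueError("need at least three alpha values")
    if phi_grid is None:
        phi_grid = np.linspace(0.25, 0.65, 9)
    phi_grid = np.asarray(phi_grid, dtype=float)

    loci = {}
    for size, tau_target in targets.items():
        locus = []
        for a in alpha_grid:
            samples = [(p, backend(size, a, p)) for p in phi_grid]
            locus.append(fit_phi_for_alpha(samples, tau_target))
        loci[size] = np.asarray(locus)

    # objective: sum of squared normalised point-to-locus distances
    a_scale = alpha_grid.max() - alpha_grid.min()
    p_scale = max(float(np.ptp(np.concatenate(list(loci.values())))), 1e-6)

    a_fine = np.linspace(alpha_grid[0], alpha_grid[-1], n_refine)

    def objective(a, p):
        tot = 0.0
        for locus in loci.values():
            phi_on = np.interp(a_fine, alpha_grid, locus)
            d2 = ((a_fine - a) / a_scale) ** 2 + ((phi_on - p) / p_scale) ** 2
            tot += float(d2.min())
        return tot

    # coarse grid search over the loci band, then local refinement
    p_lo = min(l.min() for l in loci.values())
    p_hi = max(l.max() for l in loci.values())
    best = (np.inf, None, None)
    for a in a_fine[::4]:
        for p in np.linspace(p_lo, p_hi, 120):
            val = objective(a, p)
            if val < best[0]:
                best = (val, a, p)
    from scipy.optimize import minimize
    res = minimize(lambda z: objective(z[0], z[1]),
                   np.array([best[1], best[2]]), method="Nelder-Mead",
                   options=dict(xatol=1e-5, fatol=1e-14))
    a_opt, p_opt = float(res.x[0]), float(res.x[1])
    val = objective(a_opt, p_opt)
    spread = np.ptp([np.interp(a_opt, alpha_grid, l) for l in loci.values()])
    if spread > 0.5 * p_scale:
        warnings.warn("loci do not overlap closely in the sampled window; "
                      "reporting the nearest approach", RuntimeWarning)
    return CalibrationResult(alpha_grid, loci, a_opt, p_opt, val, dict(targets))
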