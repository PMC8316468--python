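import numpy as np
import pytest

from cellsqueeze.lattice import (CS2, VELOCITIES, WEIGHTS, OPPOSITE,
                                 WALL, FLUID, INLET, OUTLET,
                                 LBMParams, FluidLattice,
                                 equilibrium, forcing_populations, moments,
                                 apply_pressure_boundaries)
from cellsqueeze.lumped import boussinesq_coefficient


def lattice_params(tau=1.0):
    """Pure lattice units: dx = dt = 1, rho0 = 1."""
    return LBMParams.from_physical(1.0, CS2 * (tau - 0.5), 1.0, tau=tau)


class TestScheme:
    def test_weight_and_velocity_identities(self):
        c = VELOCITIES.astype(float)
        assert np.isclose(WEIGHTS.sum(), 1.0)
        np.testing.assert_allclose(WEIGHTS @ c, 0.0, atol=1e-15)
        np.testing.assert_allclose(np.einsum("i,ia,ib->ab", WEIGHTS, c, c),
                                   CS2 * np.eye(3), atol=1e-15)
        np.testing.assert_array_equal(VELOCITIES[OPPOSITE], -VELOCITIES)

    def test_unit_mapping_consistency(self):
        p = LBMParams.from_physical(0.15e-6, 7.8e-7, 1060.0, tau=1.0)
        assert np.isclose(CS2 * (p.tau - 0.5) * p.dx**2 / p.dt, p.nu)
        with pytest.raises(ValueError):
            LBMParams(dx=1.0, dt=1.0, rho0=1.0, nu=CS2 * 0.5, tau=0.4)


class TestEquilibrium:
    def test_zero_velocity_equilibrium_is_weights(self):
        np.testing.assert_allclose(equilibrium(np.float64(1.0), np.zeros(3)),
                                   WEIGHTS)

    @pytest.mark.parametrize("rho,v", [
        (1.0, (0.05, 0.0, 0.0)),
        (1.1, (0.02, -0.03, 0.01)),
        (0.9, (0.0, 0.0, 0.08)),
    ])
    def test_moment_identities(self, rho, v):
        feq = equilibrium(np.float64(rho), np.array(v))
        assert np.isclose(feq.sum(), rho, rtol=1e-14)
        np.testing.assert_allclose(feq @ VELOCITIES.astype(float),
                                   rho * np.asarray(v), atol=1e-15)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            equilibrium(np.float64(-1.0), np.zeros(3))
        with pytest.raises(ValueError):
            equilibrium(np.float64(np.nan), np.zeros(3))


class TestForcing:
    def test_zero_force_gives_zero_populations(self):
        h = forcing_populations(np.array([0.01, 0.0, 0.0]), np.zeros(3), 0.9)
        np.testing.assert_allclose(h, 0.0, atol=1e-18)

    def test_moment_structure(self, rng):
        v = 0.05 * rng.standard_normal(3)
        g = rng.standard_normal(3)
        tau = 0.8
        h = forcing_populations(v, g, tau)
        assert abs(h.sum()) < 1e-15 * np.abs(h).max()
        np.testing.assert_allclose(h @ VELOCITIES.astype(float),
                                   (1 - 0.5 / tau) * g, rtol=1e-12)

    def test_rest_fluid_closed_form(self):
        # v = 0, g = (G,0,0), tau = 1:  h_i = (1/2) w_i c_ix G / cs^2
        G = 0.37
        h = forcing_populations(np.zeros(3), np.array([G, 0.0, 0.0]), 1.0)
        expect = 0.5 * WEIGHTS * VELOCITIES[:, 0] * G / CS2
        np.testing.assert_allclose(h, expect, atol=1e-15)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            forcing_populations(np.zeros(3), np.ones(3), 0.5)


class TestMoments:
    def test_rest_state(self):
        lat = FluidLattice(np.ones((4, 4, 4), np.uint8), lattice_params())
        st = moments(lat)
        np.testing.assert_allclose(st.rho, 1.0)
        np.testing.assert_allclose(st.v, 0.0)

    def test_half_force_correction(self):
        # f_i = w_i, g = (1,0,0), dt = 1  ->  v = (0.5, 0, 0)
        lat = FluidLattice(np.ones((3, 3, 3), np.uint8), lattice_params())
        g = np.zeros((3, 3, 3, 3))
        g[..., 0] = 1.0
        st = moments(lat, g)
        np.testing.assert_allclose(st.v[..., 0], 0.5)

    def test_moments_invert_equilibrium(self, rng):
        lat = FluidLattice(np.ones((2, 2, 2), np.uint8), lattice_params())
        u = np.array([0.03, -0.02, 0.05])
        lat.f[:] = equilibrium(np.float64(1.0), u)
        st = moments(lat)
        np.testing.assert_allclose(st.v, np.broadcast_to(u, st.v.shape),
                                   atol=1e-15)


class TestCollideStream:
    def test_uniform_equilibrium_is_fixed_point(self):
        lat = FluidLattice(np.ones((6, 5, 4), np.uint8), lattice_params(0.8),
                           periodic=(True, True, True))
        f0 = lat.f.copy()
        for _ in range(10):
            lat.step()
        np.testing.assert_allclose(lat.f, f0, atol=1e-14)

    def test_streaming_moves_populations_by_ci(self):
        # equilibrium background (collision fixed point) + one bump per
        # population; with tau -> inf the bump streams by exactly c_i
        lat = FluidLattice(np.ones((5, 5, 5), np.uint8), lattice_params(),
                           periodic=(True, True, True))
        lat.params = LBMParams.from_physical(1.0, CS2 * (1e12 - 0.5), 1.0,
                                             tau=1e12)
        bump = 1e-6
        lat.f[2, 2, 2, :] += bump
        lat.step()
        for q, c in enumerate(VELOCITIES):
            dst = tuple((np.array([2, 2, 2]) + c) % 5)
            assert lat.f[dst + (q,)] > WEIGHTS[q] + 0.9 * bump

    def test_mass_conserved_in_closed_domain(self, rng):
        mask = np.ones((12, 10, 8), np.uint8)
        mask[:, 0, :] = WALL
        mask[:, -1, :] = WALL
        lat = FluidLattice(mask, lattice_params(0.9),
                           periodic=(True, False, True))
        lat.f[lat.mask != WALL] += 0.01 * rng.random((lat.f[lat.mask != WALL].shape))
        m0 = lat.total_mass()
        g = np.zeros(mask.shape + (3,))
        g[mask != WALL, 0] = 1e-6
        for _ in range(1000):
            lat.step(g)
        assert abs(lat.total_mass() - m0) / m0 < 1e-12

    def test_poiseuille_profile_matches_parabola(self):
        ny = 22
        mask = np.ones((4, ny, 4), np.uint8)
        mask[:, 0, :] = WALL
        mask[:, -1, :] = WALL
        lat = FluidLattice(mask, lattice_params(1.0),
                           periodic=(True, False, True))
        G = 1e-6
        g = np.zeros(mask.shape + (3,))
        g[mask == FLUID, 0] = G
        for _ in range(8000):
            lat.step(g)
        st = lat.macroscopic(g)
        nu = CS2 * 0.5
        y = np.arange(ny)
        u_ana = G / (2 * nu) * (y - 0.5) * (ny - 1.5 - y)
        mid = ny // 2
        assert abs(st.v[0, mid, 0, 0] / u_ana[mid] - 1) < 0.01

    def test_duct_flow_matches_series_solution(self):
        ny, nz = 26, 38
        mask = np.ones((4, ny, nz), np.uint8)
        mask[:, 0, :] = WALL
        mask[:, -1, :] = WALL
        mask[:, :, 0] = WALL
        mask[:, :, -1] = WALL
        lat = FluidLattice(mask, lattice_params(1.0),
                           periodic=(True, False, False))
        G = 1e-6
        g = np.zeros(mask.shape + (3,))
        g[mask == FLUID, 0] = G
        Q = _run_to_steady(lat, g)
        Q_ana = boussinesq_coefficient(ny - 2.0, nz - 2.0, CS2 * 0.5) * G
        assert abs(Q / Q_ana - 1) < 0.01

    def test_duct_convergence_is_second_order(self):
        errs = []
        sizes = [8, 12, 18]
        for n in sizes:
            ny, nz = n + 2, int(1.5 * n) + 2
            mask = np.ones((4, ny, nz), np.uint8)
            mask[:, 0, :] = WALL
            mask[:, -1, :] = WALL
            mask[:, :, 0] = WALL
            mask[:, :, -1] = WALL
            lat = FluidLattice(mask, lattice_params(1.0),
                               periodic=(True, False, False))
            G = 1e-6
            g = np.zeros(mask.shape + (3,))
            g[mask == FLUID, 0] = G
            Q = _run_to_steady(lat, g)
            Q_ana = boussinesq_coefficient(float(n), 1.5 * n, CS2 * 0.5) * G
            errs.append(abs(Q / Q_ana - 1))
        order = np.polyfit(np.log(sizes), np.log(errs), 1)[0]
        assert -order > 1.8

    def test_shear_wave_decay_recovers_viscosity(self):
        # u_x(y) = U sin(2 pi y / L) decays at rate nu k^2
        tau = 0.8
        L = 32
        mask = np.ones((4, L, 4), np.uint8)
        lat = FluidLattice(mask, lattice_params(tau),
                           periodic=(True, True, True))
        U = 1e-4
        y = np.arange(L)
        vx = U * np.sin(2 * np.pi * y / L)
        v = np.zeros((4, L, 4, 3))
        v[..., 0] = vx[None, :, None]
        lat.f[:] = equilibrium(np.ones((4, L, 4)), v)
        n_steps = 400
        for _ in range(n_steps):
            lat.step()
        st = lat.macroscopic()
        amp = np.abs(st.v[0, :, 0, 0] * np.sin(2 * np.pi * y / L)).sum() \
            / np.abs(np.sin(2 * np.pi * y / L)**2).sum()
        nu_meas = -np.log(amp / U) / (n_steps * (2 * np.pi / L) ** 2)
        nu_true = CS2 * (tau - 0.5)
        assert abs(nu_meas / nu_true - 1) < 0.005


def _run_to_steady(lat, g, tol=1e-12, max_steps=60000):
    prev = None
    for i in range(max_steps):
        lat.step(g)
        if i % 500 == 499:
            Q = lat.macroscopic(g).v[..., 0][lat.mask != WALL].sum() \
                / lat.shape[0]
            if prev is not None and abs(Q - prev) <= tol * abs(Q):
                return Q
            prev = Q
    return Q


class TestPressureBoundaries:
    def _duct(self, nx=40, ny=26, nz=38):
        mask = np.ones((nx, ny, nz), np.uint8)
        mask[:, 0, :] = WALL
        mask[:, -1, :] = WALL
        mask[:, :, 0] = WALL
        mask[:, :, -1] = WALL
        mask[0][mask[0] == FLUID] = INLET
        mask[-1][mask[-1] == FLUID] = OUTLET
        return mask

    def test_zero_pressure_difference_decays_to_rest(self):
        mask = self._duct(nx=12, ny=10, nz=10)
        lat = FluidLattice(mask, lattice_params())
        rho = 1.0 + 1e-3 * np.random.default_rng(0) \
            .standard_normal(mask.shape)
        lat.f[:] = equilibrium(rho, np.zeros(mask.shape + (3,)))
        for _ in range(3000):
            lat.step()
            apply_pressure_boundaries(lat, 1.0, 1.0)
        st = lat.macroscopic()
        # velocity decays to noise level; through-flow vanishes entirely
        assert np.abs(st.v).max() < 1e-6
        Q = st.v[6, :, :, 0][mask[6] != WALL].sum()
        assert abs(Q) < 1e-12

    def test_pressure_driven_duct_flow_rate(self):
        mask = self._duct()
        nx, ny, nz = mask.shape
        lat = FluidLattice(mask, lattice_params())
        dP = 1e-4
        rin = 1.0 + dP / CS2 / 2
        rout = 1.0 - dP / CS2 / 2
        prev = None
        for i in range(60000):
            lat.step()
            apply_pressure_boundaries(lat, rin, rout)
            if i % 500 == 499:
                Q = lat.macroscopic().v[nx // 2, :, :, 0].sum()
                if prev is not None and abs(Q - prev) < 1e-11 * abs(Q):
                    break
                prev = Q
        Geff = dP / (nx - 1)
        Q_ana = boussinesq_coefficient(ny - 2.0, nz - 2.0, CS2 * 0.5) * Geff
        assert abs(Q / Q_ana - 1) < 0.01

    def test_reversing_pressure_reverses_flow(self):
        mask = self._duct(nx=20, ny=12, nz=12)
        dP = 1e-6          # low speed keeps the quadratic (Mach^2) term tiny
        rin = 1.0 + dP / CS2 / 2
        rout = 1.0 - dP / CS2 / 2
        lats = []
        for a, b in ((rin, rout), (rout, rin)):
            lat = FluidLattice(mask, lattice_params())
            for _ in range(3000):
                lat.step()
                apply_pressure_boundaries(lat, a, b)
            lats.append(lat.macroscopic().v)
        asym = np.abs(lats[0] + lats[1]).max() / np.abs(lats[0]).max()
        assert asym < 1e-3

    def test_boundary_face_intersecting_wall_rejected(self):
        mask = self._duct(nx=12, ny=10, nz=10)
        lat = FluidLattice(mask, lattice_params())
        lat.mask[1, 1:-1, 1:-1] = WALL        # wall right behind the inlet
        with pytest.raises(ValueError, match="wall"):
            apply_pressure_boundaries(lat, 1.01, 1.0)
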