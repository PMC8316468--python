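import numpy as np
import pytest

from cellsqueeze.membrane import MembraneMaterial
from cellsqueeze.cells import (build_cell, init_spring_network, spring_forces,
                               adapt_springs, NUCLEUS, OUTER)
from conftest import winding_number

UM = 1e-6


class TestBuildCell:
    def test_karyoplasmic_ratio_sets_nucleus_diameter(self):
        # d = 15.6 um at phi = 0.38  ->  nucleus diameter 11.3 um
        cell = build_cell(7.8 * UM, "nucleated", phi=0.38, level=2)
        d_nuc = 2 * np.linalg.norm(cell.nucleus.X - cell.nucleus.centroid(),
                                   axis=1).mean()
        assert abs(d_nuc - 11.3 * UM) < 0.05 * UM
        assert abs(cell.nucleus.volume() / cell.outer.volume() - 0.38) < 0.01

    def test_phi_near_one_approaches_cell_radius(self):
        cell = build_cell(1.0, "nucleated", phi=0.999, level=1)
        r_nuc = np.linalg.norm(cell.nucleus.X, axis=1).mean()
        assert abs(r_nuc - 1.0) < 1e-3

    def test_single_model_has_no_nucleus_or_springs(self):
        cell = build_cell(1.0, "single", level=1)
        assert cell.nucleus is None
        assert cell.springs is None
        assert cell.alpha is None

    def test_alpha_is_stiffness_ratio(self):
        cell = build_cell(1.0, "nucleated", phi=0.4,
                          outer_material=MembraneMaterial(G_s=5e-5),
                          nucleus_material=MembraneMaterial(G_s=7.75e-4),
                          level=1)
        assert np.isclose(cell.alpha, 15.5)

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_phi_rejected(self, phi):
        with pytest.raises(ValueError):
            build_cell(1.0, "nucleated", phi=phi, level=1)

    def test_nucleus_strictly_inside_outer(self):
        cell = build_cell(1.0, "nucleated", phi=0.38, level=2)
        w = winding_number(cell.nucleus.X, cell.outer.X, cell.outer.faces)
        assert np.all(w > 0.5)


class TestSpringNetwork:
    def test_spring_counts_match_element_counts(self):
        cell = build_cell(1.0, "nucleated", phi=0.38, level=2)
        net = init_spring_network(cell, E=950.0)
        assert (net.src_mem == OUTER).sum() == cell.outer.n_faces
        assert (net.src_mem == NUCLEUS).sum() == cell.nucleus.n_faces
        assert net.n_springs == cell.outer.n_faces + cell.nucleus.n_faces

    def test_rest_lengths_from_concentric_geometry(self):
        R, phi = 1.0, 0.38
        Rn = R * phi ** (1 / 3)
        cell = build_cell(R, "nucleated", phi=phi, level=3)
        net = init_spring_network(cell, E=1.0)
        elem = np.sqrt(cell.nucleus.face_areas().mean())  # element scale
        cyto = net.L0[:net.n_cyto]
        nucl = net.L0[net.n_cyto:]
        assert np.all(np.abs(cyto - (R - Rn)) < elem)
        assert np.all(np.abs(nucl - 2 * Rn) < elem)

    def test_spring_constant_follows_hooke_definition(self):
        # E = 950 Pa, A = 1 um^2, L0 = 2 um -> k = 4.75e-4 N/m;
        # dL = 0.2 um -> |F| = 9.5e-11 N
        E, A, L0, dL = 950.0, 1e-12, 2e-6, 0.2e-6
        k = E * A / L0
        assert np.isclose(k, 4.75e-4)
        assert np.isclose(k * dL, 9.5e-11)
        cell = build_cell(1e-6, "nucleated", phi=0.38, level=1)
        net = init_spring_network(cell, E=950.0)
        np.testing.assert_allclose(net.k, 950.0 * net.src_area / net.L0,
                                   rtol=1e-12)

    def test_rest_configuration_is_force_free(self):
        cell = build_cell(1.0, "nucleated", phi=0.38, level=2)
        net = init_spring_network(cell, E=1.0)
        fo, fn = spring_forces(net, cell)
        assert np.abs(fo.G).max() == 0.0
        assert np.abs(fn.G).max() == 0.0

    def test_net_force_and_torque_vanish(self):
        cell = build_cell(1.0, "nucleated", phi=0.38, level=2)
        net = init_spring_network(cell, E=1.0)
        cell.outer.X = cell.outer.X * np.array([1.15, 0.95, 1.02])
        fo, fn = spring_forces(net, cell)
        fmax = max(np.abs(fo.G).max(), np.abs(fn.G).max())
        net_force = fo.G.sum(0) + fn.G.sum(0)
        assert np.abs(net_force).max() < 1e-10 * fmax
        torque = (np.cross(cell.outer.X, fo.G).sum(0)
                  + np.cross(cell.nucleus.X, fn.G).sum(0))
        assert np.abs(torque).max() < 1e-9 * fmax

    def test_stretch_reversal_reverses_forces(self):
        cell = build_cell(1.0, "nucleated", phi=0.38, level=1)
        net = init_spring_network(cell, E=1.0)
        cell.outer.X = cell.outer.X * 1.1
        f_out, _ = spring_forces(net, cell)
        cell.outer.X = cell.outer.X_ref * 0.9
        f_in, _ = spring_forces(net, cell)
        # stretched springs pull inward, compressed push outward
        rhat = cell.outer.X_ref / np.linalg.norm(cell.outer.X_ref, axis=1,
                                                 keepdims=True)
        assert (f_out.G * rhat).sum() < 0
        assert (f_in.G * rhat).sum() > 0

    def test_requires_nucleated_cell(self):
        cell = build_cell(1.0, "single", level=1)
        with pytest.raises(ValueError):
            init_spring_network(cell, E=1.0)


class TestAdaptiveReconnection:
    def _sample_points(self, net, cell, fractions=(0.1, 0.3, 0.5, 0.7, 0.9)):
        P0, P1 = net.endpoints(cell)
        return np.concatenate([P0 + (P1 - P0) * f for f in fractions])

    def test_identity_on_undeformed_cell(self):
        cell = build_cell(1.0, "nucleated", phi=0.38, level=2)
        net = init_spring_network(cell, E=1.0)
        tgt0, mem0 = net.tgt.copy(), net.tgt_mem.copy()
        adapt_springs(net, cell)
        np.testing.assert_array_equal(net.tgt, tgt0)
        np.testing.assert_array_equal(net.tgt_mem, mem0)

    def test_squeezed_dumbbell_springs_stay_inside(self):
        # dumbbell waist + nucleus shifted into one lobe: straight
        # connections cross outside the membrane; after adaptation every
        # sampled spring point is back inside (winding-number oracle)
        cell = build_cell(1.0, "nucleated", phi=0.04, level=2)
        net = init_spring_network(cell, E=1.0)
        X = cell.outer.X.copy()
        s = 0.25 + 0.75 * np.tanh(np.abs(X[:, 0]) / 0.3) ** 2
        X[:, 1] *= s
        X[:, 2] *= s
        cell.outer.X = X
        cell.nucleus.X = cell.nucleus.X + np.array([-0.55, 0.0, 0.0])
        pts = self._sample_points(net, cell)
        w_before = winding_number(pts, cell.outer.X, cell.outer.faces)
        assert (w_before < 0.5 - 1e-9).sum() > 100    # failure mode present
        adapt_springs(net, cell)
        pts = self._sample_points(net, cell)
        w_after = winding_number(pts, cell.outer.X, cell.outer.faces)
        assert (w_after < 0.5 - 1e-9).sum() == 0      # fully contained

    def test_spring_count_conserved_by_adaptation(self):
        cell = build_cell(1.0, "nucleated", phi=0.2, level=2)
        net = init_spring_network(cell, E=1.0)
        n0 = net.n_springs
        cell.outer.X = cell.outer.X * np.array([1.0, 0.7, 1.0])
        adapt_springs(net, cell)
        assert net.n_springs == n0

    def test_tension_preserved_across_reconnection(self):
        cell = build_cell(1.0, "nucleated", phi=0.2, level=2)
        net = init_spring_network(cell, E=1.0)
        cell.outer.X = cell.outer.X * 1.08      # uniform pre-tension
        P0, P1 = net.endpoints(cell)
        L = np.linalg.norm(P1 - P0, axis=1)
        tension_before = net.k * (L - net.L0)
        adapt_springs(net, cell)
        P0, P1 = net.endpoints(cell)
        L = np.linalg.norm(P1 - P0, axis=1)
        tension_after = net.k * (L - net.L0)
        np.testing.assert_allclose(tension_after, tension_before,
                                   rtol=1e-9, atol=1e-15)
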