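"""Ring-polymer mapping: springs, U_RP, collapse/expand, R_g, Hessian."""

import numpy as np
import pytest

from qpel.errors import ParameterError, SelectionError, StructureError
from qpel.forcefield import quartic_chain
from qpel.ringpolymer import (
    RPParams,
    RPState,
    collapse,
    expand_centroid,
    max_ring_rg,
    radius_of_gyration,
    rp_hessian,
    rp_potential_forces,
    spring_constants,
)
from qpel.topology import lattice_water_box
from qpel.units import HBAR, beta_from_T


class TestSpringConstants:
    def test_linear_in_mass(self):
        k1 = spring_constants([1.0], 300.0, 16)[0]
        k2 = spring_constants([2.0], 300.0, 16)[0]
        assert abs(k2 / k1 - 2.0) < 1e-12

    def test_quadratic_in_temperature(self):
        k1 = spring_constants([1.0], 150.0, 16)[0]
        k2 = spring_constants([1.0], 300.0, 16)[0]
        assert abs(k2 / k1 - 4.0) < 1e-12

    def test_hydrogen_300k_nb32_closed_form(self):
        m = 1.00782503207
        beta = beta_from_T(300.0)
        expected = m * 32 / (HBAR * beta) ** 2
        assert abs(spring_constants([m], 300.0, 32)[0] - expected) < 1e-9 * expected

    def test_invalid_inputs(self):
        with pytest.raises((ParameterError, ValueError)):
            spring_constants([1.0], -10.0, 8)
        with pytest.raises(ParameterError):
            spring_constants([-1.0], 300.0, 8)
        with pytest.raises(ParameterError):
            spring_constants([1.0], 300.0, 0)


class TestPotential:
    def test_collapsed_state_reduces_to_classical(self, water8):
        cfg, pot = water8
        params = RPParams(n_b=8, T=260.0, masses=cfg.topology.masses)
        st = collapse(cfg, params)
        u, f = rp_potential_forces(st, pot)
        e_cl, f_cl = pot.energy_forces(cfg.positions)
        assert abs(u - e_cl) < 1e-10 * abs(e_cl)
        # per-bead force is 1/n_b of the classical force
        assert np.allclose(f, np.repeat(f_cl[None] / 8, 8, axis=0))

    def test_single_bead_is_classical(self, water8):
        cfg, pot = water8
        params = RPParams(n_b=1, T=300.0, masses=cfg.topology.masses)
        st = RPState(cfg.positions[None], params, cfg.topology, cfg.box)
        u, _ = rp_potential_forces(st, pot)
        assert abs(u - pot.energy(cfg.positions)) < 1e-12 * abs(u)

    def test_two_bead_free_atom_spring_term(self):
        """Two cyclic bonds each contribute k d^2/2 for a bead pair at distance d."""

        class Free:
            def energy_forces(self, pos):
                return np.zeros(pos.shape[0]), np.zeros_like(pos)

        params = RPParams(n_b=2, T=300.0, masses=np.array([1.0]))
        d = 0.07
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = d
        st = RPState(pos, params)
        u, f = rp_potential_forces(st, Free())
        k = params.k_sp[0]
        assert abs(u - 2 * 0.5 * k * d**2) < 1e-10 * u
        assert abs(f[0, 0, 0] - 2 * k * d) < 1e-8 * abs(f[0, 0, 0])

    def test_cyclic_relabeling_invariance(self, water8):
        cfg, pot = water8
        params = RPParams(n_b=6, T=250.0, masses=cfg.topology.masses)
        st = collapse(cfg, params)
        rng = np.random.default_rng(1)
        st.positions += 0.003 * rng.standard_normal(st.positions.shape)
        u0, _ = rp_potential_forces(st, pot)
        st2 = RPState(np.roll(st.positions, 2, axis=0), params, cfg.topology, cfg.box)
        u1, _ = rp_potential_forces(st2, pot)
        assert abs(u1 - u0) < 1e-10 * abs(u0)

    def test_spring_sum_nonnegative_zero_iff_collapsed(self, water8):
        cfg, pot = water8
        params = RPParams(n_b=4, T=250.0, masses=cfg.topology.masses)
        st = collapse(cfg, params)
        u_col, _ = rp_potential_forces(st, pot)
        mean_u = pot.energy_forces(st.positions)[0].mean()
        assert abs(u_col - mean_u) < 1e-10 * abs(mean_u)
        st.positions += 0.001
        st.positions[0] -= 0.002  # uncollapse one slice
        u, _ = rp_potential_forces(st, pot)
        assert u > pot.energy_forces(st.positions)[0].mean() - 1e-12

    def test_forces_match_finite_differences(self):
        toy = quartic_chain(2, seed=4)
        params = RPParams(n_b=4, T=200.0, masses=toy.masses)
        rng = np.random.default_rng(2)
        st = RPState(0.3 * rng.standard_normal((4, 2, 3)), params)
        u, f = rp_potential_forces(st, toy)
        h = 1e-6
        for _ in range(10):
            k = rng.integers(0, 4)
            i = rng.integers(0, 2)
            a = rng.integers(0, 3)
            stp = st.copy()
            stp.positions[k, i, a] += h
            stm = st.copy()
            stm.positions[k, i, a] -= h
            fd = -(rp_potential_forces(stp, toy)[0] - rp_potential_forces(stm, toy)[0]) / (2 * h)
            assert abs(fd - f[k, i, a]) <= 1e-6 * max(1.0, abs(fd))

    def test_hessian_matches_force_differences(self):
        toy = quartic_chain(2, seed=5)
        params = RPParams(n_b=3, T=220.0, masses=toy.masses)
        rng = np.random.default_rng(3)
        st = RPState(0.2 * rng.standard_normal((3, 2, 3)), params)
        H = rp_hessian(st, toy)
        assert np.abs(H - H.T).max() < 1e-9 * np.abs(H).max()
        h = 1e-6
        n = st.positions.size
        Hfd = np.zeros((n, n))
        for col in range(n):
            stp = st.copy()
            stp.positions.flat[col] += h
            stm = st.copy()
            stm.positions.flat[col] -= h
            fp = rp_potential_forces(stp, toy)[1].ravel()
            fm = rp_potential_forces(stm, toy)[1].ravel()
            Hfd[:, col] = -(fp - fm) / (2 * h)
        assert np.abs(H - Hfd).max() <= 1e-5 * np.abs(Hfd).max()

    def test_mismatched_bead_count_rejected(self):
        params = RPParams(n_b=4, T=300.0, masses=np.ones(2))
        with pytest.raises(StructureError):
            RPState(np.zeros((3, 2, 3)), params)
        with pytest.raises(StructureError):
            RPState(np.zeros((4, 5, 3)), params)


class TestCollapseExpand:
    def test_round_trip_identity(self, water8):
        cfg, _ = water8
        params = RPParams(n_b=5, T=270.0, masses=cfg.topology.masses)
        back = expand_centroid(collapse(cfg, params))
        assert np.array_equal(back.positions, cfg.positions)

    def test_collapsed_rg_zero(self, water8):
        cfg, _ = water8
        params = RPParams(n_b=5, T=270.0, masses=cfg.topology.masses)
        st = collapse(cfg, params)
        assert radius_of_gyration(st) == 0.0
        assert max_ring_rg(st) == 0.0
        assert np.array_equal(expand_centroid(st).positions, cfg.positions)

    def test_symmetric_ring_centroid_is_center(self):
        params = RPParams(n_b=8, T=300.0, masses=np.array([1.0]))
        th = 2 * np.pi * np.arange(8) / 8
        pos = np.stack([np.cos(th), np.sin(th), np.zeros(8)], axis=1)[:, None, :]
        center = np.array([2.0, -1.0, 0.5])
        st = RPState(pos + center, params)
        assert np.allclose(st.centroids()[0], center, atol=1e-12)


class TestRadiusOfGyration:
    def test_two_beads_at_distance_d(self):
        params = RPParams(n_b=2, T=300.0, masses=np.array([1.0]))
        d = 0.12
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 2] = d
        st = RPState(pos, params)
        assert abs(radius_of_gyration(st, unit="nm") - d / 2) < 1e-12

    def test_angstrom_reporting(self):
        params = RPParams(n_b=2, T=300.0, masses=np.array([1.0]))
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = 0.1
        st = RPState(pos, params)
        assert abs(radius_of_gyration(st) - 0.5) < 1e-12  # 0.05 nm = 0.5 A

    def test_empty_species_selection_raises(self):
        cfg = lattice_water_box(2, "H2O")
        params = RPParams(n_b=2, T=300.0, masses=cfg.topology.masses)
        st = collapse(cfg, params)
        with pytest.raises(SelectionError):
            radius_of_gyration(st, species="T")
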