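"""Samplers: stationarity, determinism, PILE thermostat, diffusion estimation."""

import numpy as np
import pytest

from qpel.errors import IntegrationFailureError, SamplingError
from qpel.forcefield import discretized_ho_energy, harmonic_lattice, single_oscillator
from qpel.ringpolymer import RPParams, RPState
from qpel.sampler import (
    DiffusionResult,
    RunSpec,
    Trajectory,
    _nm_transform,
    diffusion_coefficient,
    free_rp_mode_frequencies,
    quantum_energy_estimate,
    run_classical_nvt,
    run_rpmd_nvt,
)
from qpel.units import KB, beta_from_T


def test_classical_equipartition_on_harmonic_lattice():
    """Sampled position variance per mode equals k_B T/(m w^2) within 3 SE."""
    omegas = np.array([25.0, 40.0, 60.0, 90.0, 130.0, 180.0])
    toy = harmonic_lattice(omegas, seed=7)
    T = 300.0
    spec = RunSpec(T=T, dt=2e-3, n_steps=50000, gamma=5.0, n_b=1, seed=9, stride=10)
    traj = run_classical_nvt(toy, toy.x_min, spec)
    H = toy.hessian(toy.x_min)
    lam, V = np.linalg.eigh(H)
    flat = traj.positions.reshape(traj.n_frames, -1)
    q = flat @ V
    var = q.var(axis=0)
    expected = KB * T / lam
    # ~16 independent blocks -> relative SE of a variance ~ sqrt(2/16)
    n_blocks = 16
    blocks = np.array_split(q, n_blocks)
    bv = np.array([b.var(axis=0) for b in blocks])
    se = bv.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    assert np.all(np.abs(var - expected) < 3.5 * se)


def test_classical_kinetic_temperature(water8_is):
    """Strong coupling so the energy autocorrelation time stays well below
    the run length; the stationary kinetic temperature then resolves T."""
    rec, pot = water8_is
    spec = RunSpec(T=260.0, dt=0.5e-3, n_steps=12000, gamma=20.0, n_b=1, seed=2,
                   stride=5, equilibration=2000)
    traj = run_classical_nvt(pot, rec.configuration.positions, spec)
    kT = traj.kinetic.mean() / (0.5 * 9 * 8)
    assert abs(kT - KB * 260.0) < 0.05 * KB * 260.0


def test_same_seed_bit_identical():
    toy = single_oscillator(80.0)
    spec = RunSpec(T=250.0, dt=1e-3, n_steps=500, gamma=1.0, n_b=1, seed=42, stride=7)
    t1 = run_classical_nvt(toy, toy.x_min + 0.1, spec)
    t2 = run_classical_nvt(toy, toy.x_min + 0.1, spec)
    assert np.array_equal(t1.positions, t2.positions)
    assert np.array_equal(t1.energies, t2.energies)

    params = RPParams(n_b=4, T=250.0, masses=toy.masses)
    st = RPState(np.zeros((4, 1, 3)), params)
    spec_rp = RunSpec(T=250.0, dt=1e-3, n_steps=300, gamma=1.0, n_b=4, seed=11)
    r1 = run_rpmd_nvt(toy, st, spec_rp)
    r2 = run_rpmd_nvt(toy, st, spec_rp)
    assert np.array_equal(r1.positions, r2.positions)


def test_zero_friction_limit_conserves_energy():
    toy = single_oscillator(60.0, mass=1.5)
    spec = RunSpec(T=200.0, dt=0.5e-3, n_steps=5000, gamma=0.0, n_b=1, seed=1, stride=10)
    traj = run_classical_nvt(toy, toy.x_min + 0.2, spec)
    etot = traj.energies + traj.kinetic
    assert np.ptp(etot) < 1e-3 * max(1.0, abs(etot.mean()))


def test_integration_blowup_names_step():
    toy = single_oscillator(1e6)  # dt far beyond stability
    spec = RunSpec(T=300.0, dt=1e-2, n_steps=2000, gamma=0.0, n_b=1, seed=0)
    with pytest.raises(IntegrationFailureError) as err:
        run_classical_nvt(toy, toy.x_min + 1.0, spec)
    assert err.value.step >= 0


def test_nm_transform_orthonormal():
    for nb in (1, 2, 3, 8, 32):
        C, _ = _nm_transform(nb)
        assert np.allclose(C @ C.T, np.eye(nb), atol=1e-12)


def test_rpmd_ho_energy_estimator_matches_discretized_exact():
    """Primitive estimator vs the exact n_b-bead HO energy, within 3 SE."""
    om0 = 1.0 / (beta_from_T(300.0) * 0.0635077993)  # beta hbar w ~ 1
    toy = single_oscillator(om0)
    nb = 16
    params = RPParams(n_b=nb, T=300.0, masses=toy.masses)
    st = RPState(np.zeros((nb, 1, 3)), params)
    spec = RunSpec(T=300.0, dt=0.5e-3, n_steps=60000, gamma=5.0, n_b=nb,
                   seed=5, stride=10, equilibration=5000)
    traj = run_rpmd_nvt(toy, st, spec, store_beads=False)
    e, se = quantum_energy_estimate(traj)
    exact = 3 * discretized_ho_energy(om0, 300.0, nb)
    assert abs(e - exact) < 3 * se
    assert se < 0.15 * exact


def test_rpmd_single_bead_matches_classical_statistics():
    toy = single_oscillator(90.0)
    T = 280.0
    params = RPParams(n_b=1, T=T, masses=toy.masses)
    st = RPState(np.zeros((1, 1, 3)), params)
    spec = RunSpec(T=T, dt=1e-3, n_steps=40000, gamma=8.0, n_b=1, seed=3,
                   stride=10, equilibration=2000)
    traj = run_rpmd_nvt(toy, st, spec, store_beads=False)
    # classical HO: <U> = (3/2) kT
    assert abs(traj.aux["ubar"].mean() - 1.5 * KB * T) < 0.1 * KB * T


def test_pile_free_ring_mode_temperatures():
    """Each free-ring normal mode is thermostatted to T within a few percent."""

    class Free:
        def energy_forces(self, pos):
            return np.zeros(pos.shape[0]), np.zeros_like(pos)

    nb, T, n_atoms = 8, 300.0, 32
    params = RPParams(n_b=nb, T=T, masses=np.full(n_atoms, 2.0))
    st = RPState(np.zeros((nb, n_atoms, 3)), params)
    spec = RunSpec(T=T, dt=0.5e-3, n_steps=50000, gamma=2.0, n_b=nb,
                   seed=8, stride=5, equilibration=4000, )
    traj = run_rpmd_nvt(Free(), st, spec, store_beads=False)
    # per-mode kinetic temperature: <KE_j> = (3 n_atoms / 2) k_B T_j
    ke = traj.aux["nm_ke"].mean(axis=0)
    Tj = ke / (1.5 * n_atoms * KB)
    assert np.all(np.abs(Tj - T) < 0.02 * T)


class TestDiffusion:
    def _brownian_traj(self, d_target_nm2, n=4000, dt=0.01, n_part=200, seed=0):
        rng = np.random.default_rng(seed)
        steps = rng.standard_normal((n, n_part, 3)) * np.sqrt(2 * d_target_nm2 * dt)
        pos = np.cumsum(steps, axis=0)
        spec = RunSpec(T=300.0, dt=dt, n_steps=n, n_b=1, seed=seed, stride=1)
        return Trajectory(
            np.arange(n) * dt, pos, np.zeros(n), np.zeros(n), spec
        )

    def test_brownian_oracle_recovered_within_5_percent(self):
        """Known-D random walks: the estimate (averaged over 3 independent
        realizations to suppress the long-lag MSD wander) lands within 5%."""
        d_in = 5e-4  # nm^2/ps
        vals = []
        for seed in (0, 1, 2):
            res = diffusion_coefficient(self._brownian_traj(d_in, n=10000, seed=seed))
            assert not res.nondiffusive
            vals.append(res.D)
        assert abs(np.mean(vals) - d_in * 100) < 0.05 * d_in * 100

    def test_frozen_trajectory_gives_zero(self):
        traj = self._brownian_traj(0.0)
        traj.positions[:] = 1.0
        res = diffusion_coefficient(traj)
        assert res.D == 0.0

    def test_ballistic_flagged_nondiffusive(self):
        n, dt = 2000, 0.01
        t = np.arange(n) * dt
        pos = np.zeros((n, 5, 3))
        pos[:, :, 0] = t[:, None] * np.linspace(1, 2, 5)[None, :]
        spec = RunSpec(T=300.0, dt=dt, n_steps=n, n_b=1, seed=0, stride=1)
        traj = Trajectory(t, pos, np.zeros(n), np.zeros(n), spec)
        res = diffusion_coefficient(traj)
        assert res.nondiffusive

    def test_too_few_frames(self):
        traj = self._brownian_traj(1e-4, n=3)
        with pytest.raises(SamplingError):
            diffusion_coefficient(traj)
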