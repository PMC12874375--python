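import numpy as np
import pytest

from qpel.forcefield import WaterPotential, load_params
from qpel.inherent import minimize_to_is
from qpel.pipeline import run_classical_is_study
from qpel.ringpolymer import RPParams, RPState, collapse, radius_of_gyration
from qpel.sampler import RunSpec, run_rpmd_nvt
from qpel.topology import lattice_water_box


@pytest.fixture(scope="session")
def ff_params():
    return load_params()


@pytest.fixture(scope="session")
def water8(ff_params):
    """Jittered 8-molecule H2O lattice box with its potential."""
    cfg = lattice_water_box(8, "H2O", jitter=0.01, seed=1)
    pot = WaterPotential(cfg.topology, cfg.box, ff_params)
    return cfg, pot


@pytest.fixture(scope="session")
def water8_is(water8):
    """A converged classical inherent structure of the 8-molecule box."""
    cfg, pot = water8
    rec = minimize_to_is(cfg, pot, tol=1e-8)
    return rec, pot


@pytest.fixture(scope="session")
def mini_study():
    """Scaled-down annealed classical-IS study (N=8, 240/300 K, 25+ IS/T)."""
    return run_classical_is_study(seed=0)


def _rg_run(isotope, T, seed=4):
    ff = load_params()
    cfg = lattice_water_box(8, isotope, jitter=0.005, seed=2)
    pot = WaterPotential(cfg.topology, cfg.box, ff)
    params = RPParams(n_b=32, T=T, masses=cfg.topology.masses)
    st = collapse(cfg, params)
    spec = RunSpec(
        T=T, dt=0.25e-3, n_steps=1200, gamma=0.5, n_b=32,
        seed=seed, stride=30, equilibration=800,
    )
    traj = run_rpmd_nvt(pot, st, spec)
    states = [
        RPState(b, params, cfg.topology, cfg.box) for b in traj.aux["beads"]
    ]
    out = {}
    for sp in set(cfg.topology.species):
        out[sp] = radius_of_gyration(states, sp)
    return out


@pytest.fixture(scope="session")
def rg_by_isotope():
    """Per-species thermal R_g (Angstrom) from short RPMD runs."""
    return {
        ("H2O", 300.0): _rg_run("H2O", 300.0),
        ("D2O", 300.0): _rg_run("D2O", 300.0),
        ("T2O", 300.0): _rg_run("T2O", 300.0),
        ("H2O", 220.0): _rg_run("H2O", 220.0),
    }
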