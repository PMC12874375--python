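"""Ring-polymer representation of the quantum system.

The path-integral mapping replaces each atom i by a cyclic polymer of n_b
beads joined by harmonic springs of stiffness

    k_i^sp = m_i n_b / (hbar beta)^2        [kJ/mol/nm^2]

and rescales the bead mass to m_i' = n_b m_i.  The ring-polymer potential

    U_RP(R) = sum_i sum_k 1/2 k_i^sp |r_i^{k+1} - r_i^k|^2
              + (1/n_b) sum_k U(r^k)

defines the potential energy landscape of the quantum liquid at fixed
(T, n_b).  Springs connect beads of the same atom *without* minimum
imaging (rings are kept unwrapped); the physical potential U is evaluated
per bead slice with minimum imaging inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, SelectionError, StructureError
from .topology import Configuration, Topology
from .units import ANGSTROM_PER_NM, HBAR, beta_from_T


def spring_constants(masses, T: float, n_b: int) -> np.ndarray:
    """Per-atom ring-polymer spring constants m n_b/(hbar beta)^2.

    Linear in mass and proportional to T^2 (k^sp ∝ m T^2).
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ParameterError("masses must be positive")
    if n_b < 1:
        raise ParameterError("n_b must be >= 1")
    beta = beta_from_T(T)  # raises for T <= 0
    return masses * n_b / (HBAR * beta) ** 2


@dataclass(frozen=True)
class RPParams:
    """Thermodynamic state of the ring-polymer system."""

    n_b: int
    T: float
    masses: np.ndarray  # per-atom physical masses, amu

    def __post_init__(self):
        if self.n_b < 1:
            raise ParameterError("n_b must be >= 1")
        m = np.asarray(self.masses, dtype=float)
        if np.any(m <= 0):
            raise ParameterError("masses must be positive")
        object.__setattr__(self, "masses", m)
        beta_from_T(self.T)

    @property
    def beta(self) -> float:
        return beta_from_T(self.T)

    @property
    def k_sp(self) -> np.ndarray:
        return spring_constants(self.masses, self.T, self.n_b)

    @property
    def bead_masses(self) -> np.ndarray:
        """m' = n_b m."""
        return self.n_b * self.masses


@dataclass
class RPState:
    """Bead positions of every ring polymer, slice-major.

    ``positions`` has shape (n_b, n_atoms, 3): ``positions[k]`` is the
    k-th bead slice — a full classical configuration.  The cyclic index
    convention r^{n_b+1} = r^1 is implicit.
    """

    positions: np.ndarray
    params: RPParams
    topology: Topology | None = None
    box: float | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[0] != self.params.n_b:
            raise StructureError(
                f"positions must be (n_b, n_atoms, 3); got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.params.masses):
            raise StructureError("bead count/atom count mismatch with params")

    @property
    def n_b(self) -> int:
        return self.params.n_b

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def centroids(self) -> np.ndarray:
        # anchored mean: exactly the classical positions for a collapsed state
        dev = self.positions - self.positions[0]
        return self.positions[0] + dev.mean(axis=0)

    def copy(self) -> "RPState":
        return RPState(self.positions.copy(), self.params, self.topology, self.box)


def rp_potential_forces(state: RPState, potential) -> tuple[float, np.ndarray]:
    """U_RP (kJ/mol) and per-bead forces for a classical potential callback.

    ``potential`` must expose ``energy_forces(pos)`` accepting the batched
    slice array (n_b, n_atoms, 3).  Forces are the exact negative gradient
    of the returned energy.
    """
    pos = state.positions
    n_b = state.n_b
    k = state.params.k_sp  # (n_atoms,)

    diff = np.roll(pos, -1, axis=0) - pos  # r^{k+1} - r^k, cyclic
    u_spring = 0.5 * (k[None, :] * (diff**2).sum(axis=-1)).sum()
    e_slices, f_slices = potential.energy_forces(pos)
    u = u_spring + float(np.sum(e_slices)) / n_b

    # spring force on bead k: -k (2 r^k - r^{k+1} - r^{k-1})
    lap = np.roll(pos, -1, axis=0) + np.roll(pos, 1, axis=0) - 2.0 * pos
    forces = k[None, :, None] * lap + f_slices / n_b
    return u, forces


def rp_hessian(state: RPState, potential) -> np.ndarray:
    """Second-derivative matrix of U_RP over all bead coordinates.

    Block structure: (1/n_b) x the classical Hessian of every bead slice
    on the diagonal, plus the cyclic spring coupling k_i (2, -1, -1)
    between neighbouring beads of each atom.  Coordinate order matches
    ``state.positions.ravel()`` (slice-major).
    """
    n_b, n_atoms = state.n_b, state.n_atoms
    k = state.params.k_sp
    dim = 3 * n_atoms
    H = np.zeros((n_b * dim, n_b * dim))
    for s in range(n_b):
        sl = slice(s * dim, (s + 1) * dim)
        H[sl, sl] += potential.hessian(state.positions[s]) / n_b
    kdiag = np.repeat(k, 3)
    for s in range(n_b):
        nxt = (s + 1) % n_b
        a = slice(s * dim, (s + 1) * dim)
        b = slice(nxt * dim, (nxt + 1) * dim)
        H[a, a][np.diag_indices(dim)] += 2.0 * kdiag
        H[a, b][np.diag_indices(dim)] -= kdiag
        H[b, a][np.diag_indices(dim)] -= kdiag
    return H


def collapse(config: Configuration, params: RPParams) -> RPState:
    """Place all n_b beads of every atom at its classical position."""
    pos = np.repeat(config.positions[None, :, :], params.n_b, axis=0)
    return RPState(pos, params, config.topology, config.box)


def expand_centroid(state: RPState) -> Configuration:
    """Classical configuration at the bead centroids (inverse of collapse)."""
    if state.topology is None or state.box is None:
        raise StructureError("state carries no topology/box to expand into")
    return Configuration(state.centroids(), state.box, state.topology)


def radius_of_gyration(
    states: RPState | list[RPState],
    species: str | None = None,
    unit: str = "angstrom",
) -> float:
    """Root-mean-square ring-polymer radius of gyration.

    R_g^2 = < (1/n_b) sum_k (r_k - r_cm)^2 >, averaged over all ring
    polymers of the selected species (all atoms when ``species`` is None)
    and over the supplied frames.  Reported in Angstrom by default to
    match the usual collapse threshold (1e-4 Angstrom); pass
    ``unit='nm'`` for internal units.
    """
    if isinstance(states, RPState):
        states = [states]
    acc, count = 0.0, 0
    for st in states:
        if species is None:
            sel = np.arange(st.n_atoms)
        else:
            if st.topology is None:
                raise SelectionError("state has no topology for species selection")
            sel = st.topology.species_indices(species)
        pos = st.positions[:, sel, :]
        rel = pos - pos[0]
        dev = rel - rel.mean(axis=0, keepdims=True)
        acc += (dev**2).sum(axis=(0, 2)).sum() / st.n_b
        count += len(sel)
    if count == 0:
        raise SelectionError("empty species selection")
    rg_nm = float(np.sqrt(acc / count))
    if unit == "nm":
        return rg_nm
    if unit == "angstrom":
        return rg_nm * ANGSTROM_PER_NM
    raise ParameterError(f"unknown unit {unit!r}")


def max_ring_rg(state: RPState, unit: str = "angstrom") -> float:
    """Largest single-ring R_g in the state (collapse diagnostic)."""
    rel = state.positions - state.positions[0]
    dev = rel - rel.mean(axis=0, keepdims=True)
    rg = np.sqrt((dev**2).sum(axis=-1).mean(axis=0))  # per atom
    val = float(rg.max())
    return val * ANGSTROM_PER_NM if unit == "angstrom" else val
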