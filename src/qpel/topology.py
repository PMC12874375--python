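"""Topologies and configurations for flexible 3-site water boxes.

A water molecule is three *massive* sites in the fixed order (O, H1, H2);
the charge-carrying M site of TIP4P-type models is a massless geometric
site reconstructed from these on the fly (see :mod:`qpel.forcefield`).
Isotopologues differ only in the masses assigned to the H positions:
H2O, D2O and T2O are symmetric, while HDO assigns the H mass to H1 and
the D mass to H2 of every molecule (100% singly-substituted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .errors import ParameterError, StructureError

ISOTOPE_H_MASSES = {
    "H2O": (units.MASS_H, units.MASS_H),
    "HDO": (units.MASS_H, units.MASS_D),
    "D2O": (units.MASS_D, units.MASS_D),
    "T2O": (units.MASS_T, units.MASS_T),
}

ISOTOPE_H_LABELS = {
    "H2O": ("H", "H"),
    "HDO": ("H", "D"),
    "D2O": ("D", "D"),
    "T2O": ("T", "T"),
}


@dataclass(frozen=True)
class Topology:
    """Site bookkeeping for a box of 3-site water molecules.

    Attributes
    ----------
    n_molecules:
        Number of water molecules N; the box has ``3*N`` massive sites in
        molecule-major order (O, H1, H2).
    species:
        Per-site chemical labels, e.g. ``["O", "H", "H", ...]``.
    masses:
        Per-site masses in amu, strictly positive.
    isotope:
        Label of the isotopologue this topology was built for (metadata).
    """

    n_molecules: int
    species: tuple[str, ...]
    masses: np.ndarray
    isotope: str = "H2O"

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ParameterError("need at least one molecule")
        if len(self.species) != 3 * self.n_molecules:
            raise StructureError("every molecule must have exactly 3 sites")
        m = np.asarray(self.masses, dtype=float)
        if m.shape != (3 * self.n_molecules,):
            raise StructureError("masses must have one entry per site")
        if not np.all(m > 0):
            raise ParameterError("masses must be strictly positive")
        object.__setattr__(self, "masses", m)

    @property
    def n_sites(self) -> int:
        return 3 * self.n_molecules

    @property
    def n_dof(self) -> int:
        """d = 9N, the number of degrees of freedom."""
        return 9 * self.n_molecules

    def oxygen_indices(self) -> np.ndarray:
        return np.arange(0, self.n_sites, 3)

    def hydrogen_indices(self) -> np.ndarray:
        idx = np.arange(self.n_sites)
        return idx[idx % 3 != 0]

    def species_indices(self, label: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.species) if s == label])
        if idx.size == 0:
            from .errors import SelectionError

            raise SelectionError(f"no sites with species {label!r}")
        return idx


def water_topology(n_molecules: int, isotope: str = "H2O") -> Topology:
    """Build the topology of ``n_molecules`` water molecules of one isotopologue."""
    if isotope not in ISOTOPE_H_MASSES:
        raise ParameterError(
            f"unknown isotopologue {isotope!r}; choose from {sorted(ISOTOPE_H_MASSES)}"
        )
    mh1, mh2 = ISOTOPE_H_MASSES[isotope]
    l1, l2 = ISOTOPE_H_LABELS[isotope]
    species = tuple(["O", l1, l2] * n_molecules)
    masses = np.tile([units.MASS_O, mh1, mh2], n_molecules)
    return Topology(n_molecules, species, masses, isotope)


@dataclass
class Configuration:
    """Positions (nm) of the massive sites in a cubic periodic box."""

    positions: np.ndarray  # (n_sites, 3), nm
    box: float  # cubic edge L, nm
    topology: Topology = field(repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.topology.n_sites, 3):
            raise StructureError(
                f"positions shape {self.positions.shape} does not match "
                f"{self.topology.n_sites} sites"
            )
        if not np.all(np.isfinite(self.positions)):
            raise StructureError("positions must be finite")
        if self.box <= 0:
            raise ParameterError("box edge must be positive")

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.box, self.topology)


@dataclass
class PointSet:
    """Bare coordinate container for toy systems (no molecules, no box)."""

    positions: np.ndarray
    box: float | None = None
    topology: Topology | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)

    def copy(self) -> "PointSet":
        return PointSet(self.positions.copy(), self.box, self.topology)


def lattice_water_box(
    n_molecules: int,
    isotope: str = "H2O",
    v_cm3_mol: float = 18.0,
    jitter: float = 0.0,
    seed: int | None = None,
) -> Configuration:
    """Place water molecules on a simple-cubic lattice in a box set by v.

    Molecules are oriented in a staggered pattern; ``jitter`` adds a uniform
    random displacement (nm) to every site, which is how disordered starting
    points for minimization/equilibration are produced.
    """
    topo = water_topology(n_molecules, isotope)
    L = units.molar_volume_to_box_edge(v_cm3_mol, n_molecules)
    n_cell = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    a = L / n_cell
    # internal geometry near the force-field equilibrium
    r_oh = 0.09419
    theta = np.deg2rad(107.4)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [r_oh * np.sin(theta / 2), 0.0, r_oh * np.cos(theta / 2)],
            [-r_oh * np.sin(theta / 2), 0.0, r_oh * np.cos(theta / 2)],
        ]
    )
    rots = [
        np.eye(3),
        np.diag([1.0, -1.0, -1.0]),
        np.diag([-1.0, 1.0, -1.0]),
        np.diag([-1.0, -1.0, 1.0]),
    ]
    pos = np.empty((3 * n_molecules, 3))
    m = 0
    for i in range(n_cell):
        for j in range(n_cell):
            for k in range(n_cell):
                if m >= n_molecules:
                    break
                center = (np.array([i, j, k]) + 0.5) * a
                R = rots[(i + j + k) % len(rots)]
                pos[3 * m : 3 * m + 3] = center + local @ R.T
                m += 1
    if jitter > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.uniform(-jitter, jitter, size=pos.shape)
    return Configuration(pos, L, topo)
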