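"""Analytically solvable toy potentials used as oracles in tests.

Each factory returns a :class:`ToySystem` whose energy/force/Hessian
callbacks share the batched ``(..., n_atoms, 3)`` interface of the water
engine, so the samplers, minimizers and spectral code run on them
unchanged.  For harmonic systems the exact classical, quantum and
discretized path-integral free energies are available in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..errors import ParameterError
from ..units import HBAR, KB, beta_from_T


# ----------------------------------------------------------- closed forms
def classical_ho_free_energy(omega: float, T: float) -> float:
    """Classical free energy per mode, k_B T ln(beta hbar omega)."""
    b = beta_from_T(T)
    return KB * T * math.log(b * HBAR * omega)


def quantum_ho_free_energy(omega: float, T: float) -> float:
    """Exact quantum free energy per mode, k_B T ln(2 sinh(beta hbar omega/2))."""
    b = beta_from_T(T)
    x = 0.5 * b * HBAR * omega
    # log(2 sinh x) = x + log(1 - exp(-2x)), stable for large x
    return KB * T * (x + math.log1p(-math.exp(-2.0 * x)))

def quantum_ho_energy(omega: float, T: float) -> float:
    """Exact quantum mean energy per mode, (hbar w/2) coth(beta hbar w/2)."""
    b = beta_from_T(T)
    x = 0.5 * b * HBAR * omega
    return 0.5 * HBAR * omega / math.tanh(x)


def discretized_ho_free_energy(omega: float, T: float, n_b: int) -> float:
    """Free energy of the n_b-bead ring-polymer (discretized path integral) HO.

    Closed form k_B T ln(2 sinh(n_b asinh(beta hbar omega / (2 n_b)))),
    which converges to the exact quantum result with an O(n_b^-2) error.
    """
    if n_b < 1:
        raise ParameterError("n_b must be >= 1")
    b = beta_from_T(T)
    x = float(n_b) * math.asinh(b * HBAR * omega / (2.0 * n_b))
    return KB * T * (x + math.log1p(-math.exp(-2.0 * x)))


def discretized_ho_energy(omega: float, T: float, n_b: int) -> float:
    """Mean energy of the n_b-bead HO, d(beta F)/d(beta) in closed form."""
    if n_b < 1:
        raise ParameterError("n_b must be >= 1")
    b = beta_from_T(T)
    z = b * HBAR * omega / (2.0 * n_b)
    x = float(n_b) * math.asinh(z)
    return 0.5 * HBAR * omega / (math.tanh(x) * math.sqrt(1.0 + z * z))


# ------------------------------------------------------------ toy systems
@dataclass
class ToySystem:
    """A potential with exact analytic callbacks.

    ``energy_forces(pos)`` accepts ``(..., n_atoms, 3)`` arrays;
    ``hessian(pos)`` returns the (3n x 3n) second-derivative matrix.
    ``x_min``/``e_min`` give the analytic minimum; ``omegas`` the exact
    mass-weighted normal-mode angular frequencies at the minimum (rad/ps).
    """

    masses: np.ndarray
    energy_forces: Callable
    hessian: Callable
    x_min: np.ndarray
    e_min: float
    omegas: np.ndarray
    box: float | None = None
    n_sites: int = field(init=False)

    def __post_init__(self):
        self.n_sites = len(self.masses)

    def energy(self, pos):
        return self.energy_forces(pos)[0]


def single_oscillator(omega: float, mass: float = 1.0) -> ToySystem:
    """One particle in a 3D isotropic harmonic well of frequency omega.

    The three modes are degenerate; free energies per mode follow the
    closed forms above.
    """
    if omega <= 0 or mass <= 0:
        raise ParameterError("omega and mass must be positive")
    k = mass * omega**2

    def ef(pos):
        pos = np.asarray(pos, dtype=float)
        e = 0.5 * k * (pos**2).sum(axis=(-1, -2))
        return e, -k * pos

    def hess(pos):
        return k * np.eye(3)

    return ToySystem(
        masses=np.array([mass]),
        energy_forces=ef,
        hessian=hess,
        x_min=np.zeros((1, 3)),
        e_min=0.0,
        omegas=np.full(3, omega),
    )


def harmonic_lattice(
    omegas: np.ndarray,
    masses: np.ndarray | None = None,
    e_offset: float = 0.0,
    seed: int = 0,
) -> ToySystem:
    """A coupled harmonic system with a *prescribed* frequency spectrum.

    The Hessian is built as M^1/2 Q diag(w^2) Q^T M^1/2 with a seeded random
    orthogonal Q, so diagonalizing the mass-weighted Hessian must return
    exactly ``omegas``.  The minimum sits at the origin with energy
    ``e_offset``.
    """
    omegas = np.sort(np.asarray(omegas, dtype=float))
    if np.any(omegas < 0):
        raise ParameterError("prescribed frequencies must be non-negative")
    ndof = omegas.size
    if ndof % 3:
        raise ParameterError("need a multiple of 3 frequencies (atoms in 3D)")
    n = ndof // 3
    if masses is None:
        masses = np.ones(n)
    masses = np.asarray(masses, dtype=float)
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((ndof, ndof)))
    m3 = np.repeat(masses, 3)
    Hmw = Q @ np.diag(omegas**2) @ Q.T
    H = np.sqrt(m3)[:, None] * Hmw * np.sqrt(m3)[None, :]
    H = 0.5 * (H + H.T)

    def ef(pos):
        pos = np.asarray(pos, dtype=float)
        flat = pos.reshape(pos.shape[:-2] + (ndof,))
        e = e_offset + 0.5 * np.einsum("...i,ij,...j->...", flat, H, flat)
        f = -(flat @ H.T).reshape(pos.shape)
        return e, f

    def hess(pos):
        return H.copy()

    return ToySystem(
        masses=masses,
        energy_forces=ef,
        hessian=hess,
        x_min=np.zeros((n, 3)),
        e_min=e_offset,
        omegas=omegas,
    )


def quartic_chain(
    n_atoms: int,
    k2: float = 100.0,
    k4: float = 500.0,
    kc: float = 30.0,
    x_min: np.ndarray | None = None,
    e_offset: float = -5.0,
    seed: int = 0,
) -> ToySystem:
    """Anharmonic chain with a constructed minimum and offset energy.

    E = e_offset + sum_i [ k2/2 |d_i|^2 + k4/4 |d_i|^4 ]
               + kc/2 sum_i |d_{i+1} - d_i|^2,  d_i = x_i - x_min_i.
    The global minimum is exactly ``x_min`` with energy ``e_offset``.
    """
    if k2 <= 0 or k4 < 0 or kc < 0:
        raise ParameterError("stiffnesses must be positive (k2) / non-negative")
    if x_min is None:
        rng = np.random.default_rng(seed)
        x_min = rng.uniform(-0.2, 0.2, size=(n_atoms, 3))
    x_min = np.asarray(x_min, dtype=float)

    def ef(pos):
        pos = np.asarray(pos, dtype=float)
        d = pos - x_min
        sq = (d**2).sum(axis=-1)
        e = e_offset + (0.5 * k2 * sq + 0.25 * k4 * sq**2).sum(axis=-1)
        f = -(k2 + k4 * sq[..., None]) * d
        if n_atoms > 1 and kc > 0:
            dd = d[..., 1:, :] - d[..., :-1, :]
            e = e + 0.5 * kc * (dd**2).sum(axis=(-1, -2))
            f[..., 1:, :] -= kc * dd
            f[..., :-1, :] += kc * dd
        return e, f

    def hess(pos):
        pos = np.asarray(pos, dtype=float)
        d = (pos - x_min).reshape(n_atoms, 3)
        H = np.zeros((3 * n_atoms, 3 * n_atoms))
        for i in range(n_atoms):
            sq = d[i] @ d[i]
            blk = (k2 + k4 * sq) * np.eye(3) + 2 * k4 * np.outer(d[i], d[i])
            H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += blk
        if n_atoms > 1 and kc > 0:
            I3 = np.eye(3)
            for i in range(n_atoms - 1):
                a, b = slice(3 * i, 3 * i + 3), slice(3 * i + 3, 3 * i + 6)
                H[a, a] += kc * I3
                H[b, b] += kc * I3
                H[a, b] -= kc * I3
                H[b, a] -= kc * I3
        return H

    # spectrum at the minimum (d = 0): analytic per-branch
    H0 = np.zeros((3 * n_atoms, 3 * n_atoms))
    for i in range(n_atoms):
        H0[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += k2 * np.eye(3)
    if n_atoms > 1 and kc > 0:
        I3 = np.eye(3)
        for i in range(n_atoms - 1):
            a, b = slice(3 * i, 3 * i + 3), slice(3 * i + 3, 3 * i + 6)
            H0[a, a] += kc * I3
            H0[b, b] += kc * I3
            H0[a, b] -= kc * I3
            H0[b, a] -= kc * I3
    omegas = np.sqrt(np.linalg.eigvalsh(H0))

    return ToySystem(
        masses=np.ones(n_atoms),
        energy_forces=ef,
        hessian=hess,
        x_min=x_min,
        e_min=e_offset,
        omegas=omegas,
    )


def toy_system(kind: str, size: int = 1, **params) -> ToySystem:
    """Factory by name: 'single-oscillator' | 'harmonic-lattice' | 'quartic-chain'."""
    if size < 1:
        raise ParameterError("size must be >= 1")
    if kind == "single-oscillator":
        return single_oscillator(params.get("omega", 100.0), params.get("mass", 1.0))
    if kind == "harmonic-lattice":
        omegas = params.get("omegas")
        if omegas is None:
            rng = np.random.default_rng(params.get("seed", 0))
            omegas = rng.uniform(20.0, 400.0, size=3 * size)
        return harmonic_lattice(
            omegas,
            params.get("masses"),
            params.get("e_offset", 0.0),
            params.get("seed", 0),
        )
    if kind == "quartic-chain":
        return quartic_chain(
            size,
            params.get("k2", 100.0),
            params.get("k4", 500.0),
            params.get("kc", 30.0),
            params.get("x_min"),
            params.get("e_offset", -5.0),
            params.get("seed", 0),
        )
    raise ParameterError(f"unknown toy kind {kind!r}")
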