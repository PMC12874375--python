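"""Normal-mode spectra at inherent structures and the basin shape function.

The classical frequencies {w_i,0} are square roots of the eigenvalues of
the mass-weighted Hessian H~ = H_ab / sqrt(m_a m_b) at an IS; exactly
three eigenvalues vanish (centre-of-mass translations) and all others
must be positive.  Because the ring polymers collapse at the IS, the
d*n_b ring-polymer frequencies follow from the classical ones without any
path-integral simulation:

    w_{i,j}^2 = w_{i,0}^2 / n_b^2 + (2/(hbar beta)^2) (1 - cos(2 pi j/n_b))

for j = 1..n_b.  The j = n_b member carries the bare classical
contribution (the cosine term vanishes); the 1/n_b^2 scaling of the
classical part is fixed by requiring that the free energy assembled from
this spectrum reproduces the exact discretized-path-integral harmonic
oscillator partition function at every n_b (see qpel.forcefield.toys).

The basin shape function S = sum_i ln(hbar w_i / A0) over the d*n_b - 3
retained modes is a log-measure of basin curvature; A0 = 1 kJ/mol makes
the argument dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NotAMinimumError, ParameterError
from .units import HBAR, beta_from_T, wavenumber_from_omega

#: reference constant in the shape function, kJ/mol
A0 = 1.0

#: eigenvalues below ZERO_MODE_RTOL * lambda_max count as the 3 translations
ZERO_MODE_RTOL = 1e-8


@dataclass
class FrequencySet:
    """Classical and (optionally) ring-polymer frequencies at one IS.

    Frequencies are angular, in rad/ps.  ``classical`` holds the d - 3
    positive classical modes; ``rp`` (when built) holds the d*n_b - 3
    positive ring-polymer modes.  ``e_is`` tags the IS energy per
    molecule so (e_IS, S) pairs can be formed downstream.
    """

    classical: np.ndarray
    n_zero: int
    d: int  # degrees of freedom (9N for water)
    e_is: float | None = None
    rp: np.ndarray | None = None
    n_b: int = 1
    T: float | None = None

    def wavenumbers(self, which: str = "classical") -> np.ndarray:
        freqs = self.classical if which == "classical" else self.rp
        return wavenumber_from_omega(freqs)


def mass_weighted_eigenvalues(hessian: np.ndarray, masses3: np.ndarray) -> np.ndarray:
    """Eigenvalues of H_ab / sqrt(m_a m_b), ascending."""
    inv_sqrt = 1.0 / np.sqrt(masses3)
    Hmw = hessian * inv_sqrt[:, None] * inv_sqrt[None, :]
    return np.linalg.eigvalsh(0.5 * (Hmw + Hmw.T))


def classical_frequencies(
    hessian: np.ndarray,
    masses: np.ndarray,
    e_is: float | None = None,
    expect_zero: int = 3,
) -> FrequencySet:
    """Classical normal-mode frequencies at a converged IS.

    ``masses`` is per-atom (amu); the Hessian is un-weighted (kJ/mol/nm^2).
    Exactly ``expect_zero`` near-zero eigenvalues (centre-of-mass
    translations) are excluded; any extra negative eigenvalue beyond the
    zero tolerance means the input is not a minimum.
    """
    masses3 = np.repeat(np.asarray(masses, float), 3)
    lam = mass_weighted_eigenvalues(hessian, masses3)
    d = lam.size
    tol = ZERO_MODE_RTOL * float(np.abs(lam).max())
    zero = np.abs(lam) < tol
    n_zero = int(zero.sum())
    if n_zero > expect_zero:
        raise NotAMinimumError(
            f"{n_zero} near-zero modes (expected {expect_zero}); "
            "degenerate or non-isolated minimum"
        )
    if np.any(lam < -tol):
        n_neg = int((lam < -tol).sum())
        raise NotAMinimumError(f"{n_neg} negative mass-weighted eigenvalues")
    if n_zero < expect_zero:
        raise NotAMinimumError(
            f"only {n_zero} near-zero modes where {expect_zero} translations expected"
        )
    omega = np.sqrt(lam[~zero])
    return FrequencySet(classical=np.sort(omega), n_zero=n_zero, d=d, e_is=e_is)


def rp_frequencies(freqs: FrequencySet, T: float, n_b: int) -> FrequencySet:
    """Ring-polymer frequencies from classical ones (collapse assumed).

    Every classical mode i (including the 3 zero modes) spawns n_b modes;
    the 3 combinations that stay exactly zero (zero classical part and
    j = n_b) are excluded, leaving d*n_b - 3 positive frequencies.
    """
    if n_b < 1:
        raise ParameterError("n_b must be >= 1")
    beta = beta_from_T(T)  # raises for T <= 0
    j = np.arange(1, n_b + 1)
    ring = (2.0 / (HBAR * beta) ** 2) * (1.0 - np.cos(2.0 * np.pi * j / n_b))
    w0_all = np.concatenate([np.zeros(freqs.n_zero), freqs.classical])
    lam = (w0_all[:, None] ** 2) / n_b**2 + ring[None, :]
    lam = lam.ravel()
    keep = lam > 0.0
    dropped = int((~keep).sum())
    if dropped != freqs.n_zero:
        raise NotAMinimumError(
            f"expected {freqs.n_zero} exactly-zero ring-polymer modes, found {dropped}"
        )
    return FrequencySet(
        classical=freqs.classical,
        n_zero=freqs.n_zero,
        d=freqs.d,
        e_is=freqs.e_is,
        rp=np.sort(np.sqrt(lam[keep])),
        n_b=n_b,
        T=T,
    )


def shape_function(freqs: FrequencySet, per_molecule_by: int | None = None) -> float:
    """Basin shape function S = sum ln(hbar w / A0) over retained modes.

    Uses the ring-polymer spectrum when present, otherwise the classical
    one (the classical shape function is the n_b = 1 case).  Divide by N
    via ``per_molecule_by`` to get the intensive value used in the linear
    shape law S = a + b e_IS.
    """
    w = freqs.rp if freqs.rp is not None else freqs.classical
    if np.any(w <= 0):
        raise ParameterError("non-positive retained frequency: basin not harmonic")
    s = float(np.log(HBAR * w / A0).sum())
    if per_molecule_by is not None:
        s /= per_molecule_by
    return s


def shape_function_dbeta(freqs: FrequencySet) -> float:
    """Analytic dS/dbeta at fixed e_IS for a ring-polymer frequency set.

    The beta-dependence of S enters only through the free-ring term of the
    frequency map, so
        dS/dbeta = -(1/beta) sum_i ring_i / Omega_i^2 ,
    with ring_i the (2/(hbar beta)^2)(1 - cos) part of Omega_i^2.  This is
    the derivative the harmonic vibrational energy needs; the classical
    (n_b = 1) shape function is beta-independent and returns 0.
    """
    if freqs.rp is None or freqs.T is None:
        raise ParameterError("ring-polymer spectrum required (call rp_frequencies)")
    if freqs.n_b == 1:
        return 0.0
    beta = beta_from_T(freqs.T)
    n_b = freqs.n_b
    j = np.arange(1, n_b + 1)
    ring = (2.0 / (HBAR * beta) ** 2) * (1.0 - np.cos(2.0 * np.pi * j / n_b))
    w0_all = np.concatenate([np.zeros(freqs.n_zero), freqs.classical])
    lam = (w0_all[:, None] ** 2) / n_b**2 + ring[None, :]
    frac = np.where(lam > 0, ring[None, :] / np.where(lam > 0, lam, 1.0), 0.0)
    return float(-(frac.sum()) / beta)


def is_vdos(
    freq_sets: list[FrequencySet],
    bins: int | np.ndarray = 200,
    which: str = "classical",
    range_cm: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """IS vibrational density of states, normalized over wavenumber (cm^-1).

    Averaged over the supplied IS; returns (bin_centers, density).
    """
    if not freq_sets:
        raise ParameterError("need at least one frequency set")
    all_w = np.concatenate([fs.wavenumbers(which) for fs in freq_sets])
    hist, edges = np.histogram(all_w, bins=bins, range=range_cm, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, hist
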