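"""Landscape statistics: shape law, Gaussian landscape, entropies, T_K, Adam-Gibbs.

All quantities follow the intensive (per-molecule) convention: e_IS, E0
in kJ/mol per molecule, sigma^2 in (kJ/mol)^2, alpha per molecule, the
shape function S per molecule (d = 9 degrees of freedom per molecule),
entropies in kJ/(mol K).  With Omega_IS ~ exp(alpha N) Gaussian in e_IS,

    S_IS(e_IS) = k_B [ alpha - (e_IS - E0)^2 / (2 sigma^2) ]        (per molecule)
    E_IS(T)    = E0 - sigma^2 (beta + b + B1)                       (shape law slope b)
    E_vib      = d n_b k_B T + dS/dbeta + dB0/dbeta + dB1/dbeta E_IS
    S_vib      = d n_b k_B [1 - ln(beta A0)] - k_B S + k_B beta dS/dbeta
                 + k_B [ -(B0 + B1 E_IS) + beta dB0/dbeta + beta dB1/dbeta E_IS ]

The anharmonic vibrational free energy is modeled as beta F_anh = B0(T)
+ B1(T) e_IS with B0 = c00 + c01 T + c02 T^2; c00 is unconstrained by
energies and is calibrated against the entropy decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import CubicSpline

from .errors import (
    AssemblyError,
    NoRootError,
    ParameterError,
    RankError,
)
from .spectra import A0
from .units import KB, beta_from_T

_D_PER_MOLECULE = 9  # degrees of freedom of a 3-site molecule


# ------------------------------------------------------------- containers
@dataclass
class ShapeFit:
    """Per-temperature linear shape law S = a + b e_IS (intensive)."""

    T: float
    a: float
    b: float  # (kJ/mol)^-1
    a_se: float
    b_se: float
    r2: float
    n: int


@dataclass
class LandscapeParams:
    """Gaussian-landscape parameters, T-independent by assumption."""

    alpha: float  # per molecule
    e0: float  # kJ/mol
    sigma2: float  # (kJ/mol)^2
    e0_se: float = 0.0
    sigma2_se: float = 0.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ParameterError("sigma^2 must be positive")


@dataclass
class AnharmonicCoeffs:
    """beta F_anh = B0(T) + B1(T) e_IS with B0 = c00 + c01 T + c02 T^2."""

    c00: float = 0.0
    c01: float = 0.0  # 1/K
    c02: float = 0.0  # 1/K^2
    c01_se: float = 0.0
    c02_se: float = 0.0

    def b0(self, T):
        return self.c00 + self.c01 * T + self.c02 * T**2

    def db0_dbeta(self, T):
        """dB0/dbeta = -k_B T^2 (c01 + 2 c02 T)."""
        return -KB * np.asarray(T) ** 2 * (self.c01 + 2.0 * self.c02 * np.asarray(T))


@dataclass
class AGFit:
    """Adam-Gibbs fit ln D = ln D0 + A_table / (T S_IS).

    ``a_table`` is the printed-table convention (the fitted slope, negative
    for a liquid whose D drops on cooling); ``a_eq`` = -a_table is the
    positive activation constant of D = D0 exp[-A/(T S_IS)].
    """

    d0: float  # Angstrom^2/ps
    a_table: float  # kJ/mol
    r2: float
    slope_se: float
    log_d0_se: float
    fit_range: tuple[float, float]

    @property
    def a_eq(self) -> float:
        return -self.a_table


@dataclass
class ThermoSeries:
    """Per-temperature, per-molecule series for one isotopologue."""

    T: np.ndarray
    e_total: np.ndarray  # kJ/mol
    e_is: np.ndarray  # kJ/mol
    s_shape: np.ndarray | None = None  # shape function per molecule
    entropy: np.ndarray | None = None  # kJ/(mol K)
    diffusion: np.ndarray | None = None  # Angstrom^2/ps
    isotope: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def e_vib(self) -> np.ndarray:
        return self.e_total - self.e_is

    @property
    def beta(self) -> np.ndarray:
        return 1.0 / (KB * self.T)


# ------------------------------------------------------------------- fits
def fit_shape_linear(e_is: np.ndarray, s: np.ndarray, T: float) -> ShapeFit:
    """Least-squares line through per-IS (e_IS, S) pairs at one temperature."""
    e_is = np.asarray(e_is, float)
    s = np.asarray(s, float)
    if e_is.size < 3:
        raise ParameterError("need at least 3 (e_IS, S) pairs")
    if np.ptp(e_is) < 1e-12 * max(1.0, np.abs(e_is).max()):
        raise RankError("degenerate e_IS spread; slope is unidentifiable")
    res = stats.linregress(e_is, s)
    pred = res.intercept + res.slope * e_is
    ss_tot = ((s - s.mean()) ** 2).sum()
    r2 = 1.0 - ((s - pred) ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    return ShapeFit(
        T=T,
        a=float(res.intercept),
        b=float(res.slope),
        a_se=float(res.intercept_stderr),
        b_se=float(res.stderr),
        r2=float(r2),
        n=e_is.size,
    )


def fit_gaussian_landscape(
    T: np.ndarray, e_is: np.ndarray, b: np.ndarray, alpha: float | None = None
) -> LandscapeParams:
    """E0 and sigma^2 from the harmonic Gaussian prediction E_IS = E0 - sigma^2 (beta + b).

    Linear regression of E_IS(T) against beta + b(T): intercept E0, slope
    -sigma^2.  ``alpha`` is *not* fitted here — it comes from the
    classical landscape enumeration and is attached if supplied.
    """
    T = np.asarray(T, float)
    if T.size < 3:
        raise ParameterError("need at least 3 temperatures")
    x = 1.0 / (KB * T) + np.asarray(b, float)
    res = stats.linregress(x, np.asarray(e_is, float))
    if res.slope >= 0:
        raise ParameterError(
            "fit gave non-negative slope: E_IS must decrease with beta + b"
        )
    return LandscapeParams(
        alpha=float(alpha) if alpha is not None else np.nan,
        e0=float(res.intercept),
        sigma2=float(-res.slope),
        e0_se=float(res.intercept_stderr),
        sigma2_se=float(res.stderr),
    )


# -------------------------------------------------- harmonic thermodynamics
def poly_in_beta(T: np.ndarray, values: np.ndarray, order: int = 2) -> np.polynomial.Polynomial:
    """Fit values(T) as a low-order polynomial in beta = 1/(k_B T).

    Smooth representation used to take the dS/dbeta and db/dbeta
    derivatives analytically instead of by raw finite differences.
    """
    beta = 1.0 / (KB * np.asarray(T, float))
    if beta.size <= order:
        raise ParameterError(
            f"need more than {order} temperatures for an order-{order} fit"
        )
    return np.polynomial.Polynomial.fit(beta, np.asarray(values, float), order)


def harmonic_vibrational_energy(
    T: np.ndarray, ds_dbeta: np.ndarray, n_b: int, d: int = _D_PER_MOLECULE
) -> np.ndarray:
    """E_vib^harm = d n_b k_B T + (dS/dbeta)|_{E_IS} (per molecule).

    In the classical limit (n_b = 1, T-independent S) this is d k_B T.
    """
    return d * n_b * KB * np.asarray(T, float) + np.asarray(ds_dbeta, float)


def harmonic_vibrational_entropy(
    T: np.ndarray,
    s: np.ndarray,
    ds_dbeta: np.ndarray,
    n_b: int,
    d: int = _D_PER_MOLECULE,
) -> np.ndarray:
    """S_vib^harm = d n_b k_B [1 - ln(beta A0)] - k_B S + k_B beta dS/dbeta.

    Per molecule, kJ/(mol K).
    """
    T = np.asarray(T, float)
    beta = 1.0 / (KB * T)
    return (
        d * n_b * KB * (1.0 - np.log(beta * A0))
        - KB * np.asarray(s, float)
        + KB * beta * np.asarray(ds_dbeta, float)
    )


# --------------------------------------------------- anharmonic corrections
def anharmonic_b1(
    e_is_observed: np.ndarray, e_is_harm: np.ndarray, sigma2: float
) -> np.ndarray:
    """B1(T) = -(E_IS - E_IS^harm)/sigma^2 (zero when the Gaussian+harmonic
    prediction already matches the observed IS energies)."""
    if sigma2 <= 0:
        raise ParameterError("sigma^2 must be positive")
    return -(np.asarray(e_is_observed, float) - np.asarray(e_is_harm, float)) / sigma2


def fit_anharmonic_b0(T: np.ndarray, e_vib_anh: np.ndarray) -> AnharmonicCoeffs:
    """c01, c02 from E_vib^anh(T) = dB0/dbeta = -k_B T^2 (c01 + 2 c02 T).

    The constant c00 cannot be determined from energies (it drops out of
    the beta-derivative); it is calibrated later against the entropy
    decomposition.
    """
    T = np.asarray(T, float)
    y = np.asarray(e_vib_anh, float)
    if T.size < 3:
        raise ParameterError("need at least 3 temperatures")
    X = np.column_stack([-KB * T**2, -2.0 * KB * T**3])
    coef, res_, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise RankError("temperature grid cannot separate c01 from c02")
    resid = y - X @ coef
    dof = max(T.size - 2, 1)
    cov = np.linalg.inv(X.T @ X) * (resid @ resid) / dof
    se = np.sqrt(np.diag(cov))
    return AnharmonicCoeffs(
        c00=0.0, c01=float(coef[0]), c02=float(coef[1]),
        c01_se=float(se[0]), c02_se=float(se[1]),
    )


def anharmonic_vibrational_entropy(
    T: np.ndarray, coeffs: AnharmonicCoeffs, b1=0.0, e_is=None, db1_dbeta=0.0
) -> np.ndarray:
    """S_vib^anh = k_B[-(B0 + B1 E_IS) + beta dB0/dbeta + beta dB1/dbeta E_IS]."""
    T = np.asarray(T, float)
    beta = 1.0 / (KB * T)
    e_is = 0.0 if e_is is None else np.asarray(e_is, float)
    return KB * (
        -(coeffs.b0(T) + np.asarray(b1) * e_is)
        + beta * coeffs.db0_dbeta(T)
        + beta * np.asarray(db1_dbeta) * e_is
    )


# ------------------------------------------------------ entropy machinery
def entropy_thermodynamic_integration(
    T: np.ndarray, e_total: np.ndarray, s_ref: float, t_ref: float
) -> np.ndarray:
    """S(T) = S(T_ref) + int_{T_ref}^{T} (1/T') dE/dT' dT' on the grid.

    E(T) is spline-differentiated (C_V = dE/dT at constant V) and the
    integrand 1/T' dE/dT' integrated exactly for the cubic pieces.
    """
    T = np.asarray(T, float)
    if np.any(np.diff(T) <= 0):
        raise ParameterError("temperature grid must be strictly increasing")
    spl = CubicSpline(T, np.asarray(e_total, float))
    dspl = spl.derivative()

    def integrand(t):
        return dspl(t) / t

    out = np.empty_like(T)
    from scipy.integrate import quad

    for i, t in enumerate(T):
        lo, hi = (t_ref, t) if t >= t_ref else (t, t_ref)
        val, _ = quad(integrand, lo, hi, limit=200)
        out[i] = s_ref + (val if t >= t_ref else -val)
    return out


def theoretical_s_is(e_is: np.ndarray, params: LandscapeParams) -> np.ndarray:
    """Gaussian-landscape S_IS = k_B[alpha - (e_IS - E0)^2/(2 sigma^2)], per molecule."""
    if not np.isfinite(params.alpha):
        raise AssemblyError(
            "alpha is missing: supply the classical-fit alpha in LandscapeParams"
        )
    dev = np.asarray(e_is, float) - params.e0
    return KB * (params.alpha - dev**2 / (2.0 * params.sigma2))


@dataclass
class ConfigurationalEntropyResult:
    s_is_numerical: np.ndarray
    s_is_theoretical: np.ndarray
    c00: float
    rms_mismatch: float


def configurational_entropy(
    T: np.ndarray,
    entropy: np.ndarray,
    s_vib_harm: np.ndarray,
    coeffs: AnharmonicCoeffs,
    params: LandscapeParams,
    e_is: np.ndarray,
    b1=0.0,
    db1_dbeta=0.0,
) -> ConfigurationalEntropyResult:
    """Numerical vs theoretical S_IS, calibrating the free constant c00.

    Numerical: S_IS = S - S_vib^harm - S_vib^anh(c00).  Theoretical:
    Gaussian landscape at E_IS(T).  Since c00 enters S_vib^anh only as
    -k_B c00, the least-squares calibration is the closed-form mean
    mismatch.  Returns both curves evaluated with the calibrated c00.
    """
    T = np.asarray(T, float)
    s_anh0 = anharmonic_vibrational_entropy(
        T, AnharmonicCoeffs(0.0, coeffs.c01, coeffs.c02), b1, e_is, db1_dbeta
    )
    numerical0 = np.asarray(entropy, float) - np.asarray(s_vib_harm, float) - s_anh0
    theory = theoretical_s_is(e_is, params)
    # numerical(c00) = numerical0 + k_B c00 ; minimize ||numerical - theory||^2
    c00 = float(np.mean(theory - numerical0) / KB)
    numerical = numerical0 + KB * c00
    rms = float(np.sqrt(np.mean((numerical - theory) ** 2)))
    return ConfigurationalEntropyResult(numerical, theory, c00, rms)


# ------------------------------------------------------------- T_K and AG
def kauzmann_closed_form(params: LandscapeParams, b_const: float) -> float:
    """T_K for constant b: beta_K = sqrt(2 alpha)/sigma - b (per molecule)."""
    beta_k = np.sqrt(2.0 * params.alpha) / np.sqrt(params.sigma2) - b_const
    if beta_k <= 0:
        raise NoRootError(0.0, np.inf, beta_k, np.nan)
    return 1.0 / (KB * beta_k)


def kauzmann_temperature(
    params: LandscapeParams,
    b_of_T,
    b1_of_T=None,
    bracket: tuple[float, float] = (100.0, 390.0),
    xtol: float = 0.01,
) -> float:
    """Root of S_IS(T) = 0 with E_IS(T) = E0 - sigma^2(beta + b + B1).

    Solved directly (no linearized closed form): S_IS vanishes where
    beta + b(T) + B1(T) = sqrt(2 alpha)/sigma.  Bracketed root to
    ``xtol`` kelvin; raises :class:`NoRootError` with the boundary S_IS
    values when the window contains no sign change.
    """
    if not np.isfinite(params.alpha):
        raise AssemblyError("alpha is required for the Kauzmann temperature")
    target = np.sqrt(2.0 * params.alpha / params.sigma2)

    def g(T):
        b1 = b1_of_T(T) if b1_of_T is not None else 0.0
        return beta_from_T(T) + b_of_T(T) + b1 - target

    lo, hi = bracket
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        s_lo = theoretical_s_is(params.e0 - params.sigma2 * (target + glo), params)
        s_hi = theoretical_s_is(params.e0 - params.sigma2 * (target + ghi), params)
        raise NoRootError(lo, hi, float(s_lo), float(s_hi))
    return float(optimize.brentq(g, lo, hi, xtol=xtol))


def adam_gibbs_fit(T: np.ndarray, D: np.ndarray, s_is: np.ndarray) -> AGFit:
    """Fit ln D against 1/(T S_IS) (S_IS in kJ/(mol K), D in Angstrom^2/ps).

    Slope is reported in the printed-table sign convention (negative);
    ``a_eq`` gives the positive Adam-Gibbs activation constant of
    D = D0 exp[-A/(T S_IS)].
    """
    T = np.asarray(T, float)
    D = np.asarray(D, float)
    s_is = np.asarray(s_is, float)
    bad = (D <= 0) | (s_is <= 0)
    if np.any(bad):
        raise ParameterError(
            f"non-positive D or S_IS at T = {T[bad].tolist()}; AG fit undefined"
        )
    x = 1.0 / (T * s_is)
    if np.ptp(x) < 1e-12 * np.abs(x).max():
        raise RankError("T*S_IS is constant: AG design matrix is rank deficient")
    res = stats.linregress(x, np.log(D))
    pred = res.intercept + res.slope * x
    y = np.log(D)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ((y - pred) ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    return AGFit(
        d0=float(np.exp(res.intercept)),
        a_table=float(res.slope),
        r2=float(r2),
        slope_se=float(res.stderr),
        log_d0_se=float(res.intercept_stderr),
        fit_range=(float(x.min()), float(x.max())),
    )


# ------------------------------------------------------------ free energy
def helmholtz_assembly(
    T: np.ndarray,
    params: LandscapeParams,
    b: np.ndarray,
    s: np.ndarray,
    coeffs: AnharmonicCoeffs,
    s_is: np.ndarray,
    n_b: int,
    d: int = _D_PER_MOLECULE,
) -> dict[str, np.ndarray]:
    """Per-molecule Helmholtz free energy and its decomposition.

    F = E0 - sigma^2(beta + b) + d n_b k_B T ln(beta A0) + k_B T S
        + B0/beta - T S_IS
    """
    for name, val in [("b", b), ("S", s), ("S_IS", s_is)]:
        if val is None:
            raise AssemblyError(f"missing component {name!r} in free-energy assembly")
    T = np.asarray(T, float)
    beta = 1.0 / (KB * T)
    e_is = params.e0 - params.sigma2 * (beta + np.asarray(b, float))
    f_vib = (
        d * n_b * KB * T * np.log(beta * A0)
        + KB * T * np.asarray(s, float)
        + coeffs.b0(T) / beta
    )
    f = e_is - T * np.asarray(s_is, float) + f_vib
    return {"F": f, "E_IS": e_is, "F_vib": f_vib, "TS_IS": T * np.asarray(s_is, float)}
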