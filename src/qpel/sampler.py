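"""NVT samplers: classical Langevin MD and PILE-thermostatted RPMD.

The ring-polymer sampler uses the path-integral Langevin-equation (PILE)
scheme: exact normal-mode propagation of the free ring polymer between
force kicks, with each internal mode thermostatted at twice its own
frequency and the centroid at a configurable friction gamma (the "local"
PILE).  Both integrators are strictly deterministic given (seed, spec).

Diffusion coefficients come from the slope of the molecular
center-of-mass mean-square displacement (centroid positions for RPMD);
positions are never wrapped, so trajectories are natively unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy import stats

from .errors import IntegrationFailureError, ParameterError, SamplingError
from .ringpolymer import RPState
from .topology import Topology
from .units import HBAR, KB, beta_from_T

_ENERGY_BLOWUP = 1e10  # kJ/mol


@dataclass
class RunSpec:
    """Sampling run specification.

    Defaults follow the study protocol: dt = 0.25 fs for ring-polymer
    runs and 0.5 fs for classical MD, thermostat friction gamma =
    0.1 1/ps, n_b = 32 beads.  ``n_steps`` counts production steps taken
    after ``equilibration`` discarded steps; every random number is drawn
    from ``seed``.
    """

    T: float
    dt: float = 0.5e-3  # ps
    n_steps: int = 1000
    gamma: float = 0.1  # 1/ps
    n_b: int = 32
    seed: int = 0
    stride: int = 10
    equilibration: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.n_steps < 1 or self.stride < 1:
            raise ParameterError("dt, n_steps and stride must be positive")
        beta_from_T(self.T)


@dataclass
class Trajectory:
    """Uniformly strided frames of a sampling run."""

    times: np.ndarray  # ps
    positions: np.ndarray  # (n_frames, n_atoms, 3); centroids for RPMD
    energies: np.ndarray  # instantaneous potential energy, kJ/mol
    kinetic: np.ndarray  # instantaneous kinetic energy, kJ/mol
    spec: RunSpec
    topology: Topology | None = None
    box: float | None = None
    aux: dict = field(default_factory=dict)  # estimator pieces, bead frames

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _check_energy(e: float, step: int):
    if not np.isfinite(e) or abs(e) > _ENERGY_BLOWUP:
        raise IntegrationFailureError(step, f"potential energy {e!r}")


def boltzmann_velocities(rng, masses3, T: float) -> np.ndarray:
    """Maxwell-Boltzmann draw; masses3 broadcasts against the shape."""
    return rng.standard_normal(masses3.shape) * np.sqrt(KB * T / masses3)


def run_classical_nvt(potential, positions: np.ndarray, spec: RunSpec) -> Trajectory:
    """BAOAB Langevin sampling of exp(-beta U) at temperature spec.T.

    ``potential`` exposes ``energy_forces`` and ``masses``; ``positions``
    is the (n_atoms, 3) start.  The time-averaged kinetic energy per
    degree of freedom equals k_B T/2 at stationarity.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.array(positions, dtype=float)
    m = np.repeat(np.asarray(potential.masses, float)[:, None], 3, axis=1)
    v = boltzmann_velocities(rng, m, spec.T)
    dt = spec.dt
    c1 = np.exp(-spec.gamma * dt)
    c2 = np.sqrt((1.0 - c1**2) * KB * spec.T / m)

    e, f = potential.energy_forces(x)
    frames_t, frames_x, frames_e, frames_k = [], [], [], []
    total = spec.equilibration + spec.n_steps
    for step in range(total):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(v.shape)
        x += 0.5 * dt * v
        e, f = potential.energy_forces(x)
        _check_energy(float(e), step)
        v += 0.5 * dt * f / m
        prod = step - spec.equilibration
        if prod >= 0 and prod % spec.stride == 0:
            frames_t.append(prod * dt)
            frames_x.append(x.copy())
            frames_e.append(float(e))
            frames_k.append(0.5 * float((m * v**2).sum()))
    return Trajectory(
        np.array(frames_t),
        np.array(frames_x),
        np.array(frames_e),
        np.array(frames_k),
        spec,
        getattr(potential, "topology", None),
        getattr(potential, "box", None),
    )


def _nm_transform(n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal free-ring normal-mode matrix C and mode index array."""
    k = np.arange(n_b)
    C = np.empty((n_b, n_b))
    C[0] = np.sqrt(1.0 / n_b)
    for j in range(1, n_b // 2 + (n_b % 2)):
        C[j] = np.sqrt(2.0 / n_b) * np.cos(2 * np.pi * j * k / n_b)
    if n_b % 2 == 0 and n_b > 1:
        C[n_b // 2] = np.sqrt(1.0 / n_b) * (-1.0) ** k
    for j in range(n_b // 2 + 1, n_b):
        C[j] = np.sqrt(2.0 / n_b) * np.sin(2 * np.pi * j * k / n_b)
    return C, k


def free_rp_mode_frequencies(T: float, n_b: int) -> np.ndarray:
    """Angular frequencies of the free-ring normal modes, (2/hbar beta) sin(pi j/n_b)."""
    beta = beta_from_T(T)
    j = np.arange(n_b)
    return (2.0 / (HBAR * beta)) * np.sin(np.pi * j / n_b)


def run_rpmd_nvt(
    potential, state: RPState, spec: RunSpec, store_beads: bool = True
) -> Trajectory:
    """PILE-thermostatted dynamics of the ring-polymer system.

    Samples the classical Boltzmann distribution exp(-beta U_RP) with bead
    masses m' = n_b m.  Frames store centroid positions; ``aux`` carries
    the spring energy and mean slice potential needed by the primitive
    quantum-energy estimator, plus full bead frames when requested.
    """
    n_b = state.n_b
    if n_b != spec.n_b:
        raise ParameterError(f"state has n_b={n_b} but spec.n_b={spec.n_b}")
    rng = np.random.default_rng(spec.seed)
    params = state.params
    k_sp = params.k_sp
    mprime = np.repeat(params.bead_masses[:, None], 3, axis=1)  # (n_atoms, 3)
    x = state.positions.copy()  # (n_b, n_atoms, 3)
    p = boltzmann_velocities(rng, np.broadcast_to(mprime, x.shape), spec.T) * mprime

    C, _ = _nm_transform(n_b)
    omg = free_rp_mode_frequencies(spec.T, n_b)
    dt = spec.dt
    gam = np.where(np.arange(n_b) == 0, spec.gamma, 2.0 * omg)
    c1 = np.exp(-0.5 * gam * dt)[:, None, None]
    c2 = np.sqrt((1.0 - c1**2) * KB * spec.T * mprime[None, :, :])
    # exact free-ring evolution coefficients per mode
    cos_wt = np.cos(omg * dt)[:, None, None]
    sin_wt = np.sin(omg * dt)[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_over = np.where(omg > 0, np.sin(omg * dt) / np.where(omg > 0, omg, 1.0), dt)[
            :, None, None
        ]

    def physical_forces(x):
        e_slices, f_slices = potential.energy_forces(x)
        return e_slices, f_slices / n_b

    e_slices, f = physical_forces(x)
    frames = {"t": [], "x": [], "e": [], "k": [], "spring": [], "ubar": [],
              "beads": [], "nm_ke": []}
    total = spec.equilibration + spec.n_steps
    for step in range(total):
        # O (half) in normal modes
        pn = np.einsum("jk,kal->jal", C, p)
        pn = c1 * pn + c2 * rng.standard_normal(pn.shape)
        # B (half)
        p = np.einsum("jk,jal->kal", C, pn) + 0.5 * dt * f
        # A: exact free-ring-polymer drift
        pn = np.einsum("jk,kal->jal", C, p)
        xn = np.einsum("jk,kal->jal", C, x)
        xn_new = xn * cos_wt + (pn / mprime[None, :, :]) * sin_over
        pn_new = pn * cos_wt - (mprime[None, :, :] * omg[:, None, None] ** 2) * xn * sin_over
        xn, pn = xn_new, pn_new
        x = np.einsum("jk,jal->kal", C, xn)
        # B (half)
        e_slices, f = physical_forces(x)
        _check_energy(float(np.mean(e_slices)), step)
        p = np.einsum("jk,jal->kal", C, pn) + 0.5 * dt * f
        # O (half)
        pn = np.einsum("jk,kal->jal", C, p)
        pn = c1 * pn + c2 * rng.standard_normal(pn.shape)
        p = np.einsum("jk,jal->kal", C, pn)

        prod = step - spec.equilibration
        if prod >= 0 and prod % spec.stride == 0:
            diff = np.roll(x, -1, axis=0) - x
            spring = 0.5 * float((k_sp[None, :] * (diff**2).sum(axis=-1)).sum())
            ubar = float(np.mean(e_slices))
            frames["t"].append(prod * dt)
            frames["x"].append(x.mean(axis=0))
            frames["e"].append(spring + ubar)
            frames["k"].append(0.5 * float((p**2 / mprime[None, :, :]).sum()))
            frames["spring"].append(spring)
            frames["ubar"].append(ubar)
            pn_obs = np.einsum("jk,kal->jal", C, p)
            frames["nm_ke"].append(
                0.5 * (pn_obs**2 / mprime[None, :, :]).sum(axis=(1, 2))
            )
            if store_beads:
                frames["beads"].append(x.copy())

    aux = {
        "spring": np.array(frames["spring"]),
        "ubar": np.array(frames["ubar"]),
        "nm_ke": np.array(frames["nm_ke"]),  # per-frame, per-mode kinetic energy
        "n_b": n_b,
    }
    if store_beads:
        aux["beads"] = np.array(frames["beads"])
    return Trajectory(
        np.array(frames["t"]),
        np.array(frames["x"]),
        np.array(frames["e"]),
        np.array(frames["k"]),
        spec,
        state.topology,
        state.box,
        aux,
    )


def quantum_energy_estimate(traj: Trajectory) -> tuple[float, float]:
    """Primitive path-integral energy estimator with its standard error.

    E = d n_b/(2 beta) - <E_spring> + <U_bar>, d = 3 n_atoms.
    """
    if "spring" not in traj.aux:
        raise SamplingError("trajectory carries no ring-polymer estimator data")
    n_atoms = traj.positions.shape[1]
    d = 3 * n_atoms
    n_b = traj.aux["n_b"]
    beta = beta_from_T(traj.spec.T)
    samples = d * n_b / (2.0 * beta) - traj.aux["spring"] + traj.aux["ubar"]
    n = len(samples)
    if n < 2:
        return float(samples.mean()), np.inf
    # block averaging: successive frames are strongly correlated
    n_blocks = min(16, n // 4) or 1
    blocks = np.array_split(samples, n_blocks)
    means = np.array([b.mean() for b in blocks])
    se = means.std(ddof=1) / np.sqrt(n_blocks) if n_blocks > 1 else np.inf
    return float(samples.mean()), float(se)


def molecular_com(traj: Trajectory) -> np.ndarray:
    """Molecular center-of-mass positions (n_frames, N, 3)."""
    if traj.topology is None:
        raise SamplingError("trajectory has no topology for molecular COM")
    topo = traj.topology
    pos = traj.positions.reshape(traj.n_frames, topo.n_molecules, 3, 3)
    w = topo.masses.reshape(topo.n_molecules, 3)
    w = w / w.sum(axis=1, keepdims=True)
    return np.einsum("fmsx,ms->fmx", pos, w)


@dataclass
class DiffusionResult:
    D: float  # Angstrom^2/ps
    stderr: float
    r2: float
    exponent: float  # log-log MSD slope; 1 = diffusive, 2 = ballistic
    window: tuple[float, float]  # ps
    nondiffusive: bool
    msd_times: np.ndarray
    msd: np.ndarray  # nm^2


def diffusion_coefficient(
    traj: Trajectory,
    fit_window: tuple[float, float] = (0.3, 0.9),
    r2_threshold: float = 0.9,
) -> DiffusionResult:
    """D from the MSD slope of molecular (or atomic) centers of mass.

    MSD is averaged over all time origins and molecules; the straight-line
    fit MSD = 6 D t + c runs over the lag fraction ``fit_window`` of the
    longest lag.  ``nondiffusive`` is flagged when the log-log MSD slope
    over the window departs from 1 by more than 0.3 (ballistic growth has
    slope 2, a caged/frozen system < 0.7) or when R^2 of the linear fit
    falls below ``r2_threshold``.
    """
    if traj.topology is not None:
        com = molecular_com(traj)
    else:
        com = traj.positions
    n_frames = com.shape[0]
    if n_frames < 4:
        raise SamplingError("too few frames for an MSD fit")
    # short lags only: MSD estimates at lags comparable to the trajectory
    # length average over too few independent intervals to be usable;
    # at most ~200 lags are evaluated (the fit gains nothing from more)
    max_lag = max(n_frames // 4, 2)
    lags = np.unique(np.linspace(1, max_lag, min(max_lag, 200)).astype(int))
    msd = np.empty(lags.size)
    for i, lag in enumerate(lags):
        d = com[lag:] - com[:-lag]
        msd[i] = (d**2).sum(axis=-1).mean()
    t = lags * (traj.times[1] - traj.times[0])

    lo = int(fit_window[0] * lags.size)
    hi = max(int(fit_window[1] * lags.size), lo + 2)
    tt, mm = t[lo:hi], msd[lo:hi]
    A = np.vstack([tt, np.ones_like(tt)]).T
    coef, res, *_ = np.linalg.lstsq(A, mm, rcond=None)
    slope = coef[0]
    pred = A @ coef
    ss_tot = ((mm - mm.mean()) ** 2).sum()
    r2 = 1.0 - ((mm - pred) ** 2).sum() / ss_tot if ss_tot > 0 else 1.0
    dof = len(tt) - 2
    if dof > 0 and ss_tot > 0:
        sigma2 = ((mm - pred) ** 2).sum() / dof
        sxx = ((tt - tt.mean()) ** 2).sum()
        slope_se = np.sqrt(sigma2 / sxx)
    else:
        slope_se = 0.0
    frozen = msd.max() < 1e-16
    D_nm = 0.0 if frozen else slope / 6.0
    if frozen or np.any(mm <= 0):
        exponent = 0.0
    else:
        lg = stats.linregress(np.log(tt), np.log(mm))
        exponent = float(lg.slope)
    nondiff = (not frozen) and (r2 < r2_threshold or abs(exponent - 1.0) > 0.3)
    return DiffusionResult(
        D=float(D_nm * 100.0),
        stderr=float(slope_se / 6.0 * 100.0),
        r2=float(r2),
        exponent=exponent,
        window=(float(tt[0]), float(tt[-1])),
        nondiffusive=bool(nondiff),
        msd_times=t,
        msd=msd,
    )
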