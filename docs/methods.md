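# Methods

This note records the models, conventions, numerical choices and known
limitations behind `qpel`, in the package's own terms. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Units and constants

Internal units are amu, nm, ps, kJ/mol — mutually consistent
(1 kJ/mol = 1 amu·nm²/ps²), so no conversions appear inside force or
integration loops. ħ = 0.0635078 kJ·ps/mol and k_B = 8.31446e-3 kJ/(mol K)
are CODATA-2018 values in these units. Coordinates on disk (XYZ) are in Å;
frequencies are reported in cm⁻¹; entropies in output tables in J/(mol K).
All landscape quantities (e_IS, E0, σ², α, S_IS, the shape function S and
its slope b) follow the intensive per-molecule convention, with d = 9
degrees of freedom per molecule.

## Water model

The force field is the q-TIP4P/F functional form: a quartic expansion of a
Morse potential for the O–H stretch, a harmonic HOH bend, Lennard-Jones on
oxygen, and charges on the H sites and a massless M site on the bisector
(r_M = γr_O + (1−γ)(r_H1+r_H2)/2). Numeric constants are transcribed from
the model's source publication (Habershon, Markland & Manolopoulos, J.
Chem. Phys. 131, 024501 (2009)) into `src/qpel/forcefield/qtip4pf.toml`;
the engine is parameter-file-driven, so any TIP4P-type flexible model can
be substituted. Forces on the M site are redistributed to the three massive
sites by the (constant, linear) chain rule, keeping 9N dynamical degrees of
freedom.

Electrostatics use the conducting-boundary reaction field
(E ∝ 1/r + r²/2r_c³ − 3/2r_c), which is energy- *and* force-continuous at
the cutoff. The Lennard-Jones term is force-shifted (energy and force both
vanish at r_c): at the paper-scale cutoff of 1.0 nm the modification is
negligible, while in small study boxes — where the cutoff is capped just
below L/2 to keep the minimum-image convention valid — a bare cut-shift
would leave an O(10²) kJ/mol/nm force discontinuity that stalls
minimizers. Long-range tail corrections are omitted (constant-volume,
fixed-cutoff study; they shift absolute energies by a constant at fixed
density).

### Hessians

All radial pair terms (stretch, LJ, reaction-field Coulomb including the
M-site projection J^T H_sites J) have exact analytic second derivatives;
the bend block uses central finite differences of its *analytic gradient*
(9 coordinates per molecule, step 1e-6 nm — machine-accurate for a
harmonic-in-angle term). An independent full finite-difference-of-forces
Hessian (`hessian_fd`, step 1e-5 nm) serves as the oracle; the two agree to
~2e-8 relative on random boxes. Mass weighting
H̃ = H_ab/√(m_a m_b) is applied only in `qpel.spectra`, so one Hessian
serves every isotopologue.

## Ring-polymer system

Bead masses are m' = n_b·m and spring constants k^sp = m·n_b/(ħβ)²; springs
connect beads of one atom without minimum imaging (rings stay unwrapped),
while the physical potential is evaluated per bead slice with minimum
imaging inside. The free-ring normal-mode frequencies are
ω_j = (2/ħβ)·sin(πj/n_b).

The classical→ring-polymer frequency map is implemented as

    ω_{i,j}² = ω_{i,0}²/n_b² + (2/(ħβ)²)(1 − cos(2πj/n_b)),  j = 1..n_b.

The placement of n_b (dividing the classical part) is fixed by requiring
that the free energy assembled from this spectrum reproduce the exact
discretized-path-integral harmonic-oscillator partition function at every
n_b — in closed form, ∏_j βħΩ_j = 2 sinh(n_b·asinh(βħω₀/2n_b)) — which
converges to the exact quantum result with an O(n_b⁻²) error. The test
suite asserts this identity to 1e-10. A consequence worth recording: at
n_b = 32 the primitive discretization error of the free energy is
≈ (βħω)²/(24 n_b²), i.e. ~1.9% at 200 K for a 3000 cm⁻¹ mode and below 1%
only above roughly 280 K. The 3 zero modes of the classical Hessian
(centre-of-mass translations) spawn 3 exactly-zero ring-polymer modes
(zero classical part, j = n_b), which are excluded; all d·n_b − 3 retained
modes are positive at an IS.

The β-derivative of the shape function at fixed e_IS, needed by the
harmonic vibrational energy E_vib = d·n_b·k_BT + ∂S/∂β, is analytic:
∂S/∂β = −(1/β) Σ ring_i/Ω_i², since β enters only through the free-ring
term.

## Samplers

Classical NVT uses BAOAB Langevin; ring-polymer NVT uses the "local" PILE
scheme — exact normal-mode propagation of the free ring polymer between
half force kicks (OBABO), internal-mode frictions γ_j = 2ω_j, centroid
friction γ (default 0.1 ps⁻¹; thermalization-oriented tests use larger γ
to shorten energy autocorrelation times). Every O, A and B sub-map
preserves the exact free-ring Gibbs measure, so free-ring mode
temperatures carry no time-step bias. Defaults follow the study protocol:
dt = 0.25 fs (ring-polymer), 0.5 fs (classical), n_b = 32. Both
integrators are bit-deterministic given (seed, spec). The quantum energy
estimator is the primitive one, E = d·n_b/2β − ⟨E_spring⟩ + ⟨Ū⟩, with a
block-averaged standard error (16 blocks) because successive frames are
strongly correlated.

Positions are never wrapped, so molecular-centre-of-mass trajectories are
natively unwrapped for mean-square displacements. D = slope(MSD)/6 is fit
over a configurable window of lags capped at a quarter of the trajectory
(longer lags average too few independent intervals); at most ~200 lags are
evaluated. A log-log MSD slope far from 1 (ballistic ≈ 2, caged < 0.7) or
a poor linear fit flags the result non-diffusive.

## Inherent structures

Minimization is L-BFGS-B on the analytic gradient, finished by damped
Newton steps using the analytic (ring-polymer) Hessian with a
pseudo-inverse that projects out the translational null space — L-BFGS
line searches stall at the energy round-off floor (~1e-5 kJ/mol/nm
gradients) while Newton reaches 1e-10 and below. Default gradient
tolerance: 1e-6 kJ/mol/nm (inf-norm); idempotence of re-minimization holds
to 1e-10 in energy. 25 IS per temperature, taken from equally spaced
frames, is the study default. Distinct IS are not deduplicated (the
formalism averages over sampled IS regardless of multiplicity).

Scaled-down sampling protocol (`run_classical_is_study`): several
independent *annealing chains* per study — each chain equilibrates at the
highest temperature and is cooled through the grid, re-thermalized and
sampled at each step. At picosecond run lengths, independent cold starts
do not relax at all and their IS level is equilibration-history noise;
annealed chains at least move downhill the way the supercooled liquid
does, which is what makes the E_IS(240 K) < E_IS(300 K) signal resolvable
at N = 8.

## Landscape statistics

- Shape fits: per-IS (e_IS, S) pairs at one T, ordinary least squares
  (each IS contributes one pair; no energy binning).
- a(T), b(T) are smoothed as *linear* polynomials in β before any
  derivative or extrapolation: both laws are near-linear over the studied
  window, and higher orders are unstable when extrapolated toward T_K.
- The Gaussian fit E_IS = E0 − σ²(β+b) uses the smoothed b (per-T slope
  noise on the regressor would attenuate σ² — errors-in-variables) and is
  restricted to the Gaussian-validity window, default T ≤ 280 K, where
  B̃1 ≈ 0.
- α is never refit from quantum data; it comes from the classical
  landscape enumeration and is supplied to the chain.
- c01, c02 come from E_vib^anh(T) = −k_BT²(c01 + 2c02T); c00 is
  undetermined by energies and is calibrated in closed form against the
  entropy decomposition (it enters S_vib^anh only as −k_B·c00).
- T_K is the bracketed root of S_IS(T) = 0 (equivalently
  β + b(T) + B̃1(T) = √(2α)/σ), tolerance 0.01 K; the constant-b closed
  form β_K = √(2α)/σ − b is kept as a cross-check. A linearized closed
  form without the square root is *not* used — it does not follow from
  the Gaussian expression.
- Adam–Gibbs: ln D regressed on 1/(T·S_IS) with S_IS in kJ/(mol K);
  `a_table` is the fitted slope (negative, matching the printed-table
  sign convention), `a_eq = −a_table` the positive activation constant.
- Entropy by thermodynamic integration: S(T) = S(T_ref) + ∫ (1/T')
  (dE/dT') dT' with a cubic-spline dE/dT, against a supplied reference
  value (analytic for toy systems; configurable for water — the absolute
  water entropy scale depends on that reference).

### Uncertainties

Per-stage regression SEs miss the dominant error source: per-T shape-fit
noise propagates through smooth intermediate curves, so downstream
residuals stay small while parameters shift coherently. Reported SEs for
(E0, σ², c01, c02, D0, A) therefore come from a chain-level parametric
bootstrap: each shape fit is re-expressed in its independent error
components (the line's value at the per-T mean of e_IS, and the slope —
raw intercept and slope are almost perfectly anticorrelated), observation
noises are estimated from visible residuals around the smooth fits,
redrawn 200 times, and pushed through the deterministic chain. Against 200
independent synthetic replicates these SEs match the empirical scatter to
~10% and give ≥97% coverage at 3 SE.

## Synthetic generator

The generator (`qpel.synthetic`) emulates exactly the statistical
structure the fits assume: Gaussian IS energies with the physical
finite-size spread σ/√N; frequency sets built by sampling log-frequencies
and rigidly shifting them so the shape function hits its target exactly; a
thermodynamically closed (E, E_IS, E_vib, S) series in which every
downstream identity (entropy decomposition, F = E − TS) holds exactly at
zero noise; and an Adam–Gibbs diffusion series with lognormal noise.
`noise_scale` multiplies only the extra observation noises (shape scatter
0.02 per molecule, chosen so per-T slope SEs are ~15%, the scale of
visible error bars in full-scale shape fits; diffusion noise 5%).

Defaults are the printed full-scale values wherever those exist (E0, σ²
from the classical landscape; per-isotope c00, c01, c02; per-isotope
Adam–Gibbs D0, A). Three structural choices were open and were made once:

- **α = 6.6 per molecule.** The landscape enumeration constant is not
  printed in the source study (it comes from earlier classical work).
  Within a Gaussian landscape with the printed σ² and a monotone b(T),
  the reported absolute Kauzmann temperatures and a > 100× diffusion span
  over 200–400 K cannot both hold; α = 6.6 preserves the reported
  *differences* in T_K across isotopes and the > two-orders-of-magnitude
  Adam–Gibbs span, at the cost of absolute T_K values ~9 K above the
  reported ones.
- **b(β) = b_cl − c_iso·β** with a common classical intercept
  b_cl = 0.20 (kJ/mol)⁻¹: every quantum curve rises toward the classical
  value on heating, heavier isotopes lie closer to it, and the c_iso are
  set by the reported T_K gaps through Δβ_K = −Δb(T_K).
- **a(β) = a0 + a1·β** per isotope: the β-linear part is pure zero-point
  content — it shifts E but cancels exactly in the entropy — so the a1
  increments are sized to the reported ~22 kJ/mol H2O–T2O total-energy
  gap, while the β-independent a0 offsets set the vibrational-entropy
  spread (S_vib^harm ≈ −k_B·S), sized to the reported ≤ 15 J/(mol K)
  isotope spread in S(T).

What the generator does *not* emulate: molecular trajectories, realistic
absolute entropy/shape magnitudes (only the landscape-level parameters are
matched), T-dependent B̃1, or correlations between shape scatter and IS
energy. Passing synthetic tests therefore validate the statistical chain,
not the force field or the samplers — those are validated separately
against analytic oracles and scaled-down simulation.

## Problem sizes

Tests and the acceptance script run N = 8 molecule boxes (box edge
0.62 nm at v = 18.0 cm³/mol, cutoff capped at L/2), picosecond MD/RPMD
runs, 18–28 IS per temperature across 3–4 annealing chains, and synthetic
studies at the full N = 512 / 25-IS / 11-temperature conditions. These
sizes keep the whole suite within a few minutes on one core. What survives
the scale-down quantitatively: everything spectral/zero-point (the
H2O–T2O gap lands within ~5% of the full-scale value; band positions and
isotope shifts are robust), the collapse property, and all closed-form
identities. What does not: absolute E0/σ² from simulation (the E_IS(T)
trend at N = 8 is comparable to trap-to-trap scatter), per-isotope b(T)
orderings at fixed T (resolvable only in sign of the T-trend), and
absolute entropies (no experimental reference is bundled).

## Known limitations

- Electrostatics are reaction-field only; no Ewald/PME, no polarizable or
  ab-initio potentials, no rigid-water models.
- RPMD here is thermostatted sampling plus approximate dynamics for D;
  no rate theory, no ring-polymer contraction.
- The equation-of-state/pressure route (volume derivatives of the
  landscape parameters) is out of scope, as are H/D mixtures.
- HDO means 100% singly-substituted molecules — a useful model system,
  not an experimentally preparable liquid.
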