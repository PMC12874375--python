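"""Landscape statistics: fits, thermodynamic assemblies, T_K, Adam-Gibbs."""

import numpy as np
import pytest

from qpel.errors import AssemblyError, NoRootError, ParameterError, RankError
from qpel.forcefield import harmonic_lattice
from qpel.landscape import (
    AGFit,
    AnharmonicCoeffs,
    LandscapeParams,
    adam_gibbs_fit,
    anharmonic_b1,
    anharmonic_vibrational_entropy,
    configurational_entropy,
    entropy_thermodynamic_integration,
    fit_anharmonic_b0,
    fit_gaussian_landscape,
    fit_shape_linear,
    harmonic_vibrational_energy,
    harmonic_vibrational_entropy,
    kauzmann_closed_form,
    kauzmann_temperature,
    poly_in_beta,
    theoretical_s_is,
)
from qpel.spectra import A0
from qpel.units import HBAR, KB


class TestShapeLaw:
    def test_noiseless_line_recovered_exactly(self):
        e = np.linspace(-60, -55, 12)
        a_true, b_true = 120.0, 0.21
        fit = fit_shape_linear(e, a_true + b_true * e, T=260.0)
        assert abs(fit.a - a_true) < 1e-10
        assert abs(fit.b - b_true) < 1e-10

    def test_monte_carlo_coverage_of_b(self):
        """Recovered slope lies within 3 SE of truth in ~all of 200 replicates."""
        rng = np.random.default_rng(7)
        e = np.linspace(-61, -58, 25)
        b_true, sd = 0.2, 0.05
        hits = 0
        for _ in range(200):
            s = 100.0 + b_true * e + sd * rng.standard_normal(e.size)
            fit = fit_shape_linear(e, s, T=240.0)
            hits += abs(fit.b - b_true) <= 3 * fit.b_se
        assert hits >= 190

    def test_degenerate_spread_raises(self):
        with pytest.raises(RankError):
            fit_shape_linear(np.full(10, -60.0), np.linspace(0, 1, 10), T=250.0)

    def test_too_few_pairs(self):
        with pytest.raises(ParameterError):
            fit_shape_linear(np.array([-60.0, -59.0]), np.array([1.0, 2.0]), T=250.0)


class TestGaussianLandscape:
    def test_exact_round_trip(self):
        T = np.arange(200.0, 401.0, 20.0)
        beta = 1.0 / (KB * T)
        b = 0.2 - 0.1 * beta
        e0, s2 = -52.5, 15.0
        e_is = e0 - s2 * (beta + b)
        p = fit_gaussian_landscape(T, e_is, b, alpha=6.6)
        assert abs(p.e0 - e0) < 1e-9
        assert abs(p.sigma2 - s2) < 1e-9

    def test_classical_limit_b_zero(self):
        T = np.array([220.0, 260.0, 300.0, 340.0])
        beta = 1.0 / (KB * T)
        e_is = -52.5 - 15.0 * beta
        p = fit_gaussian_landscape(T, e_is, np.zeros_like(T))
        assert abs(p.sigma2 - 15.0) < 1e-9

    def test_needs_three_temperatures(self):
        with pytest.raises(ParameterError):
            fit_gaussian_landscape(
                np.array([240.0, 260.0]), np.array([-60.0, -59.0]), np.zeros(2)
            )


class TestHarmonicThermo:
    def test_classical_reduction_d_kt(self):
        T = np.array([250.0, 300.0])
        e = harmonic_vibrational_energy(T, np.zeros(2), n_b=1)
        assert np.allclose(e, 9 * KB * T, rtol=1e-12)

    def test_linear_s_in_beta_adds_constant(self):
        # S(beta) = c*beta at fixed E_IS -> dS/dbeta = c exactly
        T = np.linspace(210, 390, 10)
        c = -47.0
        p = poly_in_beta(T, c / (KB * T), order=2)
        d = p.deriv()
        assert np.abs(d(1.0 / (KB * T)) - c).max() < 1e-6 * abs(c)

    def test_classical_entropy_formula(self):
        T = np.array([260.0])
        s_val = np.array([210.0])
        out = harmonic_vibrational_entropy(T, s_val, np.zeros(1), n_b=1)
        beta = 1.0 / (KB * T)
        expected = 9 * KB * (1 - np.log(beta * A0)) - KB * s_val
        assert np.allclose(out, expected, rtol=1e-12)

    def test_wider_basins_mean_larger_entropy(self):
        T = np.array([260.0])
        lo = harmonic_vibrational_entropy(T, np.array([250.0]), np.zeros(1), 32)
        hi = harmonic_vibrational_entropy(T, np.array([240.0]), np.zeros(1), 32)
        assert hi > lo  # smaller shape function (wider basins) -> more entropy


class TestAnharmonic:
    def test_b1_zero_when_prediction_matches(self):
        e = np.linspace(-60, -58, 5)
        assert np.abs(anharmonic_b1(e, e, 15.0)).max() == 0.0

    def test_b1_algebraic_inversion(self):
        e = np.linspace(-60, -58, 5)
        delta = 0.37
        b1 = anharmonic_b1(e + delta, e, 15.0)
        assert np.allclose(b1, -delta / 15.0, rtol=1e-12)

    def test_b1_requires_positive_sigma2(self):
        with pytest.raises(ParameterError):
            anharmonic_b1(np.zeros(3), np.zeros(3), 0.0)

    def test_b0_exact_recovery(self):
        T = np.arange(200.0, 401.0, 25.0)
        c01, c02 = 0.0113, -1.998e-5
        e_anh = -KB * T**2 * (c01 + 2 * c02 * T)
        co = fit_anharmonic_b0(T, e_anh)
        assert abs(co.c01 - c01) < 1e-12
        assert abs(co.c02 - c02) < 1e-16

    def test_zero_coefficients_zero_series(self):
        co = AnharmonicCoeffs(0.0, 0.0, 0.0)
        assert np.all(co.db0_dbeta(np.array([200.0, 300.0])) == 0.0)

    def test_b0_needs_three_points(self):
        with pytest.raises(ParameterError):
            fit_anharmonic_b0(np.array([240.0, 260.0]), np.zeros(2))


class TestEntropyTI:
    def test_harmonic_lattice_closed_form(self):
        """TI entropy vs the classical harmonic closed form, to 0.1%."""
        omegas = np.array([30.0, 55.0, 90.0, 140.0, 200.0, 320.0])
        T = np.linspace(150.0, 400.0, 26)
        beta = 1.0 / (KB * T)
        e_total = omegas.size * KB * T  # kT per mode (kinetic + potential)
        s_exact = KB * (1.0 - np.log(beta[:, None] * HBAR * omegas[None, :])).sum(axis=1)
        t_ref = T[0]
        s = entropy_thermodynamic_integration(T, e_total, s_exact[0], t_ref)
        assert np.abs(s - s_exact).max() < 1e-3 * np.abs(s_exact).max()
        assert np.all(np.diff(s) > 0)  # C_V > 0 -> S increasing

    def test_constant_energy_no_entropy_change(self):
        T = np.linspace(200.0, 300.0, 6)
        s = entropy_thermodynamic_integration(T, np.full(6, -50.0), 0.123, 200.0)
        assert np.abs(s - 0.123).max() < 1e-12

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ParameterError):
            entropy_thermodynamic_integration(
                np.array([200.0, 250.0, 240.0]), np.zeros(3), 0.0, 200.0
            )


class TestConfigurationalEntropy:
    def test_gaussian_peak_and_root(self):
        p = LandscapeParams(alpha=6.6, e0=-52.5, sigma2=15.0)
        assert abs(theoretical_s_is(np.array([-52.5]), p)[0] - KB * 6.6) < 1e-12
        root = -52.5 - np.sqrt(15.0) * np.sqrt(2 * 6.6)
        assert abs(theoretical_s_is(np.array([root]), p)[0]) < 1e-12

    def test_missing_alpha_raises(self):
        p = LandscapeParams(alpha=np.nan, e0=-52.5, sigma2=15.0)
        with pytest.raises(AssemblyError):
            theoretical_s_is(np.array([-55.0]), p)

    def test_c00_calibration_recovers_offset(self):
        T = np.linspace(210.0, 390.0, 10)
        p = LandscapeParams(alpha=6.6, e0=-52.5, sigma2=15.0)
        e_is = p.e0 - p.sigma2 * (1.0 / (KB * T) + 0.15)
        theory = theoretical_s_is(e_is, p)
        co = AnharmonicCoeffs(c00=-2.44, c01=0.0113, c02=-1.998e-5)
        s_vib_h = np.zeros_like(T)
        s_vib_a = anharmonic_vibrational_entropy(T, co)
        entropy = theory + s_vib_h + s_vib_a
        res = configurational_entropy(T, entropy, s_vib_h, co, p, e_is)
        assert abs(res.c00 - co.c00) < 1e-10
        assert res.rms_mismatch < 1e-12
        assert np.allclose(res.s_is_numerical, res.s_is_theoretical, atol=1e-12)


class TestKauzmann:
    def test_constant_b_closed_form_matches_numerical_root(self):
        p = LandscapeParams(alpha=6.6, e0=-52.5, sigma2=15.1)
        b = 0.2
        t_closed = kauzmann_closed_form(p, b)
        t_num = kauzmann_temperature(p, lambda T: b, xtol=1e-6)
        assert abs(t_closed - t_num) < 1e-5 * t_closed

    def test_larger_b_raises_tk(self):
        p = LandscapeParams(alpha=6.6, e0=-52.5, sigma2=15.1)
        assert kauzmann_temperature(p, lambda T: 0.25) > kauzmann_temperature(
            p, lambda T: 0.15
        )

    def test_no_root_reports_boundary_values(self):
        p = LandscapeParams(alpha=50.0, e0=-52.5, sigma2=15.1)  # root far below window
        with pytest.raises(NoRootError) as err:
            kauzmann_temperature(p, lambda T: 0.0)
        assert len(err.value.values) == 2


class TestAdamGibbs:
    def test_exact_round_trip(self):
        T = np.arange(200.0, 401.0, 20.0)
        s_is = np.linspace(0.02, 0.05, T.size)
        d0, a = 11.17, -26.16
        D = d0 * np.exp(a / (T * s_is))
        fit = adam_gibbs_fit(T, D, s_is)
        assert abs(fit.d0 - d0) < 1e-8 * d0
        assert abs(fit.a_table - a) < 1e-8 * abs(a)
        assert fit.a_eq == -fit.a_table
        assert fit.r2 > 1 - 1e-12

    def test_constant_ts_is_rank_error(self):
        T = np.array([200.0, 250.0, 300.0])
        s_is = 6.0 / T  # T * S_IS constant
        with pytest.raises(RankError):
            adam_gibbs_fit(T, np.array([1.0, 1.1, 1.2]), s_is)

    def test_nonpositive_inputs_listed(self):
        T = np.array([200.0, 250.0, 300.0])
        with pytest.raises(ParameterError) as err:
            adam_gibbs_fit(T, np.array([1.0, -1.0, 1.2]), np.full(3, 0.03))
        assert "250" in str(err.value)


def test_helmholtz_identity_on_closed_pipeline():
    """F = E - T S holds exactly when all pieces come from one generator."""
    from qpel.landscape import helmholtz_assembly
    from qpel.synthetic import gen_thermo_series, preset_spec

    spec = preset_spec("H2O", noise_scale=0.0)
    ser = gen_thermo_series(spec)
    T = ser.T
    beta = 1.0 / (KB * T)
    out = helmholtz_assembly(
        T,
        spec.landscape_params(),
        spec.b_of_beta(beta),
        ser.s_shape,
        spec.coeffs,
        ser.extra["s_is"],
        n_b=spec.n_b,
    )
    f_direct = ser.e_total - T * ser.entropy
    assert np.abs(out["F"] - f_direct).max() < 1e-8 * np.abs(f_direct).max()


def test_helmholtz_missing_component_named():
    from qpel.landscape import helmholtz_assembly

    p = LandscapeParams(alpha=6.6, e0=-52.5, sigma2=15.0)
    with pytest.raises(AssemblyError) as err:
        helmholtz_assembly(
            np.array([250.0]), p, None, np.array([1.0]),
            AnharmonicCoeffs(), np.array([0.01]), n_b=32,
        )
    assert "b" in str(err.value)
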