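"""Spectra: mass weighting, the classical->RP frequency map, VDOS, shape function."""

import numpy as np
import pytest

from qpel.errors import NotAMinimumError, ParameterError
from qpel.forcefield import (
    discretized_ho_free_energy,
    harmonic_lattice,
    quantum_ho_free_energy,
)
from qpel.spectra import (
    A0,
    FrequencySet,
    classical_frequencies,
    is_vdos,
    rp_frequencies,
    shape_function,
    shape_function_dbeta,
)
from qpel.units import HBAR, beta_from_T, omega_from_wavenumber


def _lattice_freqset(omegas=(30.0, 55.0, 90.0, 140.0, 200.0, 320.0), masses=None, seed=1):
    toy = harmonic_lattice(np.array(omegas), masses=masses, seed=seed)
    H = toy.hessian(toy.x_min)
    return toy, classical_frequencies(H, toy.masses, expect_zero=0)


def test_prescribed_spectrum_recovered():
    omegas = np.array([30.0, 55.0, 90.0, 140.0, 200.0, 320.0])
    _, fs = _lattice_freqset(omegas)
    assert np.allclose(fs.classical, omegas, rtol=1e-8)


def test_mass_doubling_scales_frequencies():
    om = np.array([40.0, 70.0, 110.0, 150.0, 210.0, 260.0])
    toy1, fs1 = _lattice_freqset(om, masses=np.array([1.0, 1.0]), seed=2)
    H = toy1.hessian(toy1.x_min)
    fs2 = classical_frequencies(H, 2.0 * toy1.masses, expect_zero=0)
    assert np.allclose(fs2.classical, fs1.classical / np.sqrt(2.0), rtol=1e-10)


def test_isotope_substitution_shifts_stretch_down(mini_study):
    wh = np.concatenate(
        [fs.wavenumbers() for fs in mini_study.classical_sets[("H2O", 300.0)]]
    )
    wd = np.concatenate(
        [fs.wavenumbers() for fs in mini_study.classical_sets[("D2O", 300.0)]]
    )
    assert wh.max() > 3000.0  # H2O stretch band
    assert wd.max() < wh.max()
    # bending region present around ~1600 cm^-1 for H2O
    assert ((wh > 1400) & (wh < 1900)).any()


class TestRPFrequencies:
    def test_j_equals_nb_carries_classical_part_only(self):
        fs = FrequencySet(classical=np.array([250.0]), n_zero=0, d=1)
        nb = 8
        rp = rp_frequencies(fs, 300.0, nb)
        assert rp.rp.size == nb
        # smallest member is the pure classical contribution w0/n_b
        assert abs(rp.rp.min() - 250.0 / nb) < 1e-10

    def test_single_bead_reduces_to_classical(self):
        fs = FrequencySet(classical=np.array([120.0, 300.0]), n_zero=0, d=2)
        rp = rp_frequencies(fs, 250.0, 1)
        assert np.allclose(rp.rp, fs.classical, rtol=1e-12)

    def test_mode_count_excludes_three_zeros(self, water8_is):
        rec, pot = water8_is
        H = pot.hessian(rec.configuration.positions)
        fs = classical_frequencies(H, rec.configuration.topology.masses)
        rp = rp_frequencies(fs, 260.0, 16)
        assert rp.rp.size == 72 * 16 - 3
        assert np.all(rp.rp > 0)

    def test_ho_free_energy_within_one_percent_at_nb32(self):
        """The map's n_b placement is pinned by the exact HO free energy."""
        om0 = omega_from_wavenumber(3000.0)
        T = 300.0
        beta = beta_from_T(T)
        f_exact = quantum_ho_free_energy(om0, T)
        errs = []
        for nb in (8, 16, 32, 64):
            fs = FrequencySet(classical=np.array([om0]), n_zero=0, d=1)
            rp = rp_frequencies(fs, T, nb)
            f_rp = (1.0 / beta) * np.log(beta * HBAR * rp.rp).sum()
            assert abs(f_rp - discretized_ho_free_energy(om0, T, nb)) < 1e-10
            errs.append(abs(f_rp - f_exact) / abs(f_exact))
        assert errs[2] < 0.01  # n_b = 32
        assert all(a > b for a, b in zip(errs, errs[1:]))  # monotone in n_b

    def test_invalid_temperature(self):
        fs = FrequencySet(classical=np.array([100.0]), n_zero=0, d=1)
        with pytest.raises((ParameterError, ValueError)):
            rp_frequencies(fs, -5.0, 8)


class TestShapeFunction:
    def test_reference_frequencies_give_zero(self):
        w = np.full(10, A0 / HBAR)
        fs = FrequencySet(classical=w, n_zero=0, d=10)
        assert abs(shape_function(fs)) < 1e-12

    def test_frequency_scaling_log_identity(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(20, 400, size=15)
        fs = FrequencySet(classical=w, n_zero=0, d=15)
        s0 = shape_function(fs)
        c = 2.7
        fs2 = FrequencySet(classical=c * w, n_zero=0, d=15)
        assert abs(shape_function(fs2) - (s0 + 15 * np.log(c))) < 1e-9

    def test_nonpositive_frequency_rejected(self):
        fs = FrequencySet(classical=np.array([10.0, -1.0]), n_zero=0, d=2)
        with pytest.raises(ParameterError):
            shape_function(fs)

    def test_isotope_ordering_at_fixed_T(self, mini_study):
        s = {
            iso: mini_study.shape[(iso, 240.0)].mean()
            for iso in ("H2O", "HDO", "D2O", "T2O")
        }
        assert s["H2O"] > s["HDO"] > s["D2O"] > s["T2O"]

    def test_rp_shape_decreases_on_cooling_classical_t_independent(self, water8_is):
        rec, pot = water8_is
        H = pot.hessian(rec.configuration.positions)
        fs = classical_frequencies(H, rec.configuration.topology.masses)
        s_cl = shape_function(fs)
        s_rp = {}
        for T in (220.0, 300.0):
            s_rp[T] = shape_function(rp_frequencies(fs, T, 32))
        assert s_rp[220.0] < s_rp[300.0]  # quantum shape drops on cooling
        # classical shape is T-independent by construction (no map applied)
        assert s_cl == shape_function(fs)

    def test_analytic_dbeta_matches_finite_difference(self, water8_is):
        rec, pot = water8_is
        H = pot.hessian(rec.configuration.positions)
        fs = classical_frequencies(H, rec.configuration.topology.masses)
        T = 260.0
        rp = rp_frequencies(fs, T, 16)
        ana = shape_function_dbeta(rp)
        db = 1e-6
        beta = beta_from_T(T)
        from qpel.units import KB

        def s_at_beta(b):
            return shape_function(rp_frequencies(fs, 1.0 / (KB * b), 16))

        fd = (s_at_beta(beta + db) - s_at_beta(beta - db)) / (2 * db)
        assert abs(ana - fd) < 1e-4 * abs(fd)


class TestVDOS:
    def test_normalization(self, mini_study):
        centers, dens = is_vdos(mini_study.classical_sets[("H2O", 300.0)], bins=80)
        dx = centers[1] - centers[0]
        assert abs(dens.sum() * dx - 1.0) < 1e-8

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            is_vdos([])

    def test_mean_frequency_decreases_with_mass(self, mini_study):
        means = {}
        for iso in ("H2O", "HDO", "D2O", "T2O"):
            w = np.concatenate(
                [fs.wavenumbers() for fs in mini_study.classical_sets[(iso, 240.0)]]
            )
            means[iso] = w.mean()
        assert means["H2O"] > means["HDO"] > means["D2O"] > means["T2O"]


def test_more_than_three_negative_modes_rejected(water8_is):
    rec, pot = water8_is
    H = -pot.hessian(rec.configuration.positions)
    with pytest.raises(NotAMinimumError):
        classical_frequencies(H, rec.configuration.topology.masses)
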