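"""Full-scale reference values for water isotopologues (benchmark metadata).

These are the landscape parameters reported by the full-scale study
(N = 512, multi-nanosecond path-integral sampling at v = 18.0 cm^3/mol)
that desk-scale runs cannot reproduce; they are recorded here so fitted
results can be compared against them and so the synthetic generator's
presets have a single authoritative source inside the package.
[Q] = quantum (path-integral), [C] = classical.
"""

#: Gaussian-landscape parameters per molecule: E0 (kJ/mol), sigma^2 ((kJ/mol)^2)
GAUSSIAN_LANDSCAPE = {
    "H2O[Q]": {"E0": -52.66, "E0_sd": 0.14, "sigma2": 14.30, "sigma2_sd": 0.40},
    "HDO[Q]": {"E0": -52.40, "E0_sd": 0.12, "sigma2": 15.06, "sigma2_sd": 0.35},
    "D2O[Q]": {"E0": -52.35, "E0_sd": 0.08, "sigma2": 15.16, "sigma2_sd": 0.23},
    "T2O[Q]": {"E0": -52.46, "E0_sd": 0.06, "sigma2": 15.15, "sigma2_sd": 0.18},
    "H2O[C]": {"E0": -52.51, "E0_sd": 0.05, "sigma2": 15.10, "sigma2_sd": 0.15},
}

#: anharmonic coefficients of B0(T) = c00 + c01 T + c02 T^2
ANHARMONIC = {
    "H2O[Q]": {"c00": -2.44, "c01": 0.0113, "c02": -1.998e-5},
    "HDO[Q]": {"c00": -1.58, "c01": 0.0076, "c02": -1.485e-5},
    "D2O[Q]": {"c00": -1.23, "c01": 0.0058, "c02": -1.244e-5},
    "T2O[Q]": {"c00": -0.91, "c01": 0.0050, "c02": -1.181e-5},
    "H2O[C]": {"c00": 0.00, "c01": 0.0014, "c02": -7.853e-6},
}

#: Kauzmann temperatures (K)
KAUZMANN_T = {
    "H2O[Q]": 137.0,
    "HDO[Q]": 141.0,
    "D2O[Q]": 145.0,
    "T2O[Q]": 146.0,
    "H2O[C]": 153.0,
}

#: Adam-Gibbs parameters: D0 (Angstrom^2/ps), A (kJ/mol, table sign convention)
ADAM_GIBBS = {
    "H2O[Q]": {"D0": 11.17, "A": -26.16},
    "HDO[Q]": {"D0": 8.05, "A": -24.77},
    "D2O[Q]": {"D0": 8.35, "A": -25.39},
    "T2O[Q]": {"D0": 9.06, "A": -26.67},
    "H2O[C]": {"D0": 11.21, "A": -26.73},
}

#: per-molecule total-energy gap E(H2O) - E(T2O), kJ/mol (zero-point dominated)
DELTA_E_H2O_T2O = 22.0
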