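# q-TIP4P/F flexible water model — numeric parameters.
#
# Transcribed from the model's source publication:
#   S. Habershon, T. E. Markland, D. E. Manolopoulos,
#   J. Chem. Phys. 131, 024501 (2009), Table I,
# converted to the package's internal units (amu, nm, ps, kJ/mol;
# 1 kcal = 4.184 kJ).  The engine is parameter-file-driven: any
# TIP4P-type flexible 3-site model can be substituted by editing a copy
# of this file.

name = "q-TIP4P/F"

[intramolecular]
# O-H stretch: quartic expansion of a Morse potential
#   V(r) = D_r [ a^2 dr^2 - a^3 dr^3 + (7/12) a^4 dr^4 ],  dr = r - r_eq
d_r = 485.72056          # kJ/mol        (116.09 kcal/mol)
alpha_r = 22.87          # 1/nm          (2.287 1/Angstrom)
r_eq = 0.09419           # nm            (0.9419 Angstrom)
# HOH bend: V = (1/2) k_theta (theta - theta_eq)^2
k_theta = 367.5644       # kJ/mol/rad^2  (87.85 kcal/mol/rad^2)
theta_eq_deg = 107.4     # degrees

[lennard_jones]
# on the O site only
epsilon = 0.7748768      # kJ/mol        (0.1852 kcal/mol)
sigma = 0.31589          # nm

[electrostatics]
q_h = 0.5564             # e, on each H site
# M (charge) site: r_M = gamma r_O + (1 - gamma)(r_H1 + r_H2)/2
gamma = 0.73612
cutoff = 1.0             # nm, shared by LJ and reaction-field Coulomb
# conducting-boundary reaction field (infinite external dielectric),
# energy-shifted to vanish at the cutoff
reaction_field_dielectric = "inf"
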