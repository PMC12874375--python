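"""Force-field parameter container and TOML loading."""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass
from importlib import resources

from ..errors import ParameterError


@dataclass(frozen=True)
class ForceFieldParams:
    """Parameters of a TIP4P-type flexible 3-site water model.

    The O-H stretch is the quartic expansion of a Morse potential,
    ``V(r) = d_r [a^2 dr^2 - a^3 dr^3 + (7/12) a^4 dr^4]`` with
    ``dr = r - r_eq``; the bend is harmonic in the HOH angle.  Charges sit
    on the H sites and on a massless M site on the HOH bisector,
    ``r_M = gamma r_O + (1-gamma)(r_H1+r_H2)/2``.  Electrostatics use the
    conducting-boundary reaction field, energy-shifted to vanish at the
    cutoff; the Lennard-Jones term (O sites only) is cut and shifted.
    """

    name: str
    d_r: float          # kJ/mol
    alpha_r: float      # 1/nm
    r_eq: float         # nm
    k_theta: float      # kJ/mol/rad^2
    theta_eq: float     # rad
    epsilon: float      # kJ/mol
    sigma: float        # nm
    q_h: float          # e
    gamma: float        # M-site displacement fraction
    cutoff: float       # nm

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")
        if not 0.0 < self.gamma <= 1.0:
            raise ParameterError("gamma must lie in (0, 1]")

    @property
    def q_m(self) -> float:
        """M-site charge; the molecule is neutral."""
        return -2.0 * self.q_h


def load_params(path=None) -> ForceFieldParams:
    """Read a force-field TOML file; default is the packaged q-TIP4P/F set."""
    if path is None:
        src = resources.files("qpel.forcefield").joinpath("qtip4pf.toml")
        data = tomllib.loads(src.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    intra = data["intramolecular"]
    lj = data["lennard_jones"]
    ele = data["electrostatics"]
    return ForceFieldParams(
        name=data.get("name", "custom"),
        d_r=intra["d_r"],
        alpha_r=intra["alpha_r"],
        r_eq=intra["r_eq"],
        k_theta=intra["k_theta"],
        theta_eq=math.radians(intra["theta_eq_deg"]),
        epsilon=lj["epsilon"],
        sigma=lj["sigma"],
        q_h=ele["q_h"],
        gamma=ele["gamma"],
        cutoff=ele["cutoff"],
    )
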