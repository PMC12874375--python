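"""Energies, forces and Hessians for TIP4P-type flexible water.

All routines are batched: position arrays may carry arbitrary leading axes
(e.g. ring-polymer bead slices), with the last two axes ``(n_sites, 3)``.
The minimum-image convention is applied to every interaction displacement,
so positions never need to be wrapped into the box.

The charge-carrying M site is massless and geometric; forces acting on it
are redistributed onto the three massive sites by the (constant, linear)
chain rule, keeping the dynamical system at 9N degrees of freedom.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError, SingularGeometryError
from ..topology import Configuration, Topology
from ..units import COULOMB
from .params import ForceFieldParams

_R_SINGULAR = 1e-6  # nm


def _min_image(d: np.ndarray, box: float | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)


class WaterPotential:
    """Callable potential for one (topology, box, parameter set) triple.

    Parameters
    ----------
    topology, box:
        System definition; the box is cubic with edge ``box`` (nm).
    params:
        Force-field constants; see :class:`ForceFieldParams`.
    cutoff:
        Working cutoff r_c (nm).  Defaults to ``params.cutoff`` capped at
        just under L/2 so the minimum-image convention stays valid in
        small study boxes; an explicit value larger than L/2 is rejected.
    """

    def __init__(
        self,
        topology: Topology,
        box: float,
        params: ForceFieldParams,
        cutoff: float | None = None,
    ):
        self.topology = topology
        self.box = float(box)
        self.params = params
        half = 0.5 * self.box * (1.0 - 1e-9)
        if cutoff is None:
            self.cutoff = min(params.cutoff, half)
        else:
            if cutoff > half:
                raise ParameterError(
                    f"cutoff {cutoff} nm exceeds half the box edge {half:.4f} nm"
                )
            self.cutoff = float(cutoff)

        N = topology.n_molecules
        self.n_sites = topology.n_sites
        self.masses = topology.masses
        # charged sites per molecule: H1, H2, M
        self.q = np.tile([params.q_h, params.q_h, params.q_m], N)
        mol_of_charged = np.repeat(np.arange(N), 3)
        self._same_mol = mol_of_charged[:, None] == mol_of_charged[None, :]
        self._eye_c = np.eye(3 * N, dtype=bool)
        # reaction-field constants (conducting boundary, shifted to 0 at r_c)
        rc = self.cutoff
        self._krf = 1.0 / (2.0 * rc**3)
        self._crf = 3.0 / (2.0 * rc)
        # LJ cut: force-shifted (energy and force both vanish at r_c, so the
        # landscape stays C^1 and minimizers behave at short capped cutoffs)
        sr6 = (params.sigma / rc) ** 6
        self._lj_shift = 4.0 * params.epsilon * (sr6**2 - sr6)
        self._lj_fshift = 4.0 * params.epsilon * (-12.0 * sr6**2 + 6.0 * sr6) / rc

    # ---------------------------------------------------------------- sites
    def _mol_view(self, pos: np.ndarray) -> np.ndarray:
        return pos.reshape(pos.shape[:-2] + (self.topology.n_molecules, 3, 3))

    def m_sites(self, pos: np.ndarray) -> np.ndarray:
        g = self.params.gamma
        mol = self._mol_view(pos)
        return g * mol[..., 0, :] + 0.5 * (1.0 - g) * (mol[..., 1, :] + mol[..., 2, :])

    def charged_sites(self, pos: np.ndarray) -> np.ndarray:
        mol = self._mol_view(pos)
        out = np.empty(pos.shape[:-2] + (self.topology.n_molecules, 3, 3))
        out[..., 0, :] = mol[..., 1, :]
        out[..., 1, :] = mol[..., 2, :]
        out[..., 2, :] = self.m_sites(pos)
        return out.reshape(pos.shape[:-2] + (3 * self.topology.n_molecules, 3))

    # --------------------------------------------------------------- energy
    def energy_forces(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Total potential energy (kJ/mol) and per-site forces.

        ``positions`` has shape ``(..., n_sites, 3)``; the energy comes back
        with shape ``(...)`` and the forces with the shape of the input.
        Forces are the exact negative gradient of the returned energy.
        """
        p = self.params
        pos = np.asarray(positions, dtype=float)
        mol = self._mol_view(pos)
        forces = np.zeros_like(pos)
        fmol = self._mol_view(forces)

        # --- O-H stretches (both bonds at once: stack on a new axis)
        u = _min_image(mol[..., 1:3, :] - mol[..., 0:1, :], self.box)  # (...,N,2,3)
        r = np.linalg.norm(u, axis=-1)
        if np.any(r < _R_SINGULAR):
            raise SingularGeometryError("O-H distance below 1e-6 nm")
        dr = r - p.r_eq
        a = p.alpha_r
        e_str = p.d_r * (a**2 * dr**2 - a**3 * dr**3 + (7.0 / 12.0) * a**4 * dr**4)
        dv = p.d_r * (2 * a**2 * dr - 3 * a**3 * dr**2 + (7.0 / 3.0) * a**4 * dr**3)
        uhat = u / r[..., None]
        f_h = -dv[..., None] * uhat
        fmol[..., 1:3, :] += f_h
        fmol[..., 0, :] -= f_h.sum(axis=-2)
        energy = e_str.sum(axis=(-1, -2))

        # --- HOH bend
        u1 = _min_image(mol[..., 1, :] - mol[..., 0, :], self.box)
        u2 = _min_image(mol[..., 2, :] - mol[..., 0, :], self.box)
        r1 = np.linalg.norm(u1, axis=-1)
        r2 = np.linalg.norm(u2, axis=-1)
        e1 = u1 / r1[..., None]
        e2 = u2 / r2[..., None]
        cth = np.clip((e1 * e2).sum(axis=-1), -1.0, 1.0)
        th = np.arccos(cth)
        sth = np.sqrt(np.clip(1.0 - cth**2, 1e-12, None))
        dth = th - p.theta_eq
        energy = energy + 0.5 * p.k_theta * (dth**2).sum(axis=-1)
        dedth = p.k_theta * dth
        # grad(theta) w.r.t. H1 and H2
        g1 = (cth[..., None] * e1 - e2) / (r1 * sth)[..., None]
        g2 = (cth[..., None] * e2 - e1) / (r2 * sth)[..., None]
        fmol[..., 1, :] -= dedth[..., None] * g1
        fmol[..., 2, :] -= dedth[..., None] * g2
        fmol[..., 0, :] += dedth[..., None] * (g1 + g2)

        # --- Lennard-Jones on O sites (cut and shifted)
        ro = mol[..., 0, :]
        d = _min_image(ro[..., :, None, :] - ro[..., None, :, :], self.box)
        rr = np.linalg.norm(d, axis=-1)
        n = self.topology.n_molecules
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(rr > 0, 1.0 / rr, 0.0)
        act = (~np.eye(n, dtype=bool)) & (rr < self.cutoff)
        if np.any(act & (rr < _R_SINGULAR)):
            raise SingularGeometryError("O-O distance below 1e-6 nm")
        sr6 = np.where(act, (p.sigma * inv) ** 6, 0.0)
        e_lj = np.where(
            act,
            4.0 * p.epsilon * (sr6**2 - sr6)
            - self._lj_shift
            - (rr - self.cutoff) * self._lj_fshift,
            0.0,
        )
        energy = energy + 0.5 * e_lj.sum(axis=(-1, -2))
        dvdr = np.where(
            act, 4.0 * p.epsilon * (-12.0 * sr6**2 + 6.0 * sr6) * inv - self._lj_fshift, 0.0
        )
        fo = -(dvdr * inv)[..., None] * d  # force on i from j summed below
        fmol[..., 0, :] += fo.sum(axis=-2)

        # --- reaction-field Coulomb between charged sites of distinct molecules
        cs = self.charged_sites(pos)
        dc = _min_image(cs[..., :, None, :] - cs[..., None, :, :], self.box)
        rc = np.linalg.norm(dc, axis=-1)
        actc = (~self._same_mol) & (rc < self.cutoff)
        if np.any(actc & (rc < _R_SINGULAR)):
            raise SingularGeometryError("charge-site distance below 1e-6 nm")
        with np.errstate(divide="ignore"):
            invc = np.where(rc > 0, 1.0 / rc, 0.0)
        qq = COULOMB * self.q[:, None] * self.q[None, :]
        e_c = np.where(actc, qq * (invc + self._krf * rc**2 - self._crf), 0.0)
        energy = energy + 0.5 * e_c.sum(axis=(-1, -2))
        dvc = np.where(actc, qq * (-(invc**2) + 2.0 * self._krf * rc), 0.0)
        fc = -(dvc * invc)[..., None] * dc
        f_sites = fc.sum(axis=-2)  # force on each charged site
        # redistribute: H1, H2 direct; M via chain rule
        g = self.params.gamma
        fs = f_sites.reshape(pos.shape[:-2] + (n, 3, 3))
        fmol[..., 1, :] += fs[..., 0, :] + 0.5 * (1 - g) * fs[..., 2, :]
        fmol[..., 2, :] += fs[..., 1, :] + 0.5 * (1 - g) * fs[..., 2, :]
        fmol[..., 0, :] += g * fs[..., 2, :]

        return energy, forces

    def energy(self, positions: np.ndarray) -> np.ndarray:
        return self.energy_forces(positions)[0]

    # -------------------------------------------------------------- hessian
    def hessian(self, positions: np.ndarray, bend_step: float = 1e-6) -> np.ndarray:
        """Second-derivative matrix (9N x 9N), not mass-weighted.

        Radial pair terms (stretch, LJ, reaction-field Coulomb including the
        M-site chain rule) are analytic; the bend block uses central finite
        differences of the analytic bend gradient with step ``bend_step`` nm.
        """
        p = self.params
        pos = np.asarray(positions, dtype=float)
        if pos.ndim != 2:
            raise ParameterError("hessian expects a single configuration")
        n_sites = self.n_sites
        H = np.zeros((3 * n_sites, 3 * n_sites))

        def add_pair(i: int, j: int, d: np.ndarray, upp: float, up: float):
            """Accumulate the radial-pair block for global sites i, j."""
            r = np.linalg.norm(d)
            e = d / r
            K = upp * np.outer(e, e) + (up / r) * (np.eye(3) - np.outer(e, e))
            sl_i = slice(3 * i, 3 * i + 3)
            sl_j = slice(3 * j, 3 * j + 3)
            H[sl_i, sl_i] += K
            H[sl_j, sl_j] += K
            H[sl_i, sl_j] -= K
            H[sl_j, sl_i] -= K

        N = self.topology.n_molecules
        a = p.alpha_r
        # stretches
        for m in range(N):
            o, h1, h2 = 3 * m, 3 * m + 1, 3 * m + 2
            for h in (h1, h2):
                d = _min_image(pos[h] - pos[o], self.box)
                r = np.linalg.norm(d)
                dr = r - p.r_eq
                up = p.d_r * (2 * a**2 * dr - 3 * a**3 * dr**2 + (7.0 / 3.0) * a**4 * dr**3)
                upp = p.d_r * (2 * a**2 - 6 * a**3 * dr + 7.0 * a**4 * dr**2)
                add_pair(o, h, d, upp, up)

        # LJ (O-O)
        for mi in range(N):
            for mj in range(mi + 1, N):
                d = _min_image(pos[3 * mi] - pos[3 * mj], self.box)
                r = np.linalg.norm(d)
                if r >= self.cutoff:
                    continue
                sr6 = (p.sigma / r) ** 6
                up = 4 * p.epsilon * (-12 * sr6**2 + 6 * sr6) / r - self._lj_fshift
                upp = 4 * p.epsilon * (156 * sr6**2 - 42 * sr6) / r**2
                add_pair(3 * mi, 3 * mj, d, upp, up)

        # Coulomb in charged-site coordinates, then project through the
        # constant linear map from atom to charged-site coordinates.
        cs = self.charged_sites(pos)
        nc = 3 * N
        Hc = np.zeros((3 * nc, 3 * nc))

        def add_pair_c(i, j, d, upp, up):
            r = np.linalg.norm(d)
            e = d / r
            K = upp * np.outer(e, e) + (up / r) * (np.eye(3) - np.outer(e, e))
            sl_i = slice(3 * i, 3 * i + 3)
            sl_j = slice(3 * j, 3 * j + 3)
            Hc[sl_i, sl_i] += K
            Hc[sl_j, sl_j] += K
            Hc[sl_i, sl_j] -= K
            Hc[sl_j, sl_i] -= K

        for i in range(nc):
            for j in range(i + 1, nc):
                if self._same_mol[i, j]:
                    continue
                d = _min_image(cs[i] - cs[j], self.box)
                r = np.linalg.norm(d)
                if r >= self.cutoff:
                    continue
                qq = COULOMB * self.q[i] * self.q[j]
                up = qq * (-1.0 / r**2 + 2.0 * self._krf * r)
                upp = qq * (2.0 / r**3 + 2.0 * self._krf)
                add_pair_c(i, j, d, upp, up)

        J = self._charged_site_jacobian()
        H += J.T @ Hc @ J

        # bend: FD of the analytic bend gradient, molecule-local (9 coords)
        H += self._bend_hessian_fd(pos, bend_step)
        return H

    def _charged_site_jacobian(self) -> np.ndarray:
        """d(charged-site coords)/d(atom coords), shape (9N, 9N), constant."""
        N = self.topology.n_molecules
        g = self.params.gamma
        J = np.zeros((9 * N, 9 * N))
        I3 = np.eye(3)
        for m in range(N):
            o, h1, h2 = 3 * m, 3 * m + 1, 3 * m + 2
            cH1, cH2, cM = 3 * m, 3 * m + 1, 3 * m + 2
            J[3 * cH1 : 3 * cH1 + 3, 3 * h1 : 3 * h1 + 3] = I3
            J[3 * cH2 : 3 * cH2 + 3, 3 * h2 : 3 * h2 + 3] = I3
            J[3 * cM : 3 * cM + 3, 3 * o : 3 * o + 3] = g * I3
            J[3 * cM : 3 * cM + 3, 3 * h1 : 3 * h1 + 3] = 0.5 * (1 - g) * I3
            J[3 * cM : 3 * cM + 3, 3 * h2 : 3 * h2 + 3] = 0.5 * (1 - g) * I3
        return J

    def _bend_gradient(self, mol_pos: np.ndarray) -> np.ndarray:
        """Gradient of the bend energy of one molecule w.r.t. its 9 coords."""
        p = self.params
        u1 = _min_image(mol_pos[1] - mol_pos[0], self.box)
        u2 = _min_image(mol_pos[2] - mol_pos[0], self.box)
        r1 = np.linalg.norm(u1)
        r2 = np.linalg.norm(u2)
        e1, e2 = u1 / r1, u2 / r2
        cth = np.clip(e1 @ e2, -1.0, 1.0)
        th = np.arccos(cth)
        sth = max(np.sqrt(1.0 - cth**2), 1e-8)
        dedth = p.k_theta * (th - p.theta_eq)
        g1 = (cth * e1 - e2) / (r1 * sth)
        g2 = (cth * e2 - e1) / (r2 * sth)
        grad = np.empty((3, 3))
        grad[1] = dedth * g1
        grad[2] = dedth * g2
        grad[0] = -(grad[1] + grad[2])
        return grad.ravel()

    def _bend_hessian_fd(self, pos: np.ndarray, h: float) -> np.ndarray:
        N = self.topology.n_molecules
        H = np.zeros((9 * N, 9 * N))
        for m in range(N):
            block = np.zeros((9, 9))
            mp = pos[3 * m : 3 * m + 3].copy()
            for k in range(9):
                mp.flat[k] += h
                gp = self._bend_gradient(mp)
                mp.flat[k] -= 2 * h
                gm = self._bend_gradient(mp)
                mp.flat[k] += h
                block[:, k] = (gp - gm) / (2 * h)
            block = 0.5 * (block + block.T)
            sl = slice(9 * m, 9 * m + 9)
            H[sl, sl] += block
        return H

    def hessian_fd(self, positions: np.ndarray, step: float = 1e-5) -> np.ndarray:
        """Independent Hessian oracle: central differences of the forces."""
        pos = np.asarray(positions, dtype=float)
        n = pos.size
        H = np.zeros((n, n))
        flat = pos.copy()
        for k in range(n):
            flat.flat[k] += step
            _, fp = self.energy_forces(flat)
            flat.flat[k] -= 2 * step
            _, fm = self.energy_forces(flat)
            flat.flat[k] += step
            H[:, k] = -(fp - fm).ravel() / (2 * step)
        return 0.5 * (H + H.T)


def water_energy_forces(
    config: Configuration, params: ForceFieldParams, cutoff: float | None = None
):
    """One-shot energy/forces for a configuration (convenience wrapper)."""
    pot = WaterPotential(config.topology, config.box, params, cutoff=cutoff)
    return pot.energy_forces(config.positions)


def water_hessian(
    config: Configuration, params: ForceFieldParams, cutoff: float | None = None
) -> np.ndarray:
    """One-shot (un-weighted) Hessian for a configuration."""
    pot = WaterPotential(config.topology, config.box, params, cutoff=cutoff)
    return pot.hessian(config.positions)
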