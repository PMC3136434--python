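"""Differentiable molecular-mechanics energy model.

Supplies the analytic energies and gradients behind snapshot
minimization, normal-mode analysis and the MM force profiles: nonbonded
Coulomb + Lennard-Jones with 1-2/1-3 exclusions, harmonic bond terms at
reference lengths, an optional intra-group harmonic distance network
that stiffens the coarse solute against torsional collapse, and an
optional smooth generalized-Born-style implicit-solvent term (Still
pairwise form with fixed per-atom Born radii).

The Hessian is obtained by central finite differences of the analytic
gradient.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .core import MolecularSystem
from .mm import nonbonded_exclusions
from .units import COULOMB_CONSTANT

__all__ = ["EnergyModel"]


class EnergyModel:
    """Energy/gradient model bound to one system's topology.

    Parameters
    ----------
    system:
        Topology with charges, LJ parameters and bonds.
    bond_k:
        Harmonic bond force constant, kcal/(mol·Å²); equilibrium lengths
        are taken from the system's reference coordinates.
    network_cutoff, network_k:
        If ``network_cutoff`` is set, same-group atom pairs within the
        cutoff in the reference pose get harmonic distance restraints at
        their reference separations (an elastic-network stiffener for the
        coarse solute representation; cross receptor–ligand pairs are
        never restrained).
    include_gb, gb_solvent_dielectric:
        Smooth implicit-solvent polar term with fixed Born radii equal to
        the LJ r_min/2 radii (floored at 0.8 Å).
    """

    def __init__(self, system: MolecularSystem, *, bond_k: float = 300.0,
                 network_cutoff: float | None = None,
                 network_k: float = 5.0,
                 include_gb: bool = False,
                 gb_solvent_dielectric: float = 80.0,
                 include_nonbonded: bool = True) -> None:
        self.system = system
        n = system.n_atoms
        self.charges = system.charges
        self.rmin_half = system.lj_radii
        self.eps = system.lj_epsilons
        ref = system.coordinates

        s2i = system.serial_to_index()
        self.bond_pairs = np.array(
            [(s2i[i], s2i[j]) for i, j in system.bonds
             if i in s2i and j in s2i], dtype=int).reshape(-1, 2)
        self.bond_r0 = (np.linalg.norm(ref[self.bond_pairs[:, 0]] -
                                       ref[self.bond_pairs[:, 1]], axis=1)
                        if len(self.bond_pairs) else np.zeros(0))
        self.bond_k = bond_k

        # group id per atom (for complex: 0 receptor, 1 ligand)
        group = np.zeros(n, dtype=int)
        if system.role == "complex" and system.ligand_serials:
            group[system.ligand_indices] = 1
        self.group = group

        # nonbonded pair list: all unique pairs minus 1-2/1-3 exclusions
        self.include_nonbonded = include_nonbonded
        iu, ju = np.triu_indices(n, k=1)
        excl = nonbonded_exclusions(n, system.bonds, s2i)
        if excl:
            mask = np.array([(i, j) not in excl for i, j in zip(iu, ju)])
            iu, ju = iu[mask], ju[mask]
        self.nb_i, self.nb_j = iu, ju

        # elastic network within each group
        self.net_pairs = np.zeros((0, 2), dtype=int)
        self.net_r0 = np.zeros(0)
        self.network_k = network_k
        if network_cutoff is not None and n > 1:
            d = cdist(ref, ref)
            ii, jj = np.triu_indices(n, k=1)
            bonded = {tuple(p) for p in self.bond_pairs}
            sel = [(i, j) for i, j in zip(ii, jj)
                   if d[i, j] <= network_cutoff and group[i] == group[j]
                   and (i, j) not in bonded]
            if sel:
                self.net_pairs = np.array(sel, dtype=int)
                self.net_r0 = d[self.net_pairs[:, 0], self.net_pairs[:, 1]]

        self.include_gb = include_gb
        self.gb_eps = gb_solvent_dielectric
        self.born_radii = np.maximum(self.rmin_half, 0.8)

    # -- energy ------------------------------------------------------------
    def energy(self, coords: np.ndarray) -> float:
        coords = np.asarray(coords, float)
        e = 0.0
        if len(self.bond_pairs):
            d = np.linalg.norm(coords[self.bond_pairs[:, 0]] -
                               coords[self.bond_pairs[:, 1]], axis=1)
            e += float(np.sum(self.bond_k * (d - self.bond_r0) ** 2))
        if len(self.net_pairs):
            d = np.linalg.norm(coords[self.net_pairs[:, 0]] -
                               coords[self.net_pairs[:, 1]], axis=1)
            e += float(np.sum(self.network_k * (d - self.net_r0) ** 2))
        if self.include_nonbonded and len(self.nb_i):
            e += self._nonbonded_energy(coords)
        if self.include_gb:
            e += self._gb_energy(coords)
        return e

    def _nonbonded_energy(self, coords: np.ndarray) -> float:
        i, j = self.nb_i, self.nb_j
        d = np.linalg.norm(coords[i] - coords[j], axis=1)
        el = COULOMB_CONSTANT * np.sum(self.charges[i] * self.charges[j] / d)
        rmin = self.rmin_half[i] + self.rmin_half[j]
        eps = np.sqrt(self.eps[i] * self.eps[j])
        x6 = (rmin / d) ** 6
        return float(el + np.sum(eps * (x6 * x6 - 2.0 * x6)))

    def _gb_energy(self, coords: np.ndarray) -> float:
        q, R = self.charges, self.born_radii
        pref = -COULOMB_CONSTANT * (1.0 - 1.0 / self.gb_eps)
        n = coords.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        dv = coords[iu] - coords[ju]
        r2 = np.sum(dv * dv, axis=1)
        RR = R[iu] * R[ju]
        f = np.sqrt(r2 + RR * np.exp(-r2 / (4.0 * RR)))
        e = np.sum(q[iu] * q[ju] / f)
        e += 0.5 * np.sum(q * q / R)  # self terms (constant)
        return float(pref * e)

    # -- gradient ----------------------------------------------------------
    def gradient(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        g = np.zeros_like(coords)
        for pairs, r0, k in ((self.bond_pairs, self.bond_r0, self.bond_k),
                             (self.net_pairs, self.net_r0, self.network_k)):
            if not len(pairs):
                continue
            dv = coords[pairs[:, 0]] - coords[pairs[:, 1]]
            d = np.linalg.norm(dv, axis=1)
            coef = (2.0 * k * (d - r0) / d)[:, None] * dv
            np.add.at(g, pairs[:, 0], coef)
            np.add.at(g, pairs[:, 1], -coef)
        if self.include_nonbonded and len(self.nb_i):
            i, j = self.nb_i, self.nb_j
            dv = coords[i] - coords[j]
            d = np.linalg.norm(dv, axis=1)
            qq = COULOMB_CONSTANT * self.charges[i] * self.charges[j]
            rmin = self.rmin_half[i] + self.rmin_half[j]
            eps = np.sqrt(self.eps[i] * self.eps[j])
            x6 = (rmin / d) ** 6
            # dV/dr for el + LJ
            dVdr = -qq / d ** 2 + eps * (-12.0 * x6 * x6 + 12.0 * x6) / d
            coef = (dVdr / d)[:, None] * dv
            np.add.at(g, i, coef)
            np.add.at(g, j, -coef)
        if self.include_gb:
            g += self._gb_gradient(coords)
        return g

    def _gb_gradient(self, coords: np.ndarray) -> np.ndarray:
        q, R = self.charges, self.born_radii
        pref = -COULOMB_CONSTANT * (1.0 - 1.0 / self.gb_eps)
        n = coords.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        dv = coords[iu] - coords[ju]
        r2 = np.sum(dv * dv, axis=1)
        RR = R[iu] * R[ju]
        ex = np.exp(-r2 / (4.0 * RR))
        f2 = r2 + RR * ex
        f = np.sqrt(f2)
        # d(f²)/d(r²) = 1 − ex/4
        dEdr2 = pref * q[iu] * q[ju] * (-0.5 / (f2 * f)) * (1.0 - ex / 4.0)
        coef = (2.0 * dEdr2)[:, None] * dv
        g = np.zeros_like(coords)
        np.add.at(g, iu, coef)
        np.add.at(g, ju, -coef)
        return g

    def forces(self, coords: np.ndarray) -> np.ndarray:
        """Forces = −gradient, kcal/(mol·Å)."""
        return -self.gradient(coords)

    # -- hessian -----------------------------------------------------------
    def hessian(self, coords: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """(3n, 3n) Hessian by central differences of the analytic gradient."""
        coords = np.asarray(coords, float)
        n3 = coords.size
        H = np.empty((n3, n3))
        flat = coords.ravel().copy()
        for k in range(n3):
            x = flat.copy()
            x[k] += step
            gp = self.gradient(x.reshape(coords.shape)).ravel()
            x[k] -= 2.0 * step
            gm = self.gradient(x.reshape(coords.shape)).ravel()
            H[k] = (gp - gm) / (2.0 * step)
        return 0.5 * (H + H.T)
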