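"""Gas-phase molecular-mechanics interaction energies.

Coulomb and 12-6 Lennard-Jones cross-group sums with infinite cutoff and
no periodicity, in the single-trajectory convention: receptor and ligand
coordinates are slices of the complex frame, so intramolecular terms
cancel in the binding energy and only the receptor↔ligand cross
interaction survives.

LJ uses the r_min/ε parameterisation: per-atom radii are r_min/2 and
combine arithmetically, well depths geometrically (Lorentz–Berthelot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import MolecularSystem
from .units import COULOMB_CONSTANT

__all__ = [
    "GasPhaseEnergy",
    "coulomb_interaction",
    "lj_interaction",
    "gas_phase_binding",
    "intragroup_energy",
    "nonbonded_exclusions",
]


class ZeroDistanceError(ValueError):
    """Two interacting atoms coincide; identifies the offending pair."""


@dataclass(frozen=True)
class GasPhaseEnergy:
    """Electrostatic + van der Waals interaction energy, kcal/mol."""

    el: float
    vdw: float

    @property
    def total(self) -> float:
        return self.el + self.vdw


def _check_distances(d: np.ndarray, where: str) -> None:
    if d.size and np.min(d) <= 0.0:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ZeroDistanceError(
            f"zero interatomic distance between atoms {i} and {j} ({where})")


def coulomb_interaction(coords_a: np.ndarray, charges_a: np.ndarray,
                        coords_b: np.ndarray, charges_b: np.ndarray) -> float:
    """Vacuum Coulomb cross energy, kcal/mol, infinite cutoff."""
    coords_a = np.atleast_2d(coords_a)
    coords_b = np.atleast_2d(coords_b)
    if coords_a.shape[0] == 0 or coords_b.shape[0] == 0:
        return 0.0
    d = cdist(coords_a, coords_b)
    _check_distances(d, "coulomb")
    return float(COULOMB_CONSTANT *
                 np.einsum("i,j,ij->", charges_a, charges_b, 1.0 / d))


def lj_interaction(coords_a: np.ndarray, rmin_half_a: np.ndarray,
                   eps_a: np.ndarray, coords_b: np.ndarray,
                   rmin_half_b: np.ndarray, eps_b: np.ndarray) -> float:
    """12-6 Lennard-Jones cross energy, kcal/mol.

    V(r) = ε_ij [(r_min,ij / r)^12 − 2 (r_min,ij / r)^6], with
    r_min,ij = r_min,i/2 + r_min,j/2 and ε_ij = sqrt(ε_i ε_j).
    """
    coords_a = np.atleast_2d(coords_a)
    coords_b = np.atleast_2d(coords_b)
    if coords_a.shape[0] == 0 or coords_b.shape[0] == 0:
        return 0.0
    d = cdist(coords_a, coords_b)
    _check_distances(d, "lj")
    rmin = np.add.outer(np.asarray(rmin_half_a, float),
                        np.asarray(rmin_half_b, float))
    eps = np.sqrt(np.outer(eps_a, eps_b))
    x6 = (rmin / d) ** 6
    return float(np.sum(eps * (x6 * x6 - 2.0 * x6)))


def gas_phase_binding(system: MolecularSystem,
                      frame: np.ndarray | None = None) -> GasPhaseEnergy:
    """Receptor↔ligand gas-phase interaction for one complex frame."""
    if system.role != "complex":
        raise ValueError("gas_phase_binding expects a complex with a partition")
    xyz = system.coordinates if frame is None else np.asarray(frame, float)
    ri = system.receptor_indices
    li = system.ligand_indices
    q, rm, ep = system.charges, system.lj_radii, system.lj_epsilons
    el = coulomb_interaction(xyz[ri], q[ri], xyz[li], q[li])
    vdw = lj_interaction(xyz[ri], rm[ri], ep[ri], xyz[li], rm[li], ep[li])
    return GasPhaseEnergy(el=el, vdw=vdw)


def nonbonded_exclusions(n_atoms: int, bonds: list[tuple[int, int]],
                         serial_to_index: dict[int, int]) -> set[tuple[int, int]]:
    """1-2 and 1-3 excluded index pairs from a bond list (1-4 unscaled)."""
    adj: dict[int, set[int]] = {i: set() for i in range(n_atoms)}
    for si, sj in bonds:
        if si in serial_to_index and sj in serial_to_index:
            i, j = serial_to_index[si], serial_to_index[sj]
            adj[i].add(j)
            adj[j].add(i)
    excl: set[tuple[int, int]] = set()
    for i in range(n_atoms):
        for j in adj[i]:           # 1-2
            excl.add((min(i, j), max(i, j)))
            for k in adj[j]:       # 1-3
                if k != i:
                    excl.add((min(i, k), max(i, k)))
    return excl


def intragroup_energy(coords: np.ndarray, charges: np.ndarray,
                      rmin_half: np.ndarray, eps: np.ndarray,
                      exclusions: set[tuple[int, int]] | None = None
                      ) -> GasPhaseEnergy:
    """Full intra-group nonbonded energy over unique pairs minus exclusions.

    Only used for the single-trajectory cancellation identity; the
    binding energy itself never needs intramolecular terms.
    """
    n = coords.shape[0]
    if n < 2:
        return GasPhaseEnergy(0.0, 0.0)
    iu, ju = np.triu_indices(n, k=1)
    if exclusions:
        mask = np.array([(i, j) not in exclusions for i, j in zip(iu, ju)])
        iu, ju = iu[mask], ju[mask]
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    if d.size and d.min() <= 0:
        raise ZeroDistanceError("zero distance inside group")
    el = float(COULOMB_CONSTANT * np.sum(charges[iu] * charges[ju] / d))
    rmin = rmin_half[iu] + rmin_half[ju]
    e = np.sqrt(eps[iu] * eps[ju])
    x6 = (rmin / d) ** 6
    vdw = float(np.sum(e * (x6 * x6 - 2.0 * x6)))
    return GasPhaseEnergy(el=el, vdw=vdw)
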