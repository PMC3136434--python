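"""Computational alanine and glycine scanning by side-chain truncation.

Mutants are built geometrically on existing snapshots: an alanine mutant
truncates the side chain at Cβ and replaces the Cγ atom with a hydrogen
at a fixed length along the Cβ–Cγ bond; a glycine mutant (applied to
alanines, conventionally in hotspots) truncates at Cα the same way.  No
re-minimization is performed, so all non-mutated coordinates are
bit-identical between wild type and mutant, and ΔΔG is a pure
truncate-and-recompute difference averaged over snapshots.  By default
the per-residue ΔΔG is enthalpic (gas + solvation); the normal-mode
entropy term can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomRecord, ConformerEnsemble, MolecularSystem
from .mm import gas_phase_binding
from .pipeline import binding_solvation
from .solvation import DEFAULT_GAMMA, DEFAULT_SA_OFFSET, PBSettings

__all__ = [
    "ScanEntry",
    "make_alanine_mutant",
    "make_glycine_mutant",
    "scan",
]

#: Default C–H bond length for the replacement hydrogen, Å.
DEFAULT_CH_LENGTH = 1.09

_BACKBONE = {"N", "CA", "C", "O", "H", "HA", "HA2", "HA3", "OXT",
             "H1", "H2", "H3"}


@dataclass
class ScanEntry:
    """Per-residue scan result: ΔΔG = ΔG_mut − ΔG_wt, kcal/mol."""

    position: int
    wild_type: str
    mutation: str  # "ala" | "gly" | "none"
    ddg: float
    d_el: float
    d_vdw: float
    d_polar: float
    d_nonpolar: float
    n_snapshots: int

    def as_dict(self) -> dict:
        return {
            "position": self.position, "wild_type": self.wild_type,
            "mutation": self.mutation, "ddg_kcal_mol": self.ddg,
            "d_el_kcal_mol": self.d_el, "d_vdw_kcal_mol": self.d_vdw,
            "d_polar_kcal_mol": self.d_polar,
            "d_nonpolar_kcal_mol": self.d_nonpolar,
            "n_snapshots": self.n_snapshots,
        }


def _residue_atoms(system: MolecularSystem, residue_index: int,
                   ligand_only: bool = True) -> list[AtomRecord]:
    lig = set(system.ligand_serials) if ligand_only else None
    return [a for a in system.atoms if a.residue_index == residue_index
            and (lig is None or a.serial in lig)]


def _find(atoms: list[AtomRecord], name: str) -> AtomRecord | None:
    for a in atoms:
        if a.name == name:
            return a
    return None


def _gamma_neighbours(atoms: list[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if len(a.name) >= 2 and a.name[1] == "G"
            and a.name[0] in ("C", "O", "S", "N")]


def _truncate(system: MolecularSystem, frame: np.ndarray, residue: int,
              anchor_name: str, removed_names: set[str], h_name: str,
              h_params: tuple[float, float, float, float],
              ch_length: float) -> tuple[MolecularSystem, np.ndarray]:
    """Remove ``removed_names`` atoms of a ligand residue; cap the anchor
    with one hydrogen along anchor→first-removed-neighbour."""
    res_atoms = _residue_atoms(system, residue)
    anchor = _find(res_atoms, anchor_name)
    if anchor is None:
        raise ValueError(f"residue {residue} has no {anchor_name} atom")
    removed = [a for a in res_atoms if a.name in removed_names]
    if not removed:
        raise ValueError(f"residue {residue}: no side chain to truncate")
    s2i = system.serial_to_index()
    # direction: anchor -> the removed atom bonded to the anchor
    bonded_removed = None
    removed_serials = {a.serial for a in removed}
    for i, j in system.bonds:
        if i == anchor.serial and j in removed_serials:
            bonded_removed = j
            break
        if j == anchor.serial and i in removed_serials:
            bonded_removed = i
            break
    if bonded_removed is None:
        bonded_removed = removed[0].serial
    frame = np.asarray(frame, float)
    p_anchor = frame[s2i[anchor.serial]]
    p_gone = frame[s2i[bonded_removed]]
    v = p_gone - p_anchor
    v = v / np.linalg.norm(v)
    h_pos = p_anchor + ch_length * v

    keep_mask = np.array([a.serial not in removed_serials
                          for a in system.atoms])
    new_serial = max(a.serial for a in system.atoms) + 1
    q, r, e, m = h_params
    h_atom = AtomRecord(serial=new_serial, name=h_name, element="H",
                        residue_index=residue,
                        residue_name=anchor.residue_name,
                        chain_id=anchor.chain_id, position=h_pos,
                        charge=q, lj_radius=r, lj_epsilon=e, mass=m)
    atoms = [a.copy() for a, k in zip(system.atoms, keep_mask) if k]
    atoms.append(h_atom)
    bonds = [(i, j) for i, j in system.bonds
             if i not in removed_serials and j not in removed_serials]
    bonds.append((anchor.serial, new_serial))
    new_frame = np.vstack([frame[keep_mask], h_pos[None, :]])
    lig = (set(system.ligand_serials) - removed_serials) | {new_serial}
    mutant = MolecularSystem(
        atoms=atoms, bonds=bonds, role="complex",
        receptor_serials=system.receptor_serials,
        ligand_serials=frozenset(lig))
    return mutant, new_frame


def make_alanine_mutant(system: MolecularSystem, frame: np.ndarray,
                        residue: int, parameters=None,
                        ch_length: float = DEFAULT_CH_LENGTH
                        ) -> tuple[MolecularSystem, np.ndarray]:
    """Truncate a ligand residue's side chain at Cβ (alanine mutant).

    All side-chain atoms beyond Cβ are removed and one hydrogen with
    alanine Hβ parameters is placed on the Cβ→Cγ unit vector at
    ``ch_length``.  Glycine targets (no side chain) and residues lacking
    a Cβ raise.
    """
    res_atoms = _residue_atoms(system, residue)
    if not res_atoms:
        raise ValueError(f"residue {residue} not found in ligand")
    if res_atoms[0].residue_name == "GLY":
        raise ValueError(f"residue {residue} is glycine: no side chain to truncate")
    if _find(res_atoms, "CB") is None:
        raise ValueError(f"residue {residue} has no CB atom")
    if not _gamma_neighbours(res_atoms):
        raise ValueError(
            f"residue {residue} has no gamma atom: already alanine-like")
    removed = {a.name for a in res_atoms
               if a.name not in _BACKBONE and a.name != "CB"
               and not a.name.startswith("HB")}
    h_params = _h_parameters(parameters, "ALA", "HB1")
    return _truncate(system, frame, residue, "CB", removed, "HB1",
                     h_params, ch_length)


def make_glycine_mutant(system: MolecularSystem, frame: np.ndarray,
                        residue: int, parameters=None,
                        ch_length: float = DEFAULT_CH_LENGTH
                        ) -> tuple[MolecularSystem, np.ndarray]:
    """Truncate a ligand residue at Cα (glycine mutant).

    Removes the whole side chain including Cβ; an Hα2 hydrogen with
    glycine parameters is placed along Cα→Cβ at ``ch_length``.
    """
    res_atoms = _residue_atoms(system, residue)
    if not res_atoms:
        raise ValueError(f"residue {residue} not found in ligand")
    if res_atoms[0].residue_name == "GLY":
        raise ValueError(f"residue {residue} is already glycine")
    if _find(res_atoms, "CB") is None:
        raise ValueError(f"residue {residue} has no CB atom")
    removed = {a.name for a in res_atoms if a.name not in _BACKBONE}
    h_params = _h_parameters(parameters, "GLY", "HA2")
    return _truncate(system, frame, residue, "CA", removed, "HA2",
                     h_params, ch_length)


def _h_parameters(parameters, residue_name: str, atom_name: str
                  ) -> tuple[float, float, float, float]:
    """Replacement-hydrogen parameters from the table, or neutral defaults."""
    if parameters is not None:
        try:
            return parameters.lookup(residue_name, atom_name)
        except KeyError:
            pass
    return (0.0, 1.387, 0.0157, 1.008)


def scan(ensemble: ConformerEnsemble, positions: list[int] | None = None,
         stride_ps: float | None = None, mode: str = "auto",
         parameters=None, settings: PBSettings | None = None,
         gamma: float = DEFAULT_GAMMA, offset: float = DEFAULT_SA_OFFSET,
         ch_length: float = DEFAULT_CH_LENGTH,
         include_solvation: bool = True,
         sasa_points: int = 960) -> list[ScanEntry]:
    """Alanine/glycine scan over ligand positions, averaged over snapshots.

    ``mode='auto'`` applies a glycine mutation where the wild type is
    alanine and an alanine mutation elsewhere; ``'ala'``/``'gly'`` force
    one kind.  Alanine targets under an alanine scan yield a defined
    zero entry.  ΔΔG = ΔG_mut − ΔG_wt is enthalpic (gas + PB + SA) on
    otherwise identical coordinates; set ``include_solvation=False`` for
    gas-phase-only deltas.
    """
    settings = settings or PBSettings()
    system = ensemble.topology
    if system.role != "complex":
        raise ValueError("scan expects a complex ensemble")
    if positions is None:
        positions = system.ligand_residue_indices()
    idx = ensemble.frame_selection(stride_ps)

    res_names = {}
    for p in positions:
        atoms = _residue_atoms(system, p)
        if not atoms:
            raise ValueError(f"position {p} not found in ligand")
        res_names[p] = atoms[0].residue_name

    # wild-type terms per frame, computed once
    wt_terms = []
    for k in idx:
        frame = ensemble.frames[k]
        gas = gas_phase_binding(system, frame)
        if include_solvation:
            d_pb, d_sa = binding_solvation(system, frame, settings, gamma,
                                           offset, sasa_points)
        else:
            d_pb = d_sa = 0.0
        wt_terms.append((gas.el, gas.vdw, d_pb, d_sa))
    wt_terms = np.array(wt_terms)

    entries = []
    for p in positions:
        wt = res_names[p]
        if mode == "auto":
            mut_kind = "gly" if wt == "ALA" else "ala"
        else:
            mut_kind = mode
        if mut_kind == "ala" and wt == "ALA":
            entries.append(ScanEntry(position=p, wild_type=wt, mutation="none",
                                     ddg=0.0, d_el=0.0, d_vdw=0.0, d_polar=0.0,
                                     d_nonpolar=0.0, n_snapshots=len(idx)))
            continue
        make = make_glycine_mutant if mut_kind == "gly" else make_alanine_mutant
        deltas = []
        for row, k in enumerate(idx):
            frame = ensemble.frames[k]
            mutant, mframe = make(system, frame, p, parameters, ch_length)
            gas = gas_phase_binding(mutant, mframe)
            if include_solvation:
                d_pb, d_sa = binding_solvation(mutant, mframe, settings,
                                               gamma, offset, sasa_points)
            else:
                d_pb = d_sa = 0.0
            deltas.append(np.array([gas.el, gas.vdw, d_pb, d_sa]) -
                          wt_terms[row])
        mean = np.mean(deltas, axis=0)
        entries.append(ScanEntry(
            position=p, wild_type=wt, mutation=mut_kind,
            ddg=float(mean.sum()), d_el=float(mean[0]), d_vdw=float(mean[1]),
            d_polar=float(mean[2]), d_nonpolar=float(mean[3]),
            n_snapshots=len(idx)))
    return sorted(entries, key=lambda e: e.position)
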