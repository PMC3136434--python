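"""Domain types and I/O: atoms, systems, conformer ensembles, PDB and
parameter-table readers/writers, ligand truncation.

A :class:`MolecularSystem` couples PDB-style topology (names, residues,
bonds) with the nonbonded parameters (partial charge, Lennard-Jones
r_min/2 radius and well depth, mass) needed by the energy terms.  A
complex additionally carries a receptor/ligand partition so the
single-trajectory binding terms can be formed from one coordinate set.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "ConformerEnsemble",
    "ParameterTable",
    "ParameterLookupError",
    "PDBParseError",
    "read_parameter_table",
    "write_parameter_table",
    "read_pdb",
    "write_pdb",
    "truncate_ligand",
    "net_charge",
]


class ParameterLookupError(KeyError):
    """A (residue, atom) pair is missing from the parameter table."""


class PDBParseError(ValueError):
    """A PDB record could not be parsed; carries the line number."""


@dataclass
class AtomRecord:
    """One atom with coordinates and nonbonded parameters.

    ``lj_radius`` is the per-atom r_min/2 (Å); pair minima combine
    arithmetically (Lorentz–Berthelot), well depths geometrically.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    charge: float = 0.0
    lj_radius: float = 0.0
    lj_epsilon: float = 0.0
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.lj_radius < 0 or self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: LJ parameters must be non-negative")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")

    def copy(self) -> "AtomRecord":
        return dataclasses.replace(self, position=self.position.copy())


@dataclass
class MolecularSystem:
    """An ordered set of atoms with bonds and an optional complex partition.

    ``role`` is one of ``receptor``, ``ligand`` or ``complex``.  For a
    complex, ``receptor_serials``/``ligand_serials`` must disjointly and
    exactly cover all atom serials.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    role: str = "complex"
    receptor_serials: frozenset[int] = field(default_factory=frozenset)
    ligand_serials: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique")
        if self.role not in ("receptor", "ligand", "complex"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "complex" and self.atoms:
            r, l = frozenset(self.receptor_serials), frozenset(self.ligand_serials)
            if r & l:
                raise ValueError("receptor/ligand partition overlaps")
            if (r | l) != set(serials):
                raise ValueError("partition must exactly cover all atom serials")
            self.receptor_serials, self.ligand_serials = r, l

    # -- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def lj_radii(self) -> np.ndarray:
        return np.array([a.lj_radius for a in self.atoms], dtype=float)

    @property
    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def serial_to_index(self) -> dict[int, int]:
        return {a.serial: i for i, a in enumerate(self.atoms)}

    def indices_of(self, serials: Iterable[int]) -> np.ndarray:
        s2i = self.serial_to_index()
        return np.array(sorted(s2i[s] for s in serials), dtype=int)

    @property
    def receptor_indices(self) -> np.ndarray:
        return self.indices_of(self.receptor_serials)

    @property
    def ligand_indices(self) -> np.ndarray:
        return self.indices_of(self.ligand_serials)

    def ligand_residue_indices(self) -> list[int]:
        """Sorted residue indices occurring in the ligand partition."""
        lig = set(self.ligand_serials)
        return sorted({a.residue_index for a in self.atoms if a.serial in lig})

    def subsystem(self, serials: Iterable[int], role: str) -> "MolecularSystem":
        """New system containing only the given serials (order preserved)."""
        keep = set(serials)
        atoms = [a.copy() for a in self.atoms if a.serial in keep]
        bonds = [b for b in self.bonds if b[0] in keep and b[1] in keep]
        return MolecularSystem(atoms=atoms, bonds=bonds, role=role)

    def receptor_subsystem(self) -> "MolecularSystem":
        return self.subsystem(self.receptor_serials, "receptor")

    def ligand_subsystem(self) -> "MolecularSystem":
        return self.subsystem(self.ligand_serials, "ligand")

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            atoms=[a.copy() for a in self.atoms],
            bonds=list(self.bonds),
            role=self.role,
            receptor_serials=frozenset(self.receptor_serials),
            ligand_serials=frozenset(self.ligand_serials),
        )


@dataclass
class ConformerEnsemble:
    """Ordered snapshots of one topology with strictly increasing times (ps)."""

    topology: MolecularSystem
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # ps
    stride_ps: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("every frame must match the topology atom count")
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_selection(self, stride_ps: float | None = None,
                        start_ps: float | None = None) -> np.ndarray:
        """Indices of frames at the requested analysis stride.

        ``stride_ps`` must be a multiple of the stored stride; frames whose
        (time − first time) is a multiple of it are selected, optionally
        from ``start_ps`` onwards.
        """
        if stride_ps is None:
            idx = np.arange(self.n_frames)
        else:
            ratio = stride_ps / self.stride_ps
            if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
                raise ValueError(
                    f"analysis stride {stride_ps} ps is not a multiple of the "
                    f"frame stride {self.stride_ps} ps")
            idx = np.arange(0, self.n_frames, int(round(ratio)))
        if start_ps is not None:
            idx = idx[self.times[idx] >= start_ps]
        return idx


# ---------------------------------------------------------------------------
# Parameter table I/O
# ---------------------------------------------------------------------------

@dataclass
class ParameterTable:
    """Nonbonded parameters keyed by (residue_name, atom_name), plus bonds.

    The text format is whitespace-delimited with a header line::

        residue atom charge lj_radius lj_epsilon mass
        GLY     CA   0.10   1.908     0.1094     12.01
        ...
        [bonds]
        serial_i serial_j
    """

    entries: dict[tuple[str, str], tuple[float, float, float, float]]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def lookup(self, residue_name: str, atom_name: str):
        key = (residue_name.upper(), atom_name.upper())
        if key not in self.entries:
            raise ParameterLookupError(
                f"no parameters for residue/atom pair {key!r}")
        return self.entries[key]

    def assign(self, atom: AtomRecord) -> None:
        q, r, e, m = self.lookup(atom.residue_name, atom.name)
        atom.charge, atom.lj_radius, atom.lj_epsilon, atom.mass = q, r, e, m


def read_parameter_table(path: str | Path) -> ParameterTable:
    entries: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    bonds: list[tuple[int, int]] = []
    section = "params"
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower() == "[bonds]":
            section = "bonds"
            continue
        parts = line.split()
        if section == "params":
            if parts[0].lower() == "residue":  # header
                continue
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            res, atom = parts[0].upper(), parts[1].upper()
            entries[(res, atom)] = tuple(float(x) for x in parts[2:6])
        else:
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: bond lines need 2 serials")
            bonds.append((int(parts[0]), int(parts[1])))
    return ParameterTable(entries=entries, bonds=bonds)


def write_parameter_table(table: ParameterTable, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("residue atom charge lj_radius lj_epsilon mass\n")
    for (res, atom), (q, r, e, m) in sorted(table.entries.items()):
        buf.write(f"{res:<7s} {atom:<4s} {q: .6f} {r:.6f} {e:.6f} {m:.4f}\n")
    if table.bonds:
        buf.write("[bonds]\n")
        for i, j in table.bonds:
            buf.write(f"{i} {j}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        return dict(
            serial=int(line[6:11]),
            name=line[12:16].strip(),
            residue_name=line[17:20].strip(),
            chain_id=(line[21] if len(line) > 21 else " ").strip() or "A",
            residue_index=int(line[22:26]),
            position=np.array([float(line[30:38]), float(line[38:46]),
                               float(line[46:54])]),
            element=(line[76:78].strip() if len(line) >= 77 else "") or
                    line[12:16].strip()[:1],
        )
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record: {exc}") from exc


def read_pdb(path: str | Path, parameters: ParameterTable | None = None,
             role: str = "complex",
             ligand_chain: str | None = None):
    """Read a PDB file into a system or, for multi-model files, an ensemble.

    MODEL/ENDMDL records delimit frames; every model must list the same
    atoms.  If ``parameters`` is given, each atom's charge/LJ/mass are
    assigned from it (missing pairs raise :class:`ParameterLookupError`)
    and the table's bond list is attached.  For ``role='complex'`` the
    partition is taken from ``ligand_chain`` (defaults to the last chain
    in the file).
    """
    text = Path(path).read_text()
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    saw_model = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip()
        if rec == "MODEL":
            saw_model = True
            in_model = True
            current = []
        elif rec == "ENDMDL":
            in_model = False
            models.append(current)
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(raw, lineno))
    if not saw_model:
        models = [current]
    elif in_model and current:
        models.append(current)
    if not models or not models[0]:
        raise PDBParseError("no ATOM/HETATM records found")

    first = models[0]
    atoms = []
    for d in first:
        atom = AtomRecord(**d)
        if parameters is not None:
            parameters.assign(atom)
        atoms.append(atom)

    bonds = list(parameters.bonds) if parameters is not None else []
    if role == "complex":
        chains = [a.chain_id for a in atoms]
        lig_chain = ligand_chain if ligand_chain is not None else chains[-1]
        lig = frozenset(a.serial for a in atoms if a.chain_id == lig_chain)
        rec_serials = frozenset(a.serial for a in atoms) - lig
        system = MolecularSystem(atoms=atoms, bonds=bonds, role="complex",
                                 receptor_serials=rec_serials,
                                 ligand_serials=lig)
    else:
        system = MolecularSystem(atoms=atoms, bonds=bonds, role=role)

    if len(models) == 1:
        return system

    n = len(first)
    frames = np.empty((len(models), n, 3))
    for m, model in enumerate(models):
        if len(model) != n:
            raise PDBParseError(
                f"model {m + 1} has {len(model)} atoms, expected {n}")
        frames[m] = [d["position"] for d in model]
    times = np.arange(len(models), dtype=float)
    return ConformerEnsemble(topology=system, frames=frames, times=times,
                             stride_ps=1.0)


def write_pdb(obj: MolecularSystem | ConformerEnsemble,
              path: str | Path) -> None:
    """Write a system (single model) or ensemble (MODEL/ENDMDL) as PDB."""
    if isinstance(obj, ConformerEnsemble):
        system, frames = obj.topology, obj.frames
        multi = True
    else:
        system, frames = obj, obj.coordinates[None, :, :]
        multi = False
    lines: list[str] = []
    for m in range(frames.shape[0]):
        if multi:
            lines.append(f"MODEL     {m + 1:4d}")
        prev_chain = None
        for a, xyz in zip(system.atoms, frames[m]):
            if prev_chain is not None and a.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = a.chain_id
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial:5d} {name}{'':1s}{a.residue_name:>3s} "
                f"{a.chain_id}{a.residue_index:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}")
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# System-level operations
# ---------------------------------------------------------------------------

def net_charge(system: MolecularSystem) -> float:
    """Algebraic sum of partial charges, in e."""
    if not system.atoms:
        return 0.0
    return float(np.sum(system.charges))


_BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT", "H1", "H2", "H3"}

#: Default X–H bond length for capping hydrogens, Å.
DEFAULT_CH_LENGTH = 1.09


def truncate_ligand(system: MolecularSystem, keep: tuple[int, int],
                    cap: str = "hydrogen",
                    ch_length: float = DEFAULT_CH_LENGTH) -> MolecularSystem:
    """Restrict the ligand to a residue-index range, capping severed bonds.

    ``keep`` is an inclusive 1-based (lo, hi) range of ligand residue
    indices.  Ligand atoms outside the range are removed; each severed
    backbone bond is capped by a hydrogen placed along the old bond vector
    at ``ch_length`` (``cap='none'`` leaves the termini open).  The
    receptor is untouched.
    """
    if system.role != "complex":
        raise ValueError("truncate_ligand expects a complex")
    lo, hi = keep
    lig_res = system.ligand_residue_indices()
    kept_res = [r for r in lig_res if lo <= r <= hi]
    if not kept_res:
        raise ValueError(
            f"keep range {keep} has empty intersection with ligand residues "
            f"{lig_res[0]}..{lig_res[-1]}")
    lig = set(system.ligand_serials)
    removed = {a.serial for a in system.atoms
               if a.serial in lig and not (lo <= a.residue_index <= hi)}
    kept = [a.copy() for a in system.atoms if a.serial not in removed]
    s2a = {a.serial: a for a in system.atoms}
    caps: list[AtomRecord] = []
    next_serial = max(a.serial for a in system.atoms) + 1
    bonds: list[tuple[int, int]] = []
    for i, j in system.bonds:
        if i in removed and j in removed:
            continue
        if i in removed or j in removed:
            survivor, lost = (j, i) if i in removed else (i, j)
            if cap == "hydrogen":
                sa, la = s2a[survivor], s2a[lost]
                v = la.position - sa.position
                v = v / np.linalg.norm(v)
                caps.append(AtomRecord(
                    serial=next_serial, name="HC", element="H",
                    residue_index=sa.residue_index,
                    residue_name=sa.residue_name, chain_id=sa.chain_id,
                    position=sa.position + ch_length * v,
                    charge=0.0, lj_radius=0.6, lj_epsilon=0.0157, mass=1.008))
                bonds.append((survivor, next_serial))
                next_serial += 1
            continue
        bonds.append((i, j))
    atoms = kept + caps
    new_lig = (lig - removed) | {c.serial for c in caps}
    return MolecularSystem(
        atoms=atoms, bonds=bonds, role="complex",
        receptor_serials=system.receptor_serials,
        ligand_serials=frozenset(new_lig))
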