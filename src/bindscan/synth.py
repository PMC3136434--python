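"""Synthetic toy receptor–hairpin complexes with stored ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at a few dozen atoms: a 15-residue hairpin ligand lying in a
receptor groove with its binding energy concentrated in a 4-residue
FxxA-like hotspot (bulky residue 06, polar 07/08, alanine 09 buried in
attractive pockets), a series of ligands of net charge +1…+3 facing an
anionic receptor patch, intermittent donor–acceptor hydrogen bonds
realized as two-state telegraph processes with prescribed fractional
occupancy, and harmonic positional fluctuation about the reference pose.
Residue/atom naming follows PDB conventions so every I/O path is
exercised.  All outputs are exactly reproducible from (spec, seed), and
every stored analytic energy is a brute-force pair sum over the
reference pose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (AtomRecord, ConformerEnsemble, MolecularSystem,
                   ParameterTable)
from .energymodel import EnergyModel
from .qmpbsa import HighLevelRecord
from .ti import (SoftCoreParams, TIStage, gauss_nodes,
                 metropolis_sample_1d, softcore_lj)
from .units import COULOMB_CONSTANT, kt

__all__ = [
    "IntermittentBondSpec",
    "FixtureSpec",
    "GroundTruth",
    "build_complex",
    "sample_ensemble",
    "emit_highlevel_records",
    "emit_ti_samples",
    "three_stage_toy",
]


@dataclass(frozen=True)
class IntermittentBondSpec:
    """A donor (ligand residue, atom name) toggling against a generated
    receptor acceptor between on/off distances at a target occupancy."""

    donor_residue: int
    donor_atom: str = "CB"
    occupancy: float = 0.65
    d_on: float = 2.8   # Å, satisfies the default H-bond criterion
    d_off: float = 5.0  # Å, violates it

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one toy complex; ``seed`` is mandatory."""

    seed: int
    n_ligand_residues: int = 15
    hotspot_positions: tuple[int, ...] = (6, 7, 8, 9)
    ligand_net_charge: int = 1
    intermittent_bonds: tuple[IntermittentBondSpec, ...] = ()
    fluctuation_sigma: float = 0.08  # Å
    n_frames: int = 50
    stride_ps: float = 6.0
    dwell_frames: float = 3.0   # mean on-state dwell of telegraph bonds

    def __post_init__(self) -> None:
        if self.fluctuation_sigma < 0:
            raise ValueError("fluctuation sigma must be non-negative")
        if not 1 <= self.ligand_net_charge <= 3:
            raise ValueError("charge series covers +1..+3")
        if self.n_ligand_residues < max(self.hotspot_positions, default=0):
            raise ValueError("hotspot positions exceed ligand length")


@dataclass
class GroundTruth:
    """Analytic bookkeeping at the reference pose (brute-force pair sums)."""

    reference_el: float
    reference_vdw: float
    sidechain_energies: dict[int, float]
    scan_ddg_gas: dict[int, float]
    bond_occupancies: dict[int, float]
    ligand_net_charge: float

    @property
    def reference_gas_total(self) -> float:
        return self.reference_el + self.reference_vdw


# nonbonded parameters: (charge, lj_radius(r_min/2), lj_epsilon, mass)
_PARAMS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("SER", "N"): (0.0, 1.85, 0.08, 14.01),
    ("SER", "CA"): (0.0, 1.90, 0.08, 12.01),
    ("SER", "C"): (0.0, 1.90, 0.08, 12.01),
    ("SER", "CB"): (0.0, 1.90, 0.10, 12.01),
    ("SER", "OG"): (0.0, 1.70, 0.10, 16.00),
    ("LYS", "N"): (1.0, 1.85, 0.08, 14.01),
    ("LYS", "CA"): (0.0, 1.90, 0.08, 12.01),
    ("LYS", "C"): (0.0, 1.90, 0.08, 12.01),
    ("LYS", "CB"): (0.0, 1.90, 0.10, 12.01),
    ("LYS", "CG"): (0.0, 1.90, 0.10, 12.01),
    ("PHE", "N"): (0.0, 1.85, 0.08, 14.01),
    ("PHE", "CA"): (0.0, 1.90, 0.08, 12.01),
    ("PHE", "C"): (0.0, 1.90, 0.08, 12.01),
    ("PHE", "CB"): (0.0, 1.90, 0.10, 12.01),
    ("PHE", "CG"): (0.0, 1.90, 0.12, 12.01),
    ("THR", "N"): (0.0, 1.85, 0.08, 14.01),
    ("THR", "CA"): (0.0, 1.90, 0.08, 12.01),
    ("THR", "C"): (0.0, 1.90, 0.08, 12.01),
    ("THR", "CB"): (0.0, 1.90, 0.10, 12.01),
    ("THR", "OG1"): (0.0, 1.70, 0.12, 16.00),
    ("ALA", "N"): (0.0, 1.85, 0.08, 14.01),
    ("ALA", "CA"): (0.0, 1.90, 0.08, 12.01),
    ("ALA", "C"): (0.0, 1.90, 0.08, 12.01),
    ("ALA", "CB"): (0.0, 1.90, 0.10, 12.01),
    # replacement hydrogens for the truncation mutants: inert by design,
    # so a scan ΔΔG is exactly the removed side chain's interaction
    ("ALA", "HB1"): (0.0, 1.387, 0.0, 1.008),
    ("GLY", "HA2"): (0.0, 1.387, 0.0, 1.008),
    # receptor
    ("REC", "CA"): (0.0, 2.00, 0.06, 40.0),
    ("ASP", "OD"): (-1.0, 1.70, 0.10, 16.00),
    ("PKT", "PK1"): (0.0, 2.00, 75.0, 40.0),   # phenyl pocket
    ("PKT", "PK2"): (0.0, 2.00, 12.0, 40.0),   # polar pockets
    ("PKT", "PK3"): (0.0, 2.00, 12.0, 40.0),
    ("PKT", "PK4"): (0.0, 2.00, 40.0, 40.0),   # alanine pocket
    ("ACC", "OA"): (0.0, 1.70, 0.05, 16.00),
}

#: residue types along the hairpin: bulky 06, polar 07/08, ALA 09,
#: LYS at the charge-carrying backbone sites, SER elsewhere
_CHARGE_SITES = {1: (13,), 2: (2, 13), 3: (2, 13, 15)}


def _ligand_backbone_positions(n: int) -> list[np.ndarray]:
    """CA positions of an n-residue hairpin (two strands + turn)."""
    half = (n + 1) // 2
    pos = []
    for i in range(1, n + 1):
        if i < half:
            pos.append(np.array([3.5 * (i - 1), 2.0, 4.0]))
        elif i == half:
            pos.append(np.array([3.5 * (half - 1) + 1.5, 0.0, 4.2]))
        else:
            pos.append(np.array([3.5 * (n - i), -2.0, 4.4]))
    return pos


def build_complex(spec: FixtureSpec
                  ) -> tuple[MolecularSystem, ParameterTable, GroundTruth]:
    """Build the toy complex, its parameter table and ground truth."""
    n = spec.n_ligand_residues
    hotspots = set(spec.hotspot_positions)
    charged = set(_CHARGE_SITES[spec.ligand_net_charge])
    if charged & hotspots:
        raise ValueError("charge sites collide with hotspot positions")
    ca = _ligand_backbone_positions(n)
    down = np.array([0.0, 0.0, -1.0])
    up = np.array([0.0, 0.0, 1.0])

    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    serial = 0

    def add(name, element, res_idx, res_name, chain, pos):
        nonlocal serial
        serial += 1
        q, r, e, m = _PARAMS[(res_name, name)]
        atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                residue_index=res_idx, residue_name=res_name,
                                chain_id=chain, position=np.asarray(pos, float),
                                charge=q, lj_radius=r, lj_epsilon=e, mass=m))
        return serial

    # ---- ligand (chain L, residues 1..n) ------------------------------
    lig_serials = []
    sidechain_tips: dict[int, np.ndarray] = {}
    hotspot_kind = {}
    if hotspots:
        ordered = sorted(hotspots)
        for j, p in enumerate(ordered):
            if j == 0:
                hotspot_kind[p] = "PHE"
            elif j == len(ordered) - 1:
                hotspot_kind[p] = "ALA"
            else:
                hotspot_kind[p] = "THR"
    prev_c = None
    for i in range(1, n + 1):
        if i in hotspots:
            res = hotspot_kind[i]
        elif i in charged:
            res = "LYS"
        else:
            res = "SER"
        p = ca[i - 1]
        s_n = add("N", "N", i, res, "L", p + np.array([-1.2, 0.6, 0.0]))
        s_ca = add("CA", "C", i, res, "L", p)
        s_c = add("C", "C", i, res, "L", p + np.array([1.2, 0.6, 0.0]))
        bonds += [(s_n, s_ca), (s_ca, s_c)]
        if prev_c is not None:
            bonds.append((prev_c, s_n))
        prev_c = s_c
        direction = down if i in hotspots else up
        s_cb = add("CB", "C", i, res, "L", p + 1.53 * direction)
        bonds.append((s_ca, s_cb))
        tip_serial, tip_pos = s_cb, p + 1.53 * direction
        if res == "PHE":
            tip_pos = p + (1.53 + 1.50) * direction
            s_cg = add("CG", "C", i, res, "L", tip_pos)
            bonds.append((s_cb, s_cg))
            tip_serial = s_cg
        elif res == "THR":
            tip_pos = p + (1.53 + 1.40) * direction
            s_og = add("OG1", "O", i, res, "L", tip_pos)
            bonds.append((s_cb, s_og))
            tip_serial = s_og
        elif res == "SER":
            s_og = add("OG", "O", i, res, "L", p + (1.53 + 1.40) * direction)
            bonds.append((s_cb, s_og))
        elif res == "LYS":
            s_cg = add("CG", "C", i, res, "L", p + (1.53 + 1.50) * direction)
            bonds.append((s_cb, s_cg))
        sidechain_tips[i] = (tip_serial, tip_pos)
        lig_serials += [s for s in range(s_n, serial + 1)]

    # ---- receptor (chain R, residues 101+) ----------------------------
    # the anionic patch is a fixed property of the receptor so the whole
    # +1..+3 ligand series faces one and the same binding partner
    patch_sites = [(7.0, -4.2), (3.5, 4.2), (0.0, -4.2)]
    rec_res = 100
    tip_xy = [sidechain_tips[p][1][:2] for p in hotspots]
    for xi in np.arange(-3.5, 3.5 * (n // 2) + 4.0, 3.5):
        for yi in (-5.0, 0.0, 5.0):
            if any(np.hypot(xi - t[0], yi - t[1]) < 4.5 for t in tip_xy):
                continue  # carve the groove under the hotspot pockets
            if any(np.hypot(xi - px, yi - py) < 3.8 for px, py in patch_sites):
                continue  # leave room for the anionic patch
            rec_res += 1
            add("CA", "C", rec_res, "REC", "R", (xi, yi, -1.0))

    # attractive pockets under the hotspot side-chain tips
    for j, p in enumerate(sorted(hotspots), start=1):
        tip_serial, tip_pos = sidechain_tips[p]
        tip = next(a for a in atoms if a.serial == tip_serial)
        pk_name = f"PK{j}"
        r_pair = tip.lj_radius + _PARAMS[("PKT", pk_name)][1]
        rec_res += 1
        add(pk_name, "C", rec_res, "PKT", "R", tip_pos + r_pair * down)

    # anionic patch opposite the charge-carrying sites (net −3, fixed)
    for x, y in patch_sites:
        rec_res += 1
        add("OD", "O", rec_res, "ASP", "R", (x, y, -1.0))

    # acceptors for the intermittent bonds, d_off above each donor tip
    bond_targets = {}
    for b in spec.intermittent_bonds:
        donor = next(a for a in atoms
                     if a.residue_index == b.donor_residue
                     and a.name == b.donor_atom and a.chain_id == "L")
        rec_res += 1
        acc_serial = add("OA", "O", rec_res, "ACC", "R",
                         donor.position + b.d_off * up)
        bond_targets[acc_serial] = (donor.serial, b)

    lig_set = frozenset(lig_serials)
    rec_set = frozenset(a.serial for a in atoms) - lig_set
    system = MolecularSystem(atoms=atoms, bonds=bonds, role="complex",
                             receptor_serials=rec_set,
                             ligand_serials=lig_set)
    system._bond_targets = bond_targets  # consumed by sample_ensemble

    table = ParameterTable(entries=dict(_PARAMS), bonds=list(bonds))
    truth = _ground_truth(system, spec)
    return system, table, truth


def _pair_sum(atoms_a: list[AtomRecord], atoms_b: list[AtomRecord]
              ) -> tuple[float, float]:
    """Brute-force Coulomb + LJ double loop (bookkeeping oracle)."""
    el = vdw = 0.0
    for a in atoms_a:
        for b in atoms_b:
            d = float(np.linalg.norm(a.position - b.position))
            el += COULOMB_CONSTANT * a.charge * b.charge / d
            rmin = a.lj_radius + b.lj_radius
            eps = np.sqrt(a.lj_epsilon * b.lj_epsilon)
            x6 = (rmin / d) ** 6
            vdw += eps * (x6 * x6 - 2.0 * x6)
    return el, vdw


def _ground_truth(system: MolecularSystem, spec: FixtureSpec) -> GroundTruth:
    rec = [a for a in system.atoms if a.serial in system.receptor_serials]
    lig = [a for a in system.atoms if a.serial in system.ligand_serials]
    el, vdw = _pair_sum(rec, lig)
    side_energies = {}
    scan_ddg = {}
    for p in range(1, spec.n_ligand_residues + 1):
        res_atoms = [a for a in lig if a.residue_index == p]
        res_name = res_atoms[0].residue_name
        if res_name == "ALA":
            removed = [a for a in res_atoms if a.name == "CB"]
        else:
            removed = [a for a in res_atoms
                       if a.name not in ("N", "CA", "C", "CB")]
        if not removed:
            side_energies[p] = 0.0
            scan_ddg[p] = 0.0
            continue
        e_el, e_vdw = _pair_sum(rec, removed)
        side_energies[p] = e_el + e_vdw
        # the replacement hydrogen is inert (zero charge and well depth),
        # so the gas-phase scan delta is exactly minus the removed energy
        scan_ddg[p] = -(e_el + e_vdw)
    occ = {b.donor_residue: b.occupancy for b in spec.intermittent_bonds}
    return GroundTruth(reference_el=el, reference_vdw=vdw,
                       sidechain_energies=side_energies,
                       scan_ddg_gas=scan_ddg, bond_occupancies=occ,
                       ligand_net_charge=float(sum(a.charge for a in lig)))


def sample_ensemble(system: MolecularSystem, spec: FixtureSpec
                    ) -> ConformerEnsemble:
    """Reference pose + Gaussian fluctuation + telegraph intermittent bonds.

    Each intermittent bond's donor atom is placed at d_on/d_off from its
    acceptor according to a two-state Markov (telegraph) chain whose
    stationary occupancy is the target and whose mean on-dwell is
    ``spec.dwell_frames`` frames.
    """
    rng = np.random.default_rng(spec.seed)
    ref = system.coordinates
    nf = spec.n_frames
    frames = ref[None, :, :] + rng.normal(
        0.0, spec.fluctuation_sigma, size=(nf, system.n_atoms, 3))

    bond_targets = getattr(system, "_bond_targets", {})
    s2i = system.serial_to_index()
    for acc_serial, (donor_serial, b) in bond_targets.items():
        ai, di = s2i[acc_serial], s2i[donor_serial]
        f = b.occupancy
        # rates with exact stationary occupancy f: f·p_off = (1−f)·p_on
        if f >= 1.0:
            p_off, p_on = 0.0, 1.0
        elif f <= 0.0:
            p_off, p_on = 1.0, 0.0
        else:
            p_off = min(1.0, 1.0 / spec.dwell_frames)
            p_on = p_off * f / (1.0 - f)
            if p_on > 1.0:
                p_on, p_off = 1.0, (1.0 - f) / f
        state = rng.random() < f
        axis = ref[di] - ref[ai]
        axis = axis / np.linalg.norm(axis)
        for k in range(nf):
            d = b.d_on if state else b.d_off
            jitter = rng.normal(0.0, min(spec.fluctuation_sigma, 0.05))
            frames[k, di] = ref[ai] + (d + jitter) * axis
            state = (rng.random() >= p_off) if state else (rng.random() < p_on)
    times = spec.stride_ps * np.arange(nf, dtype=float)
    return ConformerEnsemble(topology=system, frames=frames, times=times,
                             stride_ps=spec.stride_ps)


def emit_highlevel_records(ensemble: ConformerEnsemble, mode: str = "mm_identity",
                           offset: float = 0.0, noise_sigma: float = 0.0,
                           seed: int = 0, stride_ps: float | None = None,
                           with_forces: bool = False,
                           force_noise_sigma: float = 0.0
                           ) -> list[HighLevelRecord]:
    """High-level gas-phase records derived from the MM terms.

    Modes: ``mm_identity`` (record = MM cross energy), ``mm_plus_offset``
    (+ constant) and ``mm_plus_noise`` (+ seeded Gaussian).  Forces, when
    requested, are the analytic MM forces of the full complex model,
    optionally perturbed by Gaussian noise of ``force_noise_sigma``.
    """
    from .mm import gas_phase_binding

    if mode not in ("mm_identity", "mm_plus_offset", "mm_plus_noise"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    system = ensemble.topology
    model = EnergyModel(system) if with_forces else None
    records = []
    for k in ensemble.frame_selection(stride_ps):
        frame = ensemble.frames[k]
        e = gas_phase_binding(system, frame).total
        if mode == "mm_plus_offset":
            e += offset
        elif mode == "mm_plus_noise":
            e += rng.normal(0.0, noise_sigma)
        forces = None
        if with_forces:
            forces = model.forces(frame)
            if force_noise_sigma > 0:
                forces = forces + rng.normal(0.0, force_noise_sigma,
                                             size=forces.shape)
        records.append(HighLevelRecord(frame_time=float(ensemble.times[k]),
                                       gas_binding_energy=float(e),
                                       forces_complex=forces))
    return records


# ---------------------------------------------------------------------------
# Toy alchemical transformations with closed-form / quadrature ground truth
# ---------------------------------------------------------------------------

def _harmonic(k0: float, k1: float):
    def potential(x, lam):
        return 0.5 * ((1 - lam) * k0 + lam * k1) * x * x

    def dvdl(x, lam):
        return 0.5 * (k1 - k0) * x * x

    return potential, dvdl


def _charging(k_trap: float, q: float, ext_field: float, direction: str):
    # V = ½kx² + c(λ)·qE·x; c goes 1→0 (decharge) or 0→1 (recharge)
    sgn = -1.0 if direction == "decharge" else 1.0

    def coupling(lam):
        return 1.0 - lam if direction == "decharge" else lam

    def potential(x, lam):
        return 0.5 * k_trap * x * x + coupling(lam) * q * ext_field * x

    def dvdl(x, lam):
        return sgn * q * ext_field * x

    return potential, dvdl


def _softcore_pair(k_trap: float, site: float, rmin: float, eps: float,
                   params: SoftCoreParams):
    def potential(x, lam):
        e, _ = softcore_lj(abs(x - site), lam, params, rmin, eps)
        return 0.5 * k_trap * x * x + e

    def dvdl(x, lam):
        _, d = softcore_lj(abs(x - site), lam, params, rmin, eps)
        return d

    return potential, dvdl


def _quadrature_delta_g(potential, temperature: float) -> float:
    """ΔG between λ=1 and λ=0 by dense 1-D quadrature of both partition
    functions (oracle path, independent of the Metropolis sampler)."""
    from scipy.integrate import quad

    beta = 1.0 / kt(temperature)
    z = []
    for lam in (0.0, 1.0):
        val, _ = quad(lambda x: np.exp(-beta * potential(x, lam)),
                      -40.0, 40.0, limit=400)
        z.append(val)
    return -kt(temperature) * np.log(z[1] / z[0])


def emit_ti_samples(transformation: str, n_nodes: int = 9,
                    n_per_node: int = 2000, seed: int = 0,
                    temperature: float = 300.0, label: str | None = None,
                    **params) -> tuple[TIStage, float]:
    """Metropolis-sampled dV/dλ per quadrature node plus the exact ΔG.

    Transformations: ``harmonic`` (k0→k1, ΔG = (kT/2)·ln k1/k0),
    ``decharge``/``recharge`` (linear coupling of qE·x in a harmonic
    trap, ΔG = ±q²E²/2k) and ``softcore`` (soft-core LJ appearance or
    disappearance against a trapped particle; ΔG by dense quadrature).
    """
    rng = np.random.default_rng(seed)
    if transformation == "harmonic":
        k0, k1 = params.get("k0", 1.0), params.get("k1", 4.0)
        pot, dvdl = _harmonic(k0, k1)
        truth = 0.5 * kt(temperature) * np.log(k1 / k0)
        default_label = "vdw_softcore"
    elif transformation in ("decharge", "recharge"):
        k_trap = params.get("k_trap", 2.0)
        q = params.get("q", 1.0)
        ext = params.get("ext_field", 1.0)
        pot, dvdl = _charging(k_trap, q, ext, transformation)
        truth = (q * ext) ** 2 / (2.0 * k_trap)
        if transformation == "recharge":
            truth = -truth
        default_label = transformation
    elif transformation == "softcore":
        k_trap = params.get("k_trap", 2.0)
        site = params.get("site", 2.5)
        rmin = params.get("rmin", 3.0)
        eps = params.get("eps", 1.0)
        sc = params.get("softcore", SoftCoreParams(direction="appearing"))
        pot, dvdl = _softcore_pair(k_trap, site, rmin, eps, sc)
        truth = _quadrature_delta_g(pot, temperature)
        default_label = "vdw_softcore"
    else:
        raise ValueError(f"unknown transformation {transformation!r}")

    nodes, weights = gauss_nodes(n_nodes)
    samples = []
    for lam in nodes:
        node_seed = int(rng.integers(0, 2 ** 31 - 1))
        node_rng = np.random.default_rng(node_seed)
        samples.append(metropolis_sample_1d(
            pot, dvdl, lam, n_per_node, node_rng, temperature=temperature))
    stage = TIStage(label=label or default_label, nodes=nodes,
                    weights=weights, samples=samples)
    return stage, float(truth)


def three_stage_toy(seed: int, n_per_node: int = 2000, n_nodes: int = 9,
                    temperature: float = 300.0, null: bool = False
                    ) -> tuple[list[TIStage], float]:
    """Decharge → soft-core vdW → recharge toy path with exact total.

    ``null=True`` makes the end state identical to the start state
    (same charge back on, no vdW change), so the exact total is 0.
    """
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(0, 2 ** 31 - 1)) for _ in range(3)]
    s1, t1 = emit_ti_samples("decharge", n_nodes, n_per_node, seeds[0],
                             temperature, label="decharge",
                             k_trap=2.0, q=1.0, ext_field=1.0)
    if null:
        s2, t2 = emit_ti_samples("harmonic", n_nodes, n_per_node, seeds[1],
                                 temperature, label="vdw_softcore",
                                 k0=2.0, k1=2.0)
        s3, t3 = emit_ti_samples("recharge", n_nodes, n_per_node, seeds[2],
                                 temperature, label="recharge",
                                 k_trap=2.0, q=1.0, ext_field=1.0)
    else:
        s2, t2 = emit_ti_samples("harmonic", n_nodes, n_per_node, seeds[1],
                                 temperature, label="vdw_softcore",
                                 k0=2.0, k1=4.0)
        s3, t3 = emit_ti_samples("recharge", n_nodes, n_per_node, seeds[2],
                                 temperature, label="recharge",
                                 k_trap=4.0, q=0.5, ext_field=1.0)
    return [s1, s2, s3], float(t1 + t2 + t3)
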