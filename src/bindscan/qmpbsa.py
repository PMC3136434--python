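"""Hybrid (QM-PBSA-style) free-energy assembly.

The classical gas-phase term is replaced, snapshot by snapshot, with an
externally supplied high-level (e.g. DFT) gas-phase binding energy, and
the MM polar solvation term is multiplied by a weight derived from a
power-law fit of the polar solvation energy against the solute
dielectric.  The entropy term stays classical.  Also provides the
representative-snapshot selector (mandatory coarse-stride frames plus k
extra frames minimizing a z-scored discrepancy between subset statistics
and full-trajectory values) and per-atom MM-vs-high-level force-error
profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ConformerEnsemble
from .energymodel import EnergyModel
from .entropy import EntropyResult
from .pipeline import BindingFreeEnergy, EnergyDecomposition, binding_free_energy
from .traj import HBondSpec, hbond_occupancy

__all__ = [
    "HighLevelRecord",
    "PowerLawFit",
    "ForceErrorProfile",
    "read_highlevel_records",
    "write_highlevel_records",
    "fit_polar_scaling",
    "hybrid_binding_free_energy",
    "select_representative_snapshots",
    "force_error_profile",
]


@dataclass
class HighLevelRecord:
    """Externally computed gas-phase binding energy for one frame time."""

    frame_time: float
    gas_binding_energy: float
    forces_complex: np.ndarray | None = None   # (n_atoms, 3), kcal/(mol·Å)


@dataclass
class PowerLawFit:
    """|G_polar| = amplitude · ε^exponent fit and the derived solvation weight."""

    amplitude: float
    exponent: float
    rms_residual: float
    scale_factor: float
    sign: float = -1.0

    def evaluate(self, dielectric: float) -> float:
        return self.sign * self.amplitude * dielectric ** self.exponent


@dataclass
class ForceErrorProfile:
    """Per-atom mean |F_high − F_MM|, kcal/(mol·Å)."""

    mean_abs_error: np.ndarray
    atom_labels: list[str]
    n_snapshots: int


def fit_polar_scaling(samples: list[tuple[float, float]],
                      target_dielectric: float = 1.0,
                      reference_dielectric: float = 1.0) -> PowerLawFit:
    """Least-squares power-law fit of polar solvation vs solute dielectric.

    ``samples`` are (solute_dielectric, polar_solvation) pairs of one
    sign; the fit is linear in log–log space.  The solvation weight is
    the fitted curve's ratio between the configured target and reference
    dielectrics, (ε_target/ε_ref)^exponent — the precise weighting rule
    is a configuration point, and the identity default (target = ref)
    leaves the classical result unchanged.
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 (dielectric, energy) samples")
    eps = np.array([s[0] for s in samples], float)
    g = np.array([s[1] for s in samples], float)
    if np.any(eps <= 0):
        raise ValueError("dielectrics must be positive")
    if len(np.unique(eps)) < 3:
        raise ValueError("need at least 3 distinct dielectrics")
    if np.any(g > 0) and np.any(g < 0):
        raise ValueError("polar solvation samples must be of one sign")
    if np.any(g == 0):
        raise ValueError("zero polar solvation sample: singular log fit")
    sign = 1.0 if g[0] > 0 else -1.0
    x = np.log(eps)
    y = np.log(np.abs(g))
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    b, log_a = coef
    resid = y - A @ coef
    rms = float(np.sqrt(np.mean(resid ** 2)))
    scale = (target_dielectric / reference_dielectric) ** b
    return PowerLawFit(amplitude=float(np.exp(log_a)), exponent=float(b),
                       rms_residual=rms, scale_factor=float(scale), sign=sign)


def hybrid_binding_free_energy(decompositions: list[EnergyDecomposition],
                               records: list[HighLevelRecord],
                               fit: PowerLawFit | float = 1.0,
                               entropy: EntropyResult | float = 0.0
                               ) -> BindingFreeEnergy:
    """Assemble ΔG with high-level gas terms and weighted polar solvation.

    Every decomposition's frame time must have a matching record (by
    time, to 1e-6 ps); the polar PB term of each snapshot is multiplied
    by the fit's scale factor, the nonpolar and entropy terms are
    unchanged.
    """
    scale = fit.scale_factor if isinstance(fit, PowerLawFit) else float(fit)
    by_time = {round(r.frame_time, 6): r for r in records}
    missing = [d.frame_time for d in decompositions
               if round(d.frame_time, 6) not in by_time]
    if missing:
        raise ValueError(
            f"no high-level record for frame times {missing}")
    hybrid = []
    for d in decompositions:
        rec = by_time[round(d.frame_time, 6)]
        hybrid.append(EnergyDecomposition(
            el=rec.gas_binding_energy, vdw=0.0,
            polar_pb=scale * d.polar_pb, nonpolar_sa=d.nonpolar_sa,
            frame_time=d.frame_time))
    return binding_free_energy(hybrid, entropy)


def subset_discrepancy(values: np.ndarray, subset: np.ndarray,
                       occupancies: np.ndarray | None = None,
                       occ_subset: np.ndarray | None = None) -> float:
    """Z-scored squared deviation of subset statistics from population ones.

    Statistics: mean and standard deviation of the per-frame totals plus
    each hydrogen bond's occupancy; every deviation is normalized by the
    population standard deviation of the per-frame quantity (equal
    weights).
    """
    pop_std = values.std()
    norm = pop_std if pop_std > 0 else 1.0
    sub = values[subset]
    obj = ((sub.mean() - values.mean()) / norm) ** 2
    obj += ((sub.std() - pop_std) / norm) ** 2
    if occupancies is not None:
        for col in range(occupancies.shape[1]):
            ind = occupancies[:, col]
            s = ind.std() if ind.std() > 0 else 1.0
            obj += ((ind[subset].mean() - ind.mean()) / s) ** 2
    return float(obj)


def select_representative_snapshots(values: np.ndarray, k: int,
                                    mandatory: np.ndarray | None = None,
                                    occupancies: np.ndarray | None = None,
                                    exhaustive_limit: int = 5000
                                    ) -> tuple[np.ndarray, float]:
    """Pick mandatory frames plus ``k`` extras minimizing the discrepancy.

    ``values`` are per-frame enthalpic totals (the full MM ensemble is
    the high-sample reference); ``occupancies`` an optional (n_frames,
    n_bonds) indicator matrix.  Search is exhaustive when the candidate
    pool allows at most ``exhaustive_limit`` subsets, greedy with
    pairwise-swap refinement otherwise.  Returns (sorted frame indices,
    objective value).
    """
    values = np.asarray(values, float)
    n = len(values)
    mandatory = (np.asarray(mandatory, dtype=int) if mandatory is not None
                 else np.zeros(0, dtype=int))
    pool = np.setdiff1d(np.arange(n), mandatory)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds candidate pool of {len(pool)}")

    def objective(extra):
        subset = np.sort(np.concatenate([mandatory, np.asarray(extra, int)]))
        return subset_discrepancy(values, subset, occupancies), subset

    if k == 0:
        obj, subset = objective([])
        return subset, obj

    from math import comb
    if comb(len(pool), k) <= exhaustive_limit:
        best = None
        for extra in itertools.combinations(pool, k):
            obj, subset = objective(extra)
            if best is None or obj < best[0] - 1e-15:
                best = (obj, subset)
        return best[1], best[0]

    # multi-start greedy (one start per pool frame) with swap refinement
    best: tuple[float, np.ndarray] | None = None
    for start in pool:
        chosen = [int(start)]
        while len(chosen) < k:
            scores = [(objective(chosen + [c])[0], c)
                      for c in pool if c not in chosen]
            chosen.append(min(scores)[1])
        improved = True
        cur_obj = objective(chosen)[0]
        while improved:
            improved = False
            for i in range(k):
                for cand in pool:
                    if cand in chosen:
                        continue
                    trial = chosen.copy()
                    trial[i] = cand
                    t_obj = objective(trial)[0]
                    if t_obj < cur_obj - 1e-12:
                        chosen, cur_obj, improved = trial, t_obj, True
        obj, subset = objective(chosen)
        if best is None or obj < best[0] - 1e-15:
            best = (obj, subset)
    return best[1], best[0]


def force_error_profile(ensemble: ConformerEnsemble,
                        records: list[HighLevelRecord],
                        model: EnergyModel | None = None
                        ) -> ForceErrorProfile:
    """Per-atom mean |F_high − F_MM| over recorded frames.

    MM forces are the analytic gradient of the configured energy model
    (the full complex model by default).
    """
    system = ensemble.topology
    model = model or EnergyModel(system)
    by_time = {round(t, 6): i for i, t in enumerate(ensemble.times)}
    errs = np.zeros(system.n_atoms)
    count = 0
    for rec in records:
        if rec.forces_complex is None:
            continue
        key = round(rec.frame_time, 6)
        if key not in by_time:
            raise ValueError(f"record time {rec.frame_time} not in ensemble")
        f_high = np.asarray(rec.forces_complex, float)
        if f_high.shape != (system.n_atoms, 3):
            raise ValueError(
                f"force array shape {f_high.shape} does not match "
                f"({system.n_atoms}, 3)")
        f_mm = model.forces(ensemble.frames[by_time[key]])
        errs += np.linalg.norm(f_high - f_mm, axis=1)
        count += 1
    if count == 0:
        raise ValueError("no records carry forces")
    labels = [f"{a.residue_name}{a.residue_index}:{a.name}"
              for a in system.atoms]
    return ForceErrorProfile(mean_abs_error=errs / count,
                             atom_labels=labels, n_snapshots=count)


# ---------------------------------------------------------------------------
# Text I/O for high-level records (whitespace tables keyed by frame time)
# ---------------------------------------------------------------------------

def write_highlevel_records(records: list[HighLevelRecord],
                            path: str | Path,
                            forces_path: str | Path | None = None) -> None:
    lines = ["time_ps gas_binding_energy_kcal_mol"]
    for r in records:
        lines.append(f"{r.frame_time:.6f} {r.gas_binding_energy:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")
    if forces_path is not None:
        flines = ["time_ps atom_index fx fy fz"]
        for r in records:
            if r.forces_complex is None:
                continue
            for i, f in enumerate(r.forces_complex):
                flines.append(f"{r.frame_time:.6f} {i} "
                              f"{f[0]:.10f} {f[1]:.10f} {f[2]:.10f}")
        Path(forces_path).write_text("\n".join(flines) + "\n")


def read_highlevel_records(path: str | Path,
                           forces_path: str | Path | None = None,
                           n_atoms: int | None = None
                           ) -> list[HighLevelRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("time_ps") or line.startswith("#"):
            continue
        t, e = line.split()[:2]
        records.append(HighLevelRecord(frame_time=float(t),
                                       gas_binding_energy=float(e)))
    if forces_path is not None:
        if n_atoms is None:
            raise ValueError("n_atoms required to read forces")
        by_time = {round(r.frame_time, 6): r for r in records}
        buf: dict[float, np.ndarray] = {}
        for line in Path(forces_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("time_ps") or line.startswith("#"):
                continue
            t, i, fx, fy, fz = line.split()[:5]
            key = round(float(t), 6)
            buf.setdefault(key, np.zeros((n_atoms, 3)))
            buf[key][int(i)] = [float(fx), float(fy), float(fz)]
        for key, arr in buf.items():
            if key in by_time:
                by_time[key].forces_complex = arr
    return records
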