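"""Single-trajectory MM-PBSA ensemble averaging with convergence monitoring.

The binding free energy is assembled per snapshot as

    ΔG_bind = ⟨ΔE_EL + ΔE_vdW + ΔG_PB + ΔG_SA⟩ − TΔS

where the gas terms are receptor↔ligand cross interactions (the
single-trajectory convention cancels intramolecular terms), the
solvation terms are G(complex) − G(receptor) − G(ligand) on shared
coordinates and a shared PB grid box, and the entropy term comes from
normal-mode analysis.  Standard errors are block-averaged to respect
frame autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConformerEnsemble
from .entropy import EntropyResult
from .mm import gas_phase_binding
from .solvation import (DEFAULT_GAMMA, DEFAULT_SA_OFFSET, PBSettings,
                        grid_box_for, nonpolar_term, sasa, solve_pb)
from .traj import block_average

__all__ = [
    "EnergyDecomposition",
    "BindingFreeEnergy",
    "snapshot_decomposition",
    "binding_free_energy",
    "running_average_convergence",
    "relative_to_reference",
]


@dataclass(frozen=True)
class EnergyDecomposition:
    """Per-snapshot binding terms, kcal/mol."""

    el: float
    vdw: float
    polar_pb: float
    nonpolar_sa: float
    frame_time: float = 0.0

    @property
    def gas_total(self) -> float:
        return self.el + self.vdw

    @property
    def solv_total(self) -> float:
        return self.polar_pb + self.nonpolar_sa

    @property
    def enthalpic_total(self) -> float:
        return self.gas_total + self.solv_total


@dataclass
class BindingFreeEnergy:
    """Ensemble-averaged binding free energy and components, kcal/mol."""

    el: float
    vdw: float
    polar_pb: float
    nonpolar_sa: float
    minus_T_delta_S: float
    n_snapshots: int
    standard_error: dict[str, float] = field(default_factory=dict)

    @property
    def gas_total(self) -> float:
        return self.el + self.vdw

    @property
    def solv_total(self) -> float:
        return self.polar_pb + self.nonpolar_sa

    @property
    def enthalpic_total(self) -> float:
        return self.gas_total + self.solv_total

    @property
    def delta_g(self) -> float:
        return self.enthalpic_total + self.minus_T_delta_S

    def as_dict(self) -> dict:
        return {
            "el_kcal_mol": self.el,
            "vdw_kcal_mol": self.vdw,
            "polar_pb_kcal_mol": self.polar_pb,
            "nonpolar_sa_kcal_mol": self.nonpolar_sa,
            "gas_total_kcal_mol": self.gas_total,
            "solv_total_kcal_mol": self.solv_total,
            "enthalpic_total_kcal_mol": self.enthalpic_total,
            "minus_T_delta_S_kcal_mol": self.minus_T_delta_S,
            "delta_g_kcal_mol": self.delta_g,
            "standard_error_kcal_mol": dict(self.standard_error),
            "n_snapshots": self.n_snapshots,
        }


def binding_solvation(system, frame, settings: PBSettings,
                      gamma: float = DEFAULT_GAMMA,
                      offset: float = DEFAULT_SA_OFFSET,
                      sasa_points: int = 960) -> tuple[float, float]:
    """(ΔG_PB, ΔG_SA) for one complex frame, shared grid box."""
    xyz = np.asarray(frame, float)
    q, rad = system.charges, system.lj_radii
    ri, li = system.receptor_indices, system.ligand_indices
    box = grid_box_for(xyz, rad, settings)
    pb_c = solve_pb(xyz, q, rad, settings, box=box)
    pb_r = solve_pb(xyz[ri], q[ri], rad[ri], settings, box=box)
    pb_l = solve_pb(xyz[li], q[li], rad[li], settings, box=box)
    sa_c = sasa(xyz, rad, settings.probe_radius, sasa_points).sum()
    sa_r = sasa(xyz[ri], rad[ri], settings.probe_radius, sasa_points).sum()
    sa_l = sasa(xyz[li], rad[li], settings.probe_radius, sasa_points).sum()
    d_polar = pb_c - pb_r - pb_l
    d_nonpolar = (nonpolar_term(sa_c, gamma, offset) -
                  nonpolar_term(sa_r, gamma, offset) -
                  nonpolar_term(sa_l, gamma, offset))
    return float(d_polar), float(d_nonpolar)


def snapshot_decomposition(ensemble: ConformerEnsemble,
                           stride_ps: float | None = None,
                           settings: PBSettings | None = None,
                           gamma: float = DEFAULT_GAMMA,
                           offset: float = DEFAULT_SA_OFFSET,
                           start_ps: float | None = None,
                           sasa_points: int = 960
                           ) -> list[EnergyDecomposition]:
    """Eq.-style per-snapshot decomposition at the analysis stride."""
    settings = settings or PBSettings()
    system = ensemble.topology
    out = []
    for k in ensemble.frame_selection(stride_ps, start_ps):
        frame = ensemble.frames[k]
        gas = gas_phase_binding(system, frame)
        d_pb, d_sa = binding_solvation(system, frame, settings, gamma, offset,
                                       sasa_points)
        out.append(EnergyDecomposition(el=gas.el, vdw=gas.vdw,
                                       polar_pb=d_pb, nonpolar_sa=d_sa,
                                       frame_time=float(ensemble.times[k])))
    return out


def _block_se(values: np.ndarray) -> float:
    n = len(values)
    if n < 2 or np.allclose(values, values[0]):
        return 0.0
    n_blocks = max(2, int(np.sqrt(n)))
    _, se = block_average(values, n_blocks)
    return se


def binding_free_energy(decompositions: list[EnergyDecomposition],
                        entropy: EntropyResult | float = 0.0
                        ) -> BindingFreeEnergy:
    """Assemble the ensemble-averaged binding free energy.

    ``entropy`` is either an :class:`EntropyResult` or a pre-computed
    −TΔS value in kcal/mol (0 to omit the term).
    """
    if len(decompositions) < 1:
        raise ValueError("empty snapshot selection")
    cols = {name: np.array([getattr(d, name) for d in decompositions])
            for name in ("el", "vdw", "polar_pb", "nonpolar_sa")}
    totals = np.array([d.enthalpic_total for d in decompositions])
    mtds = (entropy.minus_T_delta_S if isinstance(entropy, EntropyResult)
            else float(entropy))
    ses = {k: _block_se(v) for k, v in cols.items()}
    ses["enthalpic_total"] = _block_se(totals)
    return BindingFreeEnergy(
        el=float(cols["el"].mean()), vdw=float(cols["vdw"].mean()),
        polar_pb=float(cols["polar_pb"].mean()),
        nonpolar_sa=float(cols["nonpolar_sa"].mean()),
        minus_T_delta_S=mtds, n_snapshots=len(decompositions),
        standard_error=ses)


def running_average_convergence(times: np.ndarray, values: np.ndarray,
                                window_ps: float, tol: float = 1.0
                                ) -> tuple[bool, np.ndarray]:
    """Convergence flag for the running average of a per-frame series.

    The series is converged iff (max − min) of the running average over
    the trailing ``window_ps`` is ≤ ``tol`` kcal/mol.  Returns the flag
    and the full running-average trace for plotting.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    span = times[-1] - times[0]
    if window_ps > span:
        raise ValueError(
            f"window {window_ps} ps exceeds the series span {span} ps")
    trace = np.cumsum(values) / np.arange(1, len(values) + 1)
    tail = trace[times >= times[-1] - window_ps]
    converged = bool(tail.max() - tail.min() <= tol)
    return converged, trace


def relative_to_reference(results: dict[str, BindingFreeEnergy],
                          reference: str) -> dict[str, float]:
    """ΔΔG of each ligand relative to a named reference ligand."""
    if reference not in results:
        raise KeyError(f"reference ligand {reference!r} not in results")
    ref = results[reference].delta_g
    return {name: r.delta_g - ref for name, r in results.items()}
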