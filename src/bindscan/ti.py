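"""Three-stage thermodynamic integration bookkeeping.

An alchemical mutation is carried along decharge → soft-core vdW
transformation → recharge; each stage's free-energy change is the
λ-integral of ⟨dV/dλ⟩ evaluated by Gauss–Legendre quadrature (nine nodes
by default) over (0, 1), with block-corrected node standard errors and
first-half/second-half convergence diagnostics.  A seeded Metropolis
Monte-Carlo sampler on closed-form toy potentials stands in for the
alchemical MD engine at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj import block_average
from .units import kt

__all__ = [
    "STAGE_LABELS",
    "TIStage",
    "SoftCoreParams",
    "gauss_nodes",
    "stage_delta_g",
    "softcore_lj",
    "three_stage_total",
    "metropolis_sample_1d",
    "node_convergence",
]

STAGE_LABELS = ("decharge", "vdw_softcore", "recharge")


@dataclass
class SoftCoreParams:
    """Separation-shifted soft-core parameters.

    The 12-6 interaction is evaluated at r⁶ + shift with
    shift = α·λ_off^power·σ⁶, where λ_off is the coupling-off fraction
    (λ for a disappearing interaction, 1−λ for an appearing one), so the
    potential is finite at r = 0 for interior λ and reduces to plain LJ
    at the fully coupled endpoint.
    """

    alpha: float = 0.5
    power: int = 1
    direction: str = "appearing"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.direction not in ("appearing", "disappearing"):
            raise ValueError("direction must be appearing|disappearing")


@dataclass
class TIStage:
    """One alchemical stage: λ nodes, weights and per-node dV/dλ samples."""

    label: str
    nodes: np.ndarray
    weights: np.ndarray
    samples: list[np.ndarray]   # per node, kcal/mol

    def __post_init__(self) -> None:
        if self.label not in STAGE_LABELS:
            raise ValueError(f"unknown stage label {self.label!r}")
        self.nodes = np.asarray(self.nodes, float)
        self.weights = np.asarray(self.weights, float)
        if not np.all(np.diff(self.nodes) > 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be positive and sum to 1")
        if len(self.samples) != len(self.nodes):
            raise ValueError("one sample list per node required")


def gauss_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes and weights mapped affinely to (0, 1).

    Weights sum to 1; the rule is exact for polynomials of degree ≤ 2n−1.
    """
    if n < 1:
        raise ValueError("need at least one node")
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def stage_delta_g(stage: TIStage, n_blocks: int | None = None
                  ) -> tuple[float, float]:
    """(ΔG, SE) of one stage: weighted node means, SEs in quadrature.

    Node standard errors are block-averaged (√N blocks by default) to
    correct for sample autocorrelation; single-sample nodes get SE 0.
    """
    means = np.empty(len(stage.nodes))
    ses = np.empty(len(stage.nodes))
    for i, s in enumerate(stage.samples):
        s = np.asarray(s, float)
        if s.size == 0:
            raise ValueError(f"no samples at λ = {stage.nodes[i]:.6f}")
        means[i] = s.mean()
        if s.size < 4 or np.allclose(s, s[0]):
            ses[i] = 0.0
        else:
            nb = n_blocks or max(2, int(np.sqrt(s.size)))
            _, ses[i] = block_average(s, nb)
    dg = float(np.sum(stage.weights * means))
    se = float(np.sqrt(np.sum((stage.weights * ses) ** 2)))
    return dg, se


def three_stage_total(stages: list[TIStage]) -> dict:
    """Total ΔG over the decharge/vdW/recharge path, SEs in quadrature."""
    labels = [s.label for s in stages]
    if sorted(labels) != sorted(STAGE_LABELS):
        raise ValueError(
            f"need exactly the three stages {STAGE_LABELS}, got {labels}")
    per_stage = {}
    total, var = 0.0, 0.0
    for s in stages:
        dg, se = stage_delta_g(s)
        per_stage[s.label] = {"delta_g_kcal_mol": dg,
                              "standard_error_kcal_mol": se}
        total += dg
        var += se * se
    return {"stages": per_stage,
            "total_delta_g_kcal_mol": total,
            "total_standard_error_kcal_mol": float(np.sqrt(var))}


def softcore_lj(r: float, lam: float, params: SoftCoreParams,
                rmin: float, epsilon: float) -> tuple[float, float]:
    """Soft-core 12-6 energy and analytic dV/dλ for one pair.

    V(r, λ) = c(λ)·4ε·[σ¹²/(r⁶+Δ)² − σ⁶/(r⁶+Δ)], Δ = α·λ_off^p·σ⁶,
    with c = λ, λ_off = 1−λ for an appearing interaction (mirrored for a
    disappearing one).  ``rmin``/``epsilon`` are the pair minimum-energy
    distance and well depth (σ⁶ = r_min⁶/2).
    """
    if r < 0:
        raise ValueError("distance must be non-negative")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    sigma6 = rmin ** 6 / 2.0
    if params.direction == "appearing":
        c, dc = lam, 1.0
        lam_off, dlam_off = 1.0 - lam, -1.0
    else:
        c, dc = 1.0 - lam, -1.0
        lam_off, dlam_off = lam, 1.0
    p = params.power
    delta = params.alpha * lam_off ** p * sigma6
    ddelta = params.alpha * p * lam_off ** (p - 1) * sigma6 * dlam_off \
        if p >= 1 else 0.0
    r6 = r ** 6
    den = r6 + delta
    if den <= 0.0:
        # only reachable at r = 0 with the shift off (coupled endpoint or
        # alpha = 0): the plain-LJ wall, not an error
        return float("inf"), float("inf")
    a = sigma6 / den
    v_core = 4.0 * epsilon * (a * a - a)
    # ∂V_core/∂Δ = 4ε(−2σ¹²/den³ + σ⁶/den²)
    dv_core_ddelta = 4.0 * epsilon * (-2.0 * a * a + a) / den
    energy = c * v_core
    dvdl = dc * v_core + c * dv_core_ddelta * ddelta
    return float(energy), float(dvdl)


# ---------------------------------------------------------------------------
# Desk-scale Metropolis sampling of toy λ-potentials
# ---------------------------------------------------------------------------

def metropolis_sample_1d(potential, dvdl, lam: float, n_samples: int,
                         rng: np.random.Generator, *,
                         temperature: float = 300.0, step: float = 0.5,
                         x0: float = 0.0, equilibration: float = 0.1,
                         thin: int = 1) -> np.ndarray:
    """Metropolis samples of dV/dλ for a 1-D toy potential at fixed λ.

    ``potential(x, lam)`` and ``dvdl(x, lam)`` are callables; a fraction
    ``equilibration`` of the chain is discarded (the analogue of the
    per-node equilibration period of an alchemical MD run).
    """
    beta = 1.0 / kt(temperature)
    n_total = int(n_samples * thin / (1.0 - equilibration)) + 1
    x = x0
    e = potential(x, lam)
    out = []
    for i in range(n_total):
        trial = x + rng.uniform(-step, step)
        e_trial = potential(trial, lam)
        if e_trial <= e or rng.random() < np.exp(-beta * (e_trial - e)):
            x, e = trial, e_trial
        out.append(x)
    burn = n_total - n_samples * thin
    xs = np.array(out[burn::thin][:n_samples])
    return np.array([dvdl(x, lam) for x in xs])


def write_ti_samples(stages: list[TIStage], path) -> None:
    """Whitespace table: stage, lambda, sample_index, dV/dλ value."""
    from pathlib import Path

    lines = ["stage lambda sample_index dvdl_kcal_mol"]
    for s in stages:
        for lam, samples in zip(s.nodes, s.samples):
            for i, v in enumerate(np.asarray(samples, float)):
                lines.append(f"{s.label} {lam:.12f} {i} {v:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ti_samples(path) -> list[TIStage]:
    """Read the per-node dV/dλ table back into stages.

    Quadrature weights are reconstructed from the node count (the nodes
    must be a Gauss–Legendre set, as written by :func:`write_ti_samples`).
    """
    from pathlib import Path

    data: dict[str, dict[float, list[float]]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("stage") or line.startswith("#"):
            continue
        label, lam, _idx, val = line.split()[:4]
        data.setdefault(label, {}).setdefault(float(lam), []).append(float(val))
    stages = []
    for label, nodes_map in data.items():
        lams = np.array(sorted(nodes_map))
        ref_nodes, weights = gauss_nodes(len(lams))
        if not np.allclose(lams, ref_nodes, atol=1e-9):
            raise ValueError(
                f"stage {label!r}: λ values are not a {len(lams)}-node "
                f"Gauss–Legendre set")
        samples = [np.array(nodes_map[l]) for l in sorted(nodes_map)]
        stages.append(TIStage(label=label, nodes=lams, weights=weights,
                              samples=samples))
    return stages


def node_convergence(stage: TIStage) -> list[dict]:
    """First-half vs second-half node means (per-node convergence check)."""
    out = []
    for lam, s in zip(stage.nodes, stage.samples):
        s = np.asarray(s, float)
        h = len(s) // 2
        out.append({"lambda": float(lam),
                    "first_half_mean": float(s[:h].mean()) if h else np.nan,
                    "second_half_mean": float(s[h:].mean()) if h else np.nan})
    return out
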