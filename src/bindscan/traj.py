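"""Trajectory analytics: hydrogen-bond occupancy, block averaging,
distance distributions and backbone RMSD with optimal superposition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConformerEnsemble

__all__ = [
    "HBondSpec",
    "OccupancyResult",
    "hbond_occupancy",
    "block_average",
    "distance_distribution",
    "kabsch",
    "backbone_rmsd",
    "rmsd_flags",
]

#: Conventional geometric hydrogen-bond criterion (config-exposed).
DEFAULT_HB_DISTANCE = 3.5   # Å, donor–acceptor
DEFAULT_HB_ANGLE = 120.0    # degrees, donor–H–acceptor


@dataclass(frozen=True)
class HBondSpec:
    """Geometric hydrogen-bond criterion between topology atoms (serials)."""

    donor: int
    acceptor: int
    hydrogen: int | None = None
    distance_cutoff: float = DEFAULT_HB_DISTANCE
    angle_cutoff: float = DEFAULT_HB_ANGLE

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 <= self.angle_cutoff <= 180.0:
            raise ValueError("angle cutoff must be within [0, 180] degrees")


@dataclass
class OccupancyResult:
    """Fractional occupancy of an intermittent hydrogen bond."""

    fraction: float
    per_frame: np.ndarray
    per_block: np.ndarray
    n_frames: int


def hbond_occupancy(ensemble: ConformerEnsemble, spec: HBondSpec,
                    n_blocks: int = 5) -> OccupancyResult:
    """Fraction of frames satisfying the bond's geometric criterion.

    A frame counts iff donor–acceptor distance ≤ cutoff and, when a
    hydrogen atom is given, the donor–H–acceptor angle ≥ angle cutoff.
    """
    s2i = ensemble.topology.serial_to_index()
    try:
        di, ai = s2i[spec.donor], s2i[spec.acceptor]
        hi = s2i[spec.hydrogen] if spec.hydrogen is not None else None
    except KeyError as exc:
        raise KeyError(f"unknown atom serial {exc} in hydrogen-bond spec") from exc
    frames = ensemble.frames
    d = np.linalg.norm(frames[:, di] - frames[:, ai], axis=1)
    ok = d <= spec.distance_cutoff
    if hi is not None:
        v1 = frames[:, di] - frames[:, hi]
        v2 = frames[:, ai] - frames[:, hi]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ok &= ang >= spec.angle_cutoff
    indicator = ok.astype(float)
    if len(indicator) >= max(n_blocks, 2):
        blocks, _ = block_average(indicator, n_blocks)
    else:
        blocks = np.array([indicator.mean()])
    return OccupancyResult(fraction=float(indicator.mean()),
                           per_frame=indicator,
                           per_block=blocks,
                           n_frames=len(indicator))


def block_average(series, n_blocks: int) -> tuple[np.ndarray, float]:
    """Contiguous block means and the blocked standard error of the mean.

    The series is split into ``n_blocks`` contiguous blocks (remainder
    frames go to the last block); SE = std(block means)/√n_blocks, the
    conventional estimator for autocorrelated series.
    """
    x = np.asarray(series, float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(x) < n_blocks:
        raise ValueError(
            f"series of length {len(x)} cannot form {n_blocks} blocks")
    size = len(x) // n_blocks
    means = np.array([
        x[i * size: (i + 1) * size if i < n_blocks - 1 else len(x)].mean()
        for i in range(n_blocks)])
    se = float(means.std(ddof=1) / np.sqrt(n_blocks))
    return means, se


def distance_distribution(ensemble: ConformerEnsemble,
                          atom_pair: tuple[int, int],
                          bins: np.ndarray | float = 0.1,
                          log_counts: bool = False):
    """Histogram of a per-frame interatomic distance.

    ``bins`` is either an explicit edge array or a bin width (Å).  With
    ``log_counts`` the log₁₀ counts are returned with empty bins masked
    (NaN markers, never zeros).
    Returns (edges, counts-or-log-counts).
    """
    s2i = ensemble.topology.serial_to_index()
    i, j = s2i[atom_pair[0]], s2i[atom_pair[1]]
    d = np.linalg.norm(ensemble.frames[:, i] - ensemble.frames[:, j], axis=1)
    if np.isscalar(bins):
        width = float(bins)
        lo = np.floor(d.min() / width) * width
        hi = np.ceil(d.max() / width) * width + width / 2
        edges = np.arange(lo, hi + width, width)
    else:
        edges = np.asarray(bins, float)
    counts, edges = np.histogram(d, bins=edges)
    if log_counts:
        out = np.full(counts.shape, np.nan)
        nz = counts > 0
        out[nz] = np.log10(counts[nz])
        return edges, out
    return edges, counts


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation (and translation) superposing mobile onto reference.

    Standard closed-form least-squares solution via SVD of the covariance
    matrix, with the determinant correction for proper rotations.
    Returns (rotation matrix, translation) so that
    ``mobile @ R.T + t`` best fits ``reference``.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    C = P.T @ Q
    V, _, Wt = np.linalg.svd(C)
    sign = np.sign(np.linalg.det(V @ Wt))
    D = np.diag([1.0, 1.0, sign])
    R = (V @ D @ Wt).T
    t = rc - R @ mc
    return R, t


def backbone_rmsd(ensemble: ConformerEnsemble, reference: np.ndarray,
                  atom_serials: list[int] | None = None,
                  atom_names: tuple[str, ...] = ("N", "CA", "C")
                  ) -> np.ndarray:
    """Per-frame RMSD (Å) after optimal rigid-body superposition.

    The selection is either explicit serials or all atoms whose names
    match ``atom_names`` (backbone by default); it must be non-empty and
    present in both the ensemble topology and the reference frame.
    """
    top = ensemble.topology
    if atom_serials is None:
        sel = np.array([i for i, a in enumerate(top.atoms)
                        if a.name in atom_names], dtype=int)
    else:
        sel = top.indices_of(atom_serials)
    if sel.size == 0:
        raise ValueError("empty atom selection for RMSD")
    reference = np.asarray(reference, float)
    if reference.shape[0] != top.n_atoms:
        raise ValueError("reference frame does not match topology atom count")
    ref = reference[sel]
    out = np.empty(ensemble.n_frames)
    for k in range(ensemble.n_frames):
        mob = ensemble.frames[k][sel]
        R, t = kabsch(mob, ref)
        fitted = mob @ R.T + t
        out[k] = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
    return out


def rmsd_flags(rmsd_trace: np.ndarray, bound: float = 2.0) -> bool:
    """True if the trace stays within the equilibration bound (Å)."""
    return bool(np.all(np.asarray(rmsd_trace) <= bound))
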