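"""Implicit-solvent terms: grid Poisson–Boltzmann polar solvation and
solvent-accessible surface-area nonpolar solvation.

The polar term is the reaction-field energy of the solute's point
charges: the electrostatic grid energy with the solvent dielectric
outside the molecular cavity minus the grid energy with the solute
dielectric everywhere.  The dielectric boundary is the union of atom
spheres at their cavity radii; edge dielectrics are harmonic averages
weighted by the in-cavity fraction of each grid edge, charges are
spread trilinearly, and the boundary condition is the analytic
solvent-screened Coulomb potential of all charges.  At zero ionic
strength the linearized PB equation reduces to the Poisson equation.

The nonpolar term is γ·SASA + offset with SASA from deterministic
sphere-point sampling (Shrake–Rupley construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg
from scipy.spatial.distance import cdist

from .core import MolecularSystem
from .units import COULOMB_CONSTANT, KB, AVOGADRO

__all__ = [
    "PBSettings",
    "SolvationEnergy",
    "GridBoundaryError",
    "solve_pb",
    "solve_pb_system",
    "sasa",
    "sasa_system",
    "nonpolar_term",
    "solvation_energy",
    "grid_box_for",
]

#: Conventional surface-tension companions of the PB setup; configurable,
#: not literature ground truth.
DEFAULT_GAMMA = 0.00542     # kcal/(mol·Å²)
DEFAULT_SA_OFFSET = 0.92    # kcal/mol


class GridBoundaryError(ValueError):
    """Solute cavity reaches the grid boundary; increase grid_padding."""


@dataclass
class PBSettings:
    """Finite-difference PB solver settings (defaults follow the standard
    single-grid protocol: ε 1/80, 0.5 Å spacing, 1.4 Å probe)."""

    grid_spacing: float = 0.5           # Å
    solute_dielectric: float = 1.0
    solvent_dielectric: float = 80.0
    probe_radius: float = 1.4           # Å (SASA probe)
    grid_padding: float = 6.0           # Å beyond the cavity
    ionic_strength: float = 0.0         # mol/L, linearized salt screening
    temperature: float = 300.0          # K (enters only via salt screening)
    solver_rtol: float = 1.0e-8         # CG relative residual

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.solute_dielectric < 1 or self.solvent_dielectric < 1:
            raise ValueError("dielectrics must be >= 1")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")


def grid_box_for(coords: np.ndarray, radii: np.ndarray,
                 settings: PBSettings) -> tuple[np.ndarray, float]:
    """(center, half-width) of a cubic grid enclosing cavity + padding."""
    coords = np.atleast_2d(coords)
    center = 0.5 * (coords.min(axis=0) + coords.max(axis=0))
    reach = np.max(np.linalg.norm(coords - center, axis=1) + radii)
    half = float(reach + settings.grid_padding)
    return center, half


def _edge_dielectric(nodes_lo: np.ndarray, axis: int, h: float,
                     coords: np.ndarray, radii: np.ndarray,
                     eps_in: float, eps_out: float) -> np.ndarray:
    """Harmonic-mean dielectric on grid edges along ``axis``.

    ``nodes_lo`` is the (na, nb, nc, 3) array of lower-node positions of
    each edge.  The in-cavity fraction of each edge is the analytic
    edge–sphere intersection length per atom; overlapping-atom coverage
    is combined by a clipped sum, which is exact except where two cavity
    surfaces cross the same sub-Å edge.
    """
    shape = nodes_lo.shape[:3]
    frac = np.zeros(shape, dtype=float)
    lo_corner = nodes_lo[0, 0, 0]
    t_axes = [a for a in range(3) if a != axis]
    for c, r in zip(coords, radii):
        if r <= 0:
            continue
        rel = c - lo_corner
        lo_i = np.floor((rel - r) / h).astype(int)
        hi_i = np.ceil((rel + r) / h).astype(int) + 1
        lo_i = np.maximum(lo_i, 0)
        hi_i = np.minimum(hi_i, shape)
        if np.any(lo_i >= hi_i):
            continue
        sl = tuple(slice(l, u) for l, u in zip(lo_i, hi_i))
        pts = nodes_lo[sl]
        rho2 = ((pts[..., t_axes[0]] - c[t_axes[0]]) ** 2 +
                (pts[..., t_axes[1]] - c[t_axes[1]]) ** 2)
        w2 = r * r - rho2
        hit = w2 > 0
        if not np.any(hit):
            continue
        w = np.sqrt(np.where(hit, w2, 0.0))
        s = pts[..., axis] - c[axis]          # edge start rel. to center
        u_lo = np.clip(-w - s, 0.0, h)
        u_hi = np.clip(w - s, 0.0, h)
        frac[sl] += np.where(hit, (u_hi - u_lo) / h, 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return 1.0 / (frac / eps_in + (1.0 - frac) / eps_out)


def _spread_charges(coords: np.ndarray, charges: np.ndarray,
                    lo_corner: np.ndarray, h: float, n: int) -> np.ndarray:
    """Trilinear assignment of point charges to grid nodes."""
    rho = np.zeros((n, n, n))
    rel = (coords - lo_corner) / h
    base = np.floor(rel).astype(int)
    frac = rel - base
    for (bx, by, bz), (fx, fy, fz), q in zip(base, frac, charges):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    rho[bx + dx, by + dy, bz + dz] += q * wx * wy * wz
    return rho


def _interp_potential(phi: np.ndarray, coords: np.ndarray,
                      lo_corner: np.ndarray, h: float) -> np.ndarray:
    rel = (coords - lo_corner) / h
    base = np.floor(rel).astype(int)
    frac = rel - base
    out = np.zeros(coords.shape[0])
    for k, ((bx, by, bz), (fx, fy, fz)) in enumerate(zip(base, frac)):
        acc = 0.0
        for dx, wx in ((0, 1 - fx), (1, fx)):
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dz, wz in ((0, 1 - fz), (1, fz)):
                    acc += wx * wy * wz * phi[bx + dx, by + dy, bz + dz]
        out[k] = acc
    return out


def _grid_energy(coords: np.ndarray, charges: np.ndarray,
                 radii: np.ndarray, settings: PBSettings,
                 center: np.ndarray, half: float,
                 uniform: bool) -> float:
    """½ Σ qφ on the grid for the solvated or uniform-dielectric state."""
    h = settings.grid_spacing
    eps_in = settings.solute_dielectric
    eps_out = eps_in if uniform else settings.solvent_dielectric
    m = int(np.ceil(half / h))
    n = 2 * m + 1
    lo_corner = center - m * h
    axes = [lo_corner[d] + h * np.arange(n) for d in range(3)]

    # salt screening (linearized), solvent region only
    kappa2 = 0.0
    if not uniform and settings.ionic_strength > 0:
        n_ion = 2.0 * settings.ionic_strength * AVOGADRO * 1e-27  # Å⁻³
        l_b = COULOMB_CONSTANT / (eps_out * KB * settings.temperature)
        kappa2 = 4.0 * np.pi * l_b * n_ion

    # edge dielectrics
    if uniform:
        eps_edges = None
    else:
        node_grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        eps_edges = []
        for axis in range(3):
            sl = [slice(None)] * 3
            sl[axis] = slice(0, n - 1)
            eps_edges.append(_edge_dielectric(
                node_grid[tuple(sl)], axis, h, coords, radii,
                eps_in, eps_out))
        del node_grid

    def eps_edge(axis):
        if eps_edges is None:
            shape = [n, n, n]
            shape[axis] -= 1
            return np.full(shape, eps_in)
        return eps_edges[axis]

    # Dirichlet boundary: screened Coulomb of all charges
    phi = np.zeros((n, n, n))
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    bmask = np.zeros((n, n, n), dtype=bool)
    for axis in range(3):
        sl0 = [slice(None)] * 3
        sl0[axis] = 0
        bmask[tuple(sl0)] = True
        sl0[axis] = n - 1
        bmask[tuple(sl0)] = True
    bpts = np.stack([X[bmask], Y[bmask], Z[bmask]], axis=-1)
    d = cdist(bpts, np.atleast_2d(coords))
    d = np.maximum(d, 1e-6)
    if kappa2 > 0:
        screen = np.exp(-np.sqrt(kappa2) * d)
    else:
        screen = 1.0
    phi[bmask] = (COULOMB_CONSTANT / eps_out) * np.sum(
        screen * charges / d, axis=1)

    # assemble interior system  A φ = b  (SPD)
    ni = n - 2
    ids = -np.ones((n, n, n), dtype=np.int64)
    ids[1:-1, 1:-1, 1:-1] = np.arange(ni ** 3).reshape(ni, ni, ni)
    rho = _spread_charges(coords, charges, lo_corner, h, n)
    b = (4.0 * np.pi * COULOMB_CONSTANT / h) * rho[1:-1, 1:-1, 1:-1].ravel()

    diag = np.zeros(ni ** 3)
    if kappa2 > 0:
        # screening active only where the edge dielectric ≈ solvent
        solv_frac = np.ones((n, n, n))
        diag += (kappa2 * eps_out * h * h) * solv_frac[1:-1, 1:-1, 1:-1].ravel()

    rows, cols, vals = [], [], []
    interior = tuple(slice(1, -1) for _ in range(3))
    for axis in range(3):
        e = eps_edge(axis)
        # edge between node p (index i along axis) and p+1
        sl_lo = [slice(1, -1)] * 3
        sl_hi = [slice(1, -1)] * 3
        sl_edge = [slice(1, -1)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        sl_edge[axis] = slice(0, None)
        e_ax = e[tuple(sl_edge)]            # edges with transverse dims interior
        id_lo = ids[tuple(sl_lo)]
        id_hi = ids[tuple(sl_hi)]
        phi_lo = phi[tuple(sl_lo)]
        phi_hi = phi[tuple(sl_hi)]
        both = (id_lo >= 0) & (id_hi >= 0)
        rows.append(id_lo[both])
        cols.append(id_hi[both])
        vals.append(-e_ax[both])
        # diagonal contributions from every edge touching an interior node
        lo_in = id_lo >= 0
        np.add.at(diag, id_lo[lo_in], e_ax[lo_in])
        hi_in = id_hi >= 0
        np.add.at(diag, id_hi[hi_in], e_ax[hi_in])
        # boundary neighbours move to RHS
        lo_b = lo_in & (id_hi < 0)
        np.add.at(b, id_lo[lo_b], e_ax[lo_b] * phi_hi[lo_b])
        hi_b = hi_in & (id_lo < 0)
        np.add.at(b, id_hi[hi_b], e_ax[hi_b] * phi_lo[hi_b])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sparse.coo_matrix(
        (np.concatenate([vals, vals, diag]),
         (np.concatenate([rows, cols, np.arange(ni ** 3)]),
          np.concatenate([cols, rows, np.arange(ni ** 3)]))),
        shape=(ni ** 3, ni ** 3)).tocsr()

    M = sparse.diags(1.0 / A.diagonal())
    x0 = phi[interior].ravel()
    sol, info = cg(A, b, x0=x0, M=M, rtol=settings.solver_rtol, maxiter=20000)
    if info != 0:
        raise RuntimeError(f"PB conjugate-gradient solver did not converge ({info})")
    phi[interior] = sol.reshape(ni, ni, ni)

    phi_at = _interp_potential(phi, np.atleast_2d(coords), lo_corner, h)
    return float(0.5 * np.sum(charges * phi_at))


def solve_pb(coords: np.ndarray, charges: np.ndarray, radii: np.ndarray,
             settings: PBSettings | None = None,
             box: tuple[np.ndarray, float] | None = None) -> float:
    """Polar (reaction-field) solvation energy, kcal/mol.

    ``radii`` are the cavity radii defining the dielectric boundary.
    ``box`` optionally fixes (center, half-width); sharing one box across
    complex/receptor/ligand improves cancellation in binding differences.
    """
    settings = settings or PBSettings()
    coords = np.atleast_2d(np.asarray(coords, float))
    charges = np.asarray(charges, float)
    radii = np.asarray(radii, float)
    if not np.any(charges):
        return 0.0
    if box is None:
        box = grid_box_for(coords, radii, settings)
    center, half = box
    reach = np.max(np.linalg.norm(coords - center, axis=1) + radii)
    if reach > half - 2.0 * settings.grid_spacing:
        raise GridBoundaryError(
            f"solute cavity (reach {reach:.2f} Å) touches the grid boundary "
            f"(half-width {half:.2f} Å); increase grid_padding")
    e_solv = _grid_energy(coords, charges, radii, settings, center, half,
                          uniform=False)
    e_ref = _grid_energy(coords, charges, radii, settings, center, half,
                         uniform=True)
    return e_solv - e_ref


def solve_pb_system(system: MolecularSystem, frame: np.ndarray | None = None,
                    settings: PBSettings | None = None,
                    box=None) -> float:
    xyz = system.coordinates if frame is None else np.asarray(frame, float)
    return solve_pb(xyz, system.charges, system.lj_radii, settings, box=box)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=-1)


def sasa(coords: np.ndarray, radii: np.ndarray, probe_radius: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface areas, Å².

    Each atom's sphere of radius (radius + probe) is sampled with a
    deterministic Fibonacci lattice; points inside any neighbour's
    expanded sphere are buried.  Exact duplicates (same center and
    radius) are collapsed: only the first of each group carries area.
    """
    coords = np.atleast_2d(np.asarray(coords, float))
    radii = np.asarray(radii, float)
    n = coords.shape[0]
    pts = _fibonacci_sphere(n_points)
    big = radii + probe_radius
    areas = np.zeros(n)
    # collapse exact duplicates so coincident spheres count once
    dup_of = np.full(n, -1, dtype=int)
    for i in range(n):
        for j in range(i):
            if radii[i] == radii[j] and np.array_equal(coords[i], coords[j]):
                dup_of[i] = j
                break
    d = cdist(coords, coords)
    for i in range(n):
        if dup_of[i] >= 0:
            continue
        neigh = np.where((d[i] < big[i] + big) & (np.arange(n) != i) &
                         (dup_of != i))[0]
        neigh = neigh[[dup_of[j] < 0 for j in neigh]]
        surface = coords[i] + big[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in neigh:
            dj = np.linalg.norm(surface - coords[j], axis=1)
            exposed &= dj >= big[j]
        areas[i] = 4.0 * np.pi * big[i] ** 2 * exposed.mean()
    return areas


def sasa_system(system: MolecularSystem, frame: np.ndarray | None = None,
                probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    xyz = system.coordinates if frame is None else np.asarray(frame, float)
    return sasa(xyz, system.lj_radii, probe_radius, n_points)


def nonpolar_term(total_sasa: float, gamma: float = DEFAULT_GAMMA,
                  offset: float = DEFAULT_SA_OFFSET) -> float:
    """Nonpolar solvation γ·SASA + offset, kcal/mol."""
    if total_sasa < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * total_sasa + offset


@dataclass(frozen=True)
class SolvationEnergy:
    """Polar (PB) + nonpolar (SA) solvation free energy, kcal/mol."""

    polar: float
    nonpolar: float
    gamma: float = DEFAULT_GAMMA

    @property
    def total(self) -> float:
        return self.polar + self.nonpolar


def solvation_energy(system: MolecularSystem,
                     frame: np.ndarray | None = None,
                     settings: PBSettings | None = None,
                     gamma: float = DEFAULT_GAMMA,
                     offset: float = DEFAULT_SA_OFFSET,
                     box=None, sasa_points: int = 960) -> SolvationEnergy:
    settings = settings or PBSettings()
    polar = solve_pb_system(system, frame, settings, box=box)
    areas = sasa_system(system, frame, settings.probe_radius, sasa_points)
    return SolvationEnergy(polar=polar,
                           nonpolar=nonpolar_term(float(areas.sum()), gamma,
                                                  offset),
                           gamma=gamma)
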