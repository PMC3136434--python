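"""Solute binding entropy from normal-mode analysis of minimized snapshots.

Each sampled snapshot is minimized (conjugate gradients, then Newton
steps) under a smooth implicit-solvent MM model; translational
(Sackur–Tetrode, 1 atm standard state), rigid-rotor rotational and
harmonic-oscillator vibrational entropies are evaluated for complex,
receptor and ligand, and the binding entropy is the single-trajectory
difference ΔS = S(complex) − S(receptor) − S(ligand), reported together
with −TΔS in kcal/mol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import ConformerEnsemble, MolecularSystem
from .energymodel import EnergyModel
from .units import (ATOMIC_MASS, BOLTZMANN_SI, FREQ_TO_WAVENUMBER, PLANCK,
                    R_CAL, WAVENUMBER_TO_KELVIN)

__all__ = [
    "EntropyResult",
    "MinimizationError",
    "minimize",
    "normal_modes",
    "species_entropy",
    "binding_entropy",
]

logger = logging.getLogger(__name__)

#: Modes below this wavenumber (cm⁻¹) are treated as rigid-body modes.
NEAR_ZERO_CM = 1.0

_ATM_PA = 101325.0


class MinimizationError(RuntimeError):
    """Minimization hit the iteration cap; carries the final gradient RMS."""

    def __init__(self, rms: float, tolerance: float) -> None:
        super().__init__(
            f"minimization stalled at gradient RMS {rms:.3e} "
            f"(tolerance {tolerance:.3e})")
        self.final_rms = rms


def minimize(model: EnergyModel, frame: np.ndarray,
             tolerance: float = 1e-4, cg_tolerance: float = 1e-2,
             max_iter: int = 2000) -> np.ndarray:
    """Minimize a frame to the requested gradient RMS, kcal/(mol·Å).

    Conjugate gradients take the structure to ``cg_tolerance``, then
    Newton (trust-region with the finite-difference Hessian) refines to
    ``tolerance``.
    """
    shape = frame.shape
    x0 = np.asarray(frame, float).ravel()

    def fun(x):
        return model.energy(x.reshape(shape))

    def jac(x):
        return model.gradient(x.reshape(shape)).ravel()

    def rms(x):
        g = jac(x)
        return float(np.sqrt(np.mean(g * g)))

    if rms(x0) <= tolerance:
        return x0.reshape(shape)

    n3 = x0.size
    res = optimize.minimize(fun, x0, jac=jac, method="CG",
                            options={"gtol": cg_tolerance / 4.0,
                                     "maxiter": max_iter})
    x = res.x
    if rms(x) > tolerance:
        def hess(xv):
            return model.hessian(xv.reshape(shape))

        res = optimize.minimize(fun, x, jac=jac, hess=hess,
                                method="trust-ncg",
                                options={"gtol": tolerance * np.sqrt(n3) / 4.0,
                                         "maxiter": max_iter})
        x = res.x
    final = rms(x)
    if final > tolerance:
        raise MinimizationError(final, tolerance)
    return x.reshape(shape)


def _is_linear(coords: np.ndarray, tol: float = 1e-6) -> bool:
    if coords.shape[0] <= 2:
        return True
    c = coords - coords.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


def expected_zero_modes(coords: np.ndarray) -> int:
    n = coords.shape[0]
    if n == 1:
        return 3
    return 5 if _is_linear(coords) else 6


def normal_modes(model: EnergyModel, frame: np.ndarray,
                 masses: np.ndarray | None = None,
                 threshold_cm: float = NEAR_ZERO_CM) -> np.ndarray:
    """Vibrational wavenumbers (cm⁻¹) of a minimized frame.

    The mass-weighted Hessian is diagonalized; modes with |wavenumber|
    below ``threshold_cm`` are removed as rigid-body modes.  A warning is
    issued if their count differs from the 3/5/6 expected for a
    point/linear/nonlinear solute (incomplete minimization or a floppy
    internal mode).  Imaginary modes are returned as negative
    wavenumbers.
    """
    frame = np.asarray(frame, float)
    masses = model.system.masses if masses is None else np.asarray(masses)
    n = frame.shape[0]
    if n == 1:
        return np.zeros(0)
    H = model.hessian(frame)
    invsqrt = 1.0 / np.sqrt(np.repeat(masses, 3))
    Hmw = H * np.outer(invsqrt, invsqrt)
    evals = np.linalg.eigvalsh(Hmw)
    wavenumbers = np.sign(evals) * FREQ_TO_WAVENUMBER * np.sqrt(np.abs(evals))
    near_zero = np.abs(wavenumbers) < threshold_cm
    expected = expected_zero_modes(frame)
    if int(near_zero.sum()) != expected:
        warnings.warn(
            f"found {int(near_zero.sum())} near-zero modes, expected "
            f"{expected}: minimization may be incomplete or the solute has "
            f"free internal modes", stacklevel=2)
    return np.sort(wavenumbers[~near_zero])


@dataclass
class EntropyResult:
    """Entropy components in cal/(mol·K) plus −TΔS in kcal/mol."""

    translational: float
    rotational: float
    vibrational: float
    temperature: float
    n_snapshots: int = 1
    skipped: int = 0

    @property
    def total(self) -> float:
        return self.translational + self.rotational + self.vibrational

    @property
    def minus_T_delta_S(self) -> float:
        return -self.temperature * self.total / 1000.0


def _translational_entropy(total_mass_amu: float, T: float) -> float:
    m = total_mass_amu * ATOMIC_MASS
    lam = (2.0 * np.pi * m * BOLTZMANN_SI * T) / PLANCK ** 2  # m⁻²
    V = BOLTZMANN_SI * T / _ATM_PA
    return R_CAL * (1.5 * np.log(lam) + np.log(V) + 2.5)


def _rotational_entropy(coords: np.ndarray, masses: np.ndarray,
                        T: float) -> float:
    n = coords.shape[0]
    if n == 1:
        return 0.0
    xyz = (coords - np.average(coords, axis=0, weights=masses)) * 1e-10
    m = masses * ATOMIC_MASS
    r2 = np.sum(xyz * xyz, axis=1)
    inertia = (np.eye(3)[None] * (m * r2)[:, None, None] -
               m[:, None, None] * np.einsum("ai,aj->aij", xyz, xyz)).sum(axis=0)
    evals = np.sort(np.linalg.eigvalsh(inertia))
    pref = 8.0 * np.pi ** 2 * BOLTZMANN_SI * T / PLANCK ** 2
    if _is_linear(coords):
        I = evals[-1]
        return R_CAL * (np.log(pref * I) + 1.0)
    Ia, Ib, Ic = evals
    q = np.sqrt(np.pi * Ia * Ib * Ic) * pref ** 1.5
    return R_CAL * (np.log(q) + 1.5)


def _vibrational_entropy(wavenumbers: np.ndarray, T: float) -> float:
    real = wavenumbers[wavenumbers > 0]
    if real.size == 0:
        return 0.0
    x = real * WAVENUMBER_TO_KELVIN / T
    return float(R_CAL * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))


def species_entropy(system: MolecularSystem, frame: np.ndarray,
                    T: float = 300.0, *,
                    minimize_first: bool = True,
                    tolerance: float = 1e-4,
                    model_kwargs: dict | None = None) -> EntropyResult:
    """Ideal-gas/rigid-rotor/harmonic-oscillator entropy of one species."""
    if system.n_atoms == 0:
        raise ValueError("cannot compute entropy of an empty species")
    kwargs = dict(network_cutoff=8.0, include_gb=True)
    kwargs.update(model_kwargs or {})
    model = EnergyModel(system, **kwargs)
    x = np.asarray(frame, float)
    if minimize_first and system.n_atoms > 1:
        x = minimize(model, x, tolerance=tolerance)
    wn = normal_modes(model, x)
    return EntropyResult(
        translational=_translational_entropy(float(system.masses.sum()), T),
        rotational=_rotational_entropy(x, system.masses, T),
        vibrational=_vibrational_entropy(wn, T),
        temperature=T)


def binding_entropy(ensemble: ConformerEnsemble, stride_ps: float | None = None,
                    T: float = 300.0, *, tolerance: float = 1e-4,
                    model_kwargs: dict | None = None) -> EntropyResult:
    """Snapshot-averaged binding entropy ΔS = S_complex − S_receptor − S_ligand.

    Snapshots whose minimization fails to converge are skipped with a
    logged count; more than 50% skipped raises.
    """
    system = ensemble.topology
    if system.role != "complex":
        raise ValueError("binding_entropy expects a complex ensemble")
    if not system.ligand_serials or not system.receptor_serials:
        raise ValueError("complex must have non-empty receptor and ligand")
    receptor = system.receptor_subsystem()
    ligand = system.ligand_subsystem()
    ri, li = system.receptor_indices, system.ligand_indices
    idx = ensemble.frame_selection(stride_ps)
    comps = []
    skipped = 0
    for k in idx:
        frame = ensemble.frames[k]
        try:
            sc = species_entropy(system, frame, T, tolerance=tolerance,
                                 model_kwargs=model_kwargs)
            sr = species_entropy(receptor, frame[ri], T, tolerance=tolerance,
                                 model_kwargs=model_kwargs)
            sl = species_entropy(ligand, frame[li], T, tolerance=tolerance,
                                 model_kwargs=model_kwargs)
        except MinimizationError as exc:
            skipped += 1
            logger.warning("snapshot %d skipped: %s", k, exc)
            continue
        comps.append((sc.translational - sr.translational - sl.translational,
                      sc.rotational - sr.rotational - sl.rotational,
                      sc.vibrational - sr.vibrational - sl.vibrational))
    if skipped > len(idx) / 2:
        raise RuntimeError(
            f"{skipped}/{len(idx)} snapshots failed to minimize")
    if not comps:
        raise RuntimeError("no snapshots survived minimization")
    arr = np.array(comps)
    mean = arr.mean(axis=0)
    return EntropyResult(translational=float(mean[0]),
                         rotational=float(mean[1]),
                         vibrational=float(mean[2]),
                         temperature=T, n_snapshots=len(comps),
                         skipped=skipped)
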