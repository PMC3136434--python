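"""Minimization, normal modes and statistical-thermodynamic entropies
against closed forms."""

import numpy as np
import pytest

from bindscan.core import MolecularSystem, ConformerEnsemble
from bindscan.energymodel import EnergyModel
from bindscan.entropy import (EntropyResult, binding_entropy, minimize,
                              normal_modes, species_entropy)
from bindscan.units import (ATOMIC_MASS, BOLTZMANN_SI, FREQ_TO_WAVENUMBER,
                            PLANCK, R_CAL)

from conftest import make_atom


def lj_pair(sep, eps=0.2, radius=1.9):
    atoms = [make_atom(1, [0.0, 0, 0], lj_epsilon=eps, lj_radius=radius),
             make_atom(2, [sep, 0, 0], lj_epsilon=eps, lj_radius=radius)]
    return MolecularSystem(atoms=atoms, role="ligand")


class TestMinimize:
    def test_analytic_minimum_left_unchanged(self):
        system = lj_pair(3.8)  # combined r_min
        model = EnergyModel(system)
        out = minimize(model, system.coordinates, tolerance=1e-6)
        np.testing.assert_allclose(out, system.coordinates, atol=1e-6)

    def test_perturbed_pair_returns_to_rmin(self):
        system = lj_pair(4.1)  # +0.3 Å past the minimum
        model = EnergyModel(system)
        out = minimize(model, system.coordinates, tolerance=1e-8)
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(3.8, abs=1e-4)

    def test_zero_interaction_system_accepted(self):
        system = lj_pair(3.0, eps=0.0)
        model = EnergyModel(system)
        out = minimize(model, system.coordinates, tolerance=1e-6)
        np.testing.assert_array_equal(out, system.coordinates)

    def test_energy_not_increased(self):
        system = lj_pair(4.5)
        model = EnergyModel(system)
        out = minimize(model, system.coordinates, tolerance=1e-6)
        assert model.energy(out) <= model.energy(system.coordinates) + 1e-12


class TestNormalModes:
    def test_harmonic_diatomic_frequency_closed_form(self):
        atoms = [make_atom(1, [0.0, 0, 0], mass=12.0, lj_epsilon=0.0),
                 make_atom(2, [1.5, 0, 0], mass=16.0, lj_epsilon=0.0)]
        system = MolecularSystem(atoms=atoms, bonds=[(1, 2)], role="ligand")
        model = EnergyModel(system, bond_k=300.0, include_nonbonded=False)
        wn = normal_modes(model, system.coordinates)
        mu = 12.0 * 16.0 / 28.0
        expected = FREQ_TO_WAVENUMBER * np.sqrt(2.0 * 300.0 / mu)
        assert len(wn) == 1
        assert wn[0] == pytest.approx(expected, rel=1e-3)

    def test_single_atom_has_no_vibrations(self):
        system = MolecularSystem(atoms=[make_atom(1, [0, 0, 0])], role="ligand")
        wn = normal_modes(EnergyModel(system), system.coordinates)
        assert wn.size == 0

    def test_rigid_translation_leaves_spectrum_unchanged(self):
        atoms = [make_atom(1, [0.0, 0, 0], mass=12.0, lj_epsilon=0.0),
                 make_atom(2, [1.5, 0, 0], mass=16.0, lj_epsilon=0.0)]
        system = MolecularSystem(atoms=atoms, bonds=[(1, 2)], role="ligand")
        model = EnergyModel(system, include_nonbonded=False)
        a = normal_modes(model, system.coordinates)
        b = normal_modes(model, system.coordinates + [10.0, -4.0, 2.0])
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_unminimized_floppy_system_warns(self):
        atoms = [make_atom(1, [0.0, 0, 0], lj_epsilon=0.0),
                 make_atom(2, [5.0, 0, 0], lj_epsilon=0.0)]
        system = MolecularSystem(atoms=atoms, role="ligand")
        with pytest.warns(UserWarning, match="near-zero"):
            normal_modes(EnergyModel(system), system.coordinates)


class TestSpeciesEntropy:
    def test_single_atom_translation_only(self):
        system = MolecularSystem(atoms=[make_atom(1, [0, 0, 0], mass=12.0)],
                                 role="ligand")
        res = species_entropy(system, system.coordinates, T=300.0)
        m = 12.0 * ATOMIC_MASS
        lam = 2.0 * np.pi * m * BOLTZMANN_SI * 300.0 / PLANCK ** 2
        V = BOLTZMANN_SI * 300.0 / 101325.0
        expected = R_CAL * (1.5 * np.log(lam) + np.log(V) + 2.5)
        assert res.translational == pytest.approx(expected, rel=1e-9)
        assert res.rotational == 0.0 and res.vibrational == 0.0

    def test_rigid_linear_pair_rotational_closed_form(self):
        atoms = [make_atom(1, [0.0, 0, 0], mass=12.0, lj_epsilon=0.0),
                 make_atom(2, [2.0, 0, 0], mass=12.0, lj_epsilon=0.0)]
        system = MolecularSystem(atoms=atoms, role="complex",
                                 receptor_serials=frozenset({1}),
                                 ligand_serials=frozenset({2}))
        with pytest.warns(UserWarning):
            res = species_entropy(system, system.coordinates, T=300.0,
                                  minimize_first=False,
                                  model_kwargs={"include_gb": False,
                                                "network_cutoff": None})
        mu = 6.0 * ATOMIC_MASS
        inertia = mu * (2.0e-10) ** 2
        pref = 8.0 * np.pi ** 2 * BOLTZMANN_SI * 300.0 / PLANCK ** 2
        expected_rot = R_CAL * (np.log(pref * inertia) + 1.0)
        assert res.vibrational == 0.0
        assert res.rotational == pytest.approx(expected_rot, rel=1e-9)

    def test_vibrational_entropy_increases_with_temperature(self):
        atoms = [make_atom(1, [0.0, 0, 0], mass=12.0, lj_epsilon=0.0),
                 make_atom(2, [1.5, 0, 0], mass=16.0, lj_epsilon=0.0)]
        system = MolecularSystem(atoms=atoms, bonds=[(1, 2)], role="ligand")
        s300 = species_entropy(system, system.coordinates, T=300.0)
        s600 = species_entropy(system, system.coordinates, T=600.0)
        assert s600.vibrational > s300.vibrational

    def test_extensive_over_noninteracting_duplicates(self):
        one = MolecularSystem(
            atoms=[make_atom(1, [0.0, 0, 0], lj_epsilon=0.0),
                   make_atom(2, [1.5, 0, 0], lj_epsilon=0.0)],
            bonds=[(1, 2)], role="ligand")
        two = MolecularSystem(
            atoms=[make_atom(1, [0.0, 0, 0], lj_epsilon=0.0),
                   make_atom(2, [1.5, 0, 0], lj_epsilon=0.0),
                   make_atom(3, [0.0, 0, 500.0], lj_epsilon=0.0),
                   make_atom(4, [1.5, 0, 500.0], lj_epsilon=0.0)],
            bonds=[(1, 2), (3, 4)], role="ligand")
        with pytest.warns(UserWarning):
            # the duplicated system has extra rigid-body-like zero modes
            s1 = species_entropy(one, one.coordinates, minimize_first=False,
                                 model_kwargs={"include_gb": False,
                                               "network_cutoff": None})
            s2 = species_entropy(two, two.coordinates, minimize_first=False,
                                 model_kwargs={"include_gb": False,
                                               "network_cutoff": None})
        assert s2.vibrational == pytest.approx(2.0 * s1.vibrational, rel=1e-9)

    def test_empty_species_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            species_entropy(MolecularSystem(atoms=[], role="ligand"),
                            np.zeros((0, 3)))


class TestBindingEntropy:
    def test_empty_ligand_partition_rejected(self, tiny_complex):
        bad = MolecularSystem(atoms=[a.copy() for a in tiny_complex.atoms],
                              bonds=list(tiny_complex.bonds), role="receptor")
        frames = bad.coordinates[None]
        ens = ConformerEnsemble(topology=bad, frames=frames,
                                times=np.array([0.0]))
        with pytest.raises(ValueError):
            binding_entropy(ens)

    def test_deterministic_to_microkcal(self, tiny_complex):
        frames = tiny_complex.coordinates[None]
        ens = ConformerEnsemble(topology=tiny_complex, frames=frames,
                                times=np.array([0.0]))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = binding_entropy(ens, T=300.0)
            b = binding_entropy(ens, T=300.0)
        assert a.minus_T_delta_S == pytest.approx(b.minus_T_delta_S, abs=1e-6)
        assert a.total == a.translational + a.rotational + a.vibrational
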