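"""Hybrid free-energy assembly: power-law polar scaling, reduction
identities, representative-snapshot selection and force-error profiles."""

import itertools

import numpy as np
import pytest

from bindscan import mm, synth
from bindscan.energymodel import EnergyModel
from bindscan.pipeline import EnergyDecomposition, binding_free_energy
from bindscan.qmpbsa import (HighLevelRecord, fit_polar_scaling,
                             force_error_profile, hybrid_binding_free_energy,
                             read_highlevel_records,
                             select_representative_snapshots,
                             subset_discrepancy, write_highlevel_records)


@pytest.fixture(scope="module")
def ensemble():
    spec = synth.FixtureSpec(seed=2, n_frames=10)
    system, _, _ = synth.build_complex(spec)
    return synth.sample_ensemble(system, spec)


def gas_decomps(ens):
    out = []
    for k in range(ens.n_frames):
        g = mm.gas_phase_binding(ens.topology, ens.frames[k])
        out.append(EnergyDecomposition(el=g.el, vdw=g.vdw, polar_pb=12.0,
                                       nonpolar_sa=-2.0,
                                       frame_time=float(ens.times[k])))
    return out


class TestPolarScalingFit:
    def test_exact_power_law_recovered(self):
        eps = np.array([1.0, 2.0, 4.0, 8.0])
        samples = [(e, -5.0 * e ** -1.0) for e in eps]
        fit = fit_polar_scaling(samples)
        assert fit.exponent == pytest.approx(-1.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(5.0, rel=1e-8)
        assert fit.rms_residual < 1e-10
        assert fit.evaluate(2.0) == pytest.approx(-2.5, rel=1e-8)

    def test_constant_samples_give_identity_weight(self):
        fit = fit_polar_scaling([(1.0, -3.0), (2.0, -3.0), (4.0, -3.0)],
                                target_dielectric=4.0)
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)
        assert fit.scale_factor == pytest.approx(1.0, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_polar_scaling([(1.0, -3.0), (2.0, -2.0)])

    def test_sign_mixed_samples_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            fit_polar_scaling([(1.0, -3.0), (2.0, 2.0), (4.0, -1.0)])


class TestHybridAssembly:
    def test_identity_records_reduce_to_classical(self, ensemble):
        decomps = gas_decomps(ensemble)
        records = synth.emit_highlevel_records(ensemble, "mm_identity")
        classical = binding_free_energy(decomps)
        hybrid = hybrid_binding_free_energy(decomps, records, 1.0)
        assert hybrid.delta_g == pytest.approx(classical.delta_g, abs=1e-9)

    def test_constant_offset_shifts_exactly(self, ensemble):
        decomps = gas_decomps(ensemble)
        records = synth.emit_highlevel_records(ensemble, "mm_plus_offset",
                                               offset=3.75)
        classical = binding_free_energy(decomps)
        hybrid = hybrid_binding_free_energy(decomps, records, 1.0)
        assert hybrid.delta_g - classical.delta_g == pytest.approx(3.75,
                                                                   abs=1e-9)

    def test_noisy_records_mean_shift_bounded(self, ensemble):
        spec = synth.FixtureSpec(seed=3, n_frames=200)
        system, _, _ = synth.build_complex(spec)
        big = synth.sample_ensemble(system, spec)
        decomps = gas_decomps(big)
        sigma = 0.5
        records = synth.emit_highlevel_records(big, "mm_plus_noise",
                                               noise_sigma=sigma, seed=11)
        classical = binding_free_energy(decomps)
        hybrid = hybrid_binding_free_energy(decomps, records, 1.0)
        assert abs(hybrid.delta_g - classical.delta_g) < \
            3.0 * sigma / np.sqrt(big.n_frames)

    def test_polar_scale_multiplies_pb_term(self, ensemble):
        decomps = gas_decomps(ensemble)
        records = synth.emit_highlevel_records(ensemble, "mm_identity")
        hybrid = hybrid_binding_free_energy(decomps, records, 0.5)
        assert hybrid.polar_pb == pytest.approx(6.0, abs=1e-12)
        assert hybrid.nonpolar_sa == pytest.approx(-2.0, abs=1e-12)

    def test_missing_record_names_times(self, ensemble):
        decomps = gas_decomps(ensemble)
        records = synth.emit_highlevel_records(ensemble, "mm_identity")[:-1]
        with pytest.raises(ValueError, match="54"):
            hybrid_binding_free_energy(decomps, records, 1.0)

    def test_record_roundtrip_through_text(self, ensemble, tmp_path):
        records = synth.emit_highlevel_records(ensemble, "mm_identity",
                                               with_forces=True)
        write_highlevel_records(records, tmp_path / "rec.txt",
                                tmp_path / "forces.txt")
        back = read_highlevel_records(tmp_path / "rec.txt",
                                      tmp_path / "forces.txt",
                                      n_atoms=ensemble.topology.n_atoms)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert b.gas_binding_energy == pytest.approx(a.gas_binding_energy,
                                                         abs=1e-9)
            np.testing.assert_allclose(b.forces_complex, a.forces_complex,
                                       atol=1e-9)


class TestSnapshotSelection:
    def test_whole_pool_gives_zero_objective(self):
        vals = np.random.default_rng(0).normal(size=8)
        subset, obj = select_representative_snapshots(vals, 8)
        assert list(subset) == list(range(8))
        assert obj == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        vals = np.random.default_rng(seed).normal(size=10)
        subset, obj = select_representative_snapshots(vals, 2)
        best = min(itertools.combinations(range(10), 2),
                   key=lambda c: subset_discrepancy(vals, np.array(c)))
        assert tuple(subset) == tuple(best)

    def test_frame_matching_population_mean_chosen(self):
        vals = np.array([1.0, 3.0, 2.0, 0.0, 4.0])  # mean 2 at index 2
        subset, _ = select_representative_snapshots(vals, 1)
        assert 2 in subset

    def test_optimum_no_worse_than_extending_previous_optimum(self):
        # the (k+1)-optimum is at least as good as the best single-frame
        # extension of the k-optimum (best-subset statistics matching is
        # not monotone in k itself: a small subset can nail the population
        # mean and spread exactly)
        vals = np.random.default_rng(3).normal(size=12)
        for k in range(1, 6):
            sub_k, _ = select_representative_snapshots(vals, k)
            extensions = [
                subset_discrepancy(vals, np.sort(np.append(sub_k, c)))
                for c in range(12) if c not in sub_k]
            _, obj_next = select_representative_snapshots(vals, k + 1)
            assert obj_next <= min(extensions) + 1e-12

    def test_mandatory_frames_always_included(self):
        vals = np.random.default_rng(4).normal(size=10)
        mand = np.array([0, 5])
        subset, _ = select_representative_snapshots(vals, 2, mandatory=mand)
        assert {0, 5} <= set(subset) and len(subset) == 4

    def test_occupancy_statistics_enter_objective(self):
        vals = np.zeros(6)
        occ = np.array([[1], [1], [1], [0], [0], [0]], dtype=float)
        subset, obj = select_representative_snapshots(vals, 2,
                                                      occupancies=occ)
        # the best 2-subset reproduces the 0.5 occupancy: one on, one off
        assert occ[subset].mean() == pytest.approx(0.5)

    def test_k_beyond_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            select_representative_snapshots(np.zeros(4), 5)

    def test_greedy_matches_exhaustive_on_larger_pool(self):
        vals = np.random.default_rng(7).normal(size=18)
        exh, obj_exh = select_representative_snapshots(vals, 3,
                                                       exhaustive_limit=10000)
        greedy, obj_greedy = select_representative_snapshots(
            vals, 3, exhaustive_limit=1)
        assert obj_greedy == pytest.approx(obj_exh, abs=1e-9)


class TestForceErrors:
    def test_identity_forces_give_zero_profile(self, ensemble):
        records = synth.emit_highlevel_records(ensemble, "mm_identity",
                                               with_forces=True)
        profile = force_error_profile(ensemble, records)
        assert profile.mean_abs_error.max() == 0.0
        assert profile.n_snapshots == ensemble.n_frames

    def test_unit_perturbation_on_one_atom(self, ensemble):
        records = synth.emit_highlevel_records(ensemble, "mm_identity",
                                               with_forces=True)
        for r in records:
            r.forces_complex[7] += np.array([1.0, 0.0, 0.0])
        profile = force_error_profile(ensemble, records)
        assert profile.mean_abs_error[7] == pytest.approx(1.0, abs=1e-9)
        others = np.delete(profile.mean_abs_error, 7)
        assert others.max() == 0.0

    def test_gaussian_perturbations_match_expected_magnitude(self, ensemble):
        sigma = 0.3
        records = synth.emit_highlevel_records(ensemble, "mm_identity",
                                               with_forces=True,
                                               force_noise_sigma=sigma,
                                               seed=5)
        profile = force_error_profile(ensemble, records)
        # E|N(0, σ²I₃)| = 2σ√(2/π)·Γ(2)/Γ(3/2)… = σ·√2·Γ(2)/Γ(3/2)
        expected = sigma * np.sqrt(2) * 1.0 / (np.sqrt(np.pi) / 2)
        mean = profile.mean_abs_error.mean()
        n_eff = profile.mean_abs_error.size * profile.n_snapshots
        assert mean == pytest.approx(expected, abs=4 * sigma / np.sqrt(n_eff))

    def test_shape_mismatch_rejected(self, ensemble):
        rec = HighLevelRecord(frame_time=0.0, gas_binding_energy=0.0,
                              forces_complex=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="shape"):
            force_error_profile(ensemble, [rec])
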