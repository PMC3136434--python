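"""Hydrogen-bond occupancy, block averaging, distance histograms and
superposition RMSD."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bindscan import synth
from bindscan.core import ConformerEnsemble
from bindscan.traj import (HBondSpec, backbone_rmsd, block_average,
                           distance_distribution, hbond_occupancy, kabsch,
                           rmsd_flags)


def bond_fixture(seed, n_frames, occupancy=0.65):
    spec = synth.FixtureSpec(
        seed=seed, n_frames=n_frames,
        intermittent_bonds=(synth.IntermittentBondSpec(
            donor_residue=10, occupancy=occupancy),))
    system, _, _ = synth.build_complex(spec)
    ens = synth.sample_ensemble(system, spec)
    donor = next(a.serial for a in system.atoms
                 if a.residue_index == 10 and a.name == "CB")
    acceptor = next(a.serial for a in system.atoms if a.name == "OA")
    return ens, HBondSpec(donor=donor, acceptor=acceptor)


class TestHBondOccupancy:
    def test_permanent_bond_is_fully_occupied(self):
        ens, spec = bond_fixture(seed=1, n_frames=50, occupancy=1.0)
        assert hbond_occupancy(ens, spec).fraction == 1.0

    def test_telegraph_fixture_recovers_target(self):
        ens, spec = bond_fixture(seed=2, n_frames=1000)
        occ = hbond_occupancy(ens, spec)
        assert occ.fraction == pytest.approx(0.65, abs=0.05)
        assert occ.n_frames == 1000
        assert np.all((occ.per_block >= 0) & (occ.per_block <= 1))

    def test_equals_brute_force_indicator_count(self):
        ens, spec = bond_fixture(seed=3, n_frames=20)
        occ = hbond_occupancy(ens, spec)
        s2i = ens.topology.serial_to_index()
        di, ai = s2i[spec.donor], s2i[spec.acceptor]
        count = sum(
            1 for k in range(20)
            if np.linalg.norm(ens.frames[k, di] - ens.frames[k, ai])
            <= spec.distance_cutoff)
        assert occ.fraction == pytest.approx(count / 20.0, abs=1e-12)

    def test_angle_criterion_applies_with_hydrogen(self):
        ens, spec = bond_fixture(seed=4, n_frames=10, occupancy=1.0)
        s2i = ens.topology.serial_to_index()
        di, ai = s2i[spec.donor], s2i[spec.acceptor]
        h_serial = ens.topology.atoms[0].serial
        hi = s2i[h_serial]
        with_h = HBondSpec(donor=spec.donor, acceptor=spec.acceptor,
                           hydrogen=h_serial)
        # H on the donor–acceptor line: angle 180°, bond counted
        ens.frames[:, hi] = 0.5 * (ens.frames[:, di] + ens.frames[:, ai])
        assert hbond_occupancy(ens, with_h).fraction == 1.0
        # H far off the line: acute D–H–A angle, bond rejected
        ens.frames[:, hi] = ens.frames[:, di] + np.array([20.0, 0.0, 0.0])
        assert hbond_occupancy(ens, with_h).fraction == 0.0

    def test_unknown_atom_rejected(self):
        ens, spec = bond_fixture(seed=5, n_frames=5)
        with pytest.raises(KeyError, match="serial"):
            hbond_occupancy(ens, HBondSpec(donor=99999, acceptor=spec.acceptor))

    def test_occupancy_invariant_to_frame_order(self):
        ens, spec = bond_fixture(seed=6, n_frames=100)
        f = hbond_occupancy(ens, spec).fraction
        rng = np.random.default_rng(0)
        perm = rng.permutation(100)
        shuffled = ConformerEnsemble(topology=ens.topology,
                                     frames=ens.frames[perm],
                                     times=ens.times)
        assert hbond_occupancy(shuffled, spec).fraction == pytest.approx(
            f, abs=1e-12)


class TestBlockAverage:
    def test_constant_series(self):
        means, se = block_average(np.full(20, 3.0), 4)
        np.testing.assert_allclose(means, 3.0)
        assert se == 0.0

    def test_one_to_eight_in_four_blocks(self):
        means, _ = block_average(np.arange(1.0, 9.0), 4)
        np.testing.assert_allclose(means, [1.5, 3.5, 5.5, 7.5])

    def test_ar1_series_inflates_blocked_error(self):
        rng = np.random.default_rng(0)
        n, phi = 4000, 0.9
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        naive = x.std(ddof=1) / np.sqrt(n)
        _, blocked = block_average(x, 20)
        assert blocked > 1.5 * naive

    def test_remainder_goes_to_last_block(self):
        means, _ = block_average(np.arange(10.0), 3)
        assert len(means) == 3
        assert means[-1] == pytest.approx(np.arange(6.0, 10.0).mean())

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            block_average(np.arange(3.0), 4)


class TestDistanceDistribution:
    def test_rigid_fixture_occupies_single_bin(self, default_fixture):
        spec, system, _, _ = default_fixture
        rigid = synth.FixtureSpec(seed=1, fluctuation_sigma=0.0, n_frames=10)
        ens = synth.sample_ensemble(system, rigid)
        s1, s2 = system.atoms[0].serial, system.atoms[4].serial
        edges, counts = distance_distribution(ens, (s1, s2), bins=0.1)
        assert (counts > 0).sum() == 1
        assert counts.sum() == 10

    def test_counts_conserved(self):
        ens, spec = bond_fixture(seed=7, n_frames=123)
        edges, counts = distance_distribution(ens, (spec.donor, spec.acceptor))
        assert counts.sum() == 123

    def test_two_state_fixture_masses_match_frequencies(self):
        ens, spec = bond_fixture(seed=8, n_frames=1000)
        edges, counts = distance_distribution(ens, (spec.donor, spec.acceptor),
                                              bins=0.5)
        centers = 0.5 * (edges[:-1] + edges[1:])
        near = counts[centers < 3.5].sum() / 1000.0
        assert near == pytest.approx(0.65, abs=0.05)

    def test_log_counts_mask_empty_bins(self):
        ens, spec = bond_fixture(seed=9, n_frames=50)
        edges, logc = distance_distribution(ens, (spec.donor, spec.acceptor),
                                            bins=0.1, log_counts=True)
        assert np.isnan(logc).any()          # empty bins are markers
        assert np.nanmax(logc) <= np.log10(50.0)


class TestBackboneRMSD:
    def test_identical_frame_gives_zero(self, rigid_ensemble):
        out = backbone_rmsd(rigid_ensemble, rigid_ensemble.frames[0])
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed_by_superposition(self, rigid_ensemble):
        ref = rigid_ensemble.frames[0]
        R = Rotation.from_euler("zyx", [40.0, -25.0, 70.0],
                                degrees=True).as_matrix()
        moved = ref @ R.T + np.array([12.0, -7.0, 3.0])
        ens = ConformerEnsemble(topology=rigid_ensemble.topology,
                                frames=moved[None], times=np.array([0.0]))
        assert backbone_rmsd(ens, ref)[0] < 1e-9

    def test_isotropic_displacement_magnitude_recovered(self, rigid_ensemble):
        ref = rigid_ensemble.frames[0]
        rng = np.random.default_rng(1)
        d = 0.25
        direc = rng.normal(size=ref.shape)
        direc /= np.linalg.norm(direc, axis=1)[:, None]
        ens = ConformerEnsemble(topology=rigid_ensemble.topology,
                                frames=(ref + d * direc)[None],
                                times=np.array([0.0]))
        # superposition can only reduce the displacement slightly
        out = backbone_rmsd(ens, ref)[0]
        assert out == pytest.approx(d, rel=0.15)

    def test_symmetry_in_frame_and_reference(self, rigid_ensemble):
        ref = rigid_ensemble.frames[0]
        other = ref + np.random.default_rng(2).normal(scale=0.3,
                                                      size=ref.shape)
        ens_a = ConformerEnsemble(topology=rigid_ensemble.topology,
                                  frames=other[None], times=np.array([0.0]))
        ens_b = ConformerEnsemble(topology=rigid_ensemble.topology,
                                  frames=ref[None], times=np.array([0.0]))
        a = backbone_rmsd(ens_a, ref)[0]
        b = backbone_rmsd(ens_b, other)[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_kabsch_agrees_with_independent_superposition(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(30, 3)) * 5
        R_true = Rotation.random(rng=rng).as_matrix()
        mob = ref @ R_true.T + [4.0, 5.0, -6.0]
        R, t = kabsch(mob, ref)
        est, rssd = Rotation.align_vectors(ref - ref.mean(0),
                                           mob - mob.mean(0))
        np.testing.assert_allclose(R, est.as_matrix(), atol=1e-9)
        np.testing.assert_allclose(mob @ R.T + t, ref, atol=1e-9)

    def test_empty_selection_rejected(self, rigid_ensemble):
        with pytest.raises(ValueError, match="selection"):
            backbone_rmsd(rigid_ensemble, rigid_ensemble.frames[0],
                          atom_names=("ZZ",))

    def test_monitoring_flag(self):
        assert rmsd_flags(np.array([0.5, 1.9]), bound=2.0)
        assert not rmsd_flags(np.array([0.5, 2.6]), bound=2.0)
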