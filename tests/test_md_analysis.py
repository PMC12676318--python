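import math

import numpy as np
import pytest

from hitfunnel.io_model import Trajectory
from hitfunnel.md_analysis import (
    EnergySeries,
    HBondCriteria,
    energy_ratio,
    energy_summary,
    hbond_counts,
    read_energy_series,
    traj_rmsd,
    traj_rmsf,
)
from hitfunnel.synthetic_data import gen_trajectory, random_rotation, stream


def make_traj(frames, residue_indices=None, names=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    return Trajectory(
        frames=frames,
        atom_names=names or ["CA"] * n,
        elements=["C"] * n,
        residue_indices=residue_indices or list(range(1, n + 1)),
        residue_names=["ALA"] * n,
        times=np.arange(frames.shape[0], dtype=float),
    )


class TestTrajRmsd:
    def test_identical_frames_are_zero(self, rng):
        base = rng.normal(size=(8, 3))
        traj = make_traj([base] * 4)
        np.testing.assert_allclose(traj_rmsd(traj), 0.0, atol=1e-12)

    def test_rigid_motion_frames_are_zero(self, rng):
        base = rng.normal(size=(12, 3)) * 4
        frames = [base]
        r = stream(23, "test-rmsd-rigid")
        for _ in range(3):
            frames.append(base @ random_rotation(r).T + r.uniform(-5, 5, 3))
        assert np.all(traj_rmsd(make_traj(frames)) <= 1e-9)

    def test_gaussian_noise_rmsd_scale(self):
        sigma = 0.3
        traj, _ = gen_trajectory(20, 600, sigma, seed=31)
        # frame 0 also carries noise: deviation between two noisy frames ~ sigma*sqrt(2)*sqrt(3)
        vals = traj_rmsd(traj)[1:]
        expected = sigma * math.sqrt(2.0) * math.sqrt(3.0)
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_empty_selection_is_an_error(self):
        traj, _ = gen_trajectory(3, 5, 0.1, seed=1)
        with pytest.raises(ValueError, match="selection"):
            traj_rmsd(traj, selection=["CB"])

    def test_agrees_with_mdanalysis_oracle(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        A = rng.normal(size=(30, 3)) * 5
        B = A + rng.normal(size=(30, 3)) * 0.5
        traj = make_traj([A, B])
        ours = traj_rmsd(traj)[1]
        theirs = mda_rmsd(B, A, superposition=True, center=True)
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestTrajRmsf:
    def test_static_trajectory_is_zero(self):
        traj, truth = gen_trajectory(10, 6, 0.0, seed=2)
        _, vals = traj_rmsf(traj)
        np.testing.assert_allclose(vals, 0.0, atol=1e-12)
        np.testing.assert_allclose(truth, 0.0)

    def test_recovers_sigma_sqrt3_at_many_frames(self):
        sigma = 0.5
        traj, truth = gen_trajectory(10_000, 12, sigma, seed=33)
        _, vals = traj_rmsf(traj)
        expected = sigma * math.sqrt(3.0)
        assert truth[0] == pytest.approx(expected)
        np.testing.assert_allclose(vals, expected, rtol=0.03)

    def test_noisiest_residue_ranks_first(self):
        profile = np.full(10, 0.2)
        profile[6] = 2.0  # one residue with 10x the noise
        traj, truth = gen_trajectory(500, 10, profile, seed=34)
        res_ids, vals = traj_rmsf(traj)
        assert res_ids[np.argmax(vals)] == 7
        assert np.argmax(truth) == 6

    def test_single_frame_is_an_error(self):
        with pytest.raises(ValueError, match="frames"):
            gen_trajectory(1, 5, 0.1, seed=3)
        traj, _ = gen_trajectory(2, 5, 0.1, seed=3)
        with pytest.raises(ValueError, match="frames"):
            traj_rmsf(Trajectory(traj.frames[:1], traj.atom_names, traj.elements,
                                 traj.residue_indices, traj.residue_names, traj.times[:1]))

    def test_alignment_removes_global_drift(self, rng):
        base = rng.normal(size=(20, 3)) * 5
        frames = [base @ random_rotation(rng).T + rng.uniform(-8, 8, 3) for _ in range(50)]
        traj = make_traj(frames)
        _, aligned = traj_rmsf(traj, align=True)
        _, raw = traj_rmsf(traj, align=False)
        np.testing.assert_allclose(aligned, 0.0, atol=1e-9)
        assert raw.mean() > 1.0


class TestHbondCounts:
    def test_boundary_at_cutoff(self):
        near = [[0, 0, 0], [3.49, 0, 0]]
        far = [[0, 0, 0], [3.51, 0, 0]]
        for coords, expected in ((near, 1), (far, 0)):
            traj = make_traj([coords], names=["N", "O"])
            counts = hbond_counts(traj, donors=[0], acceptors=[1])
            assert counts.tolist() == [expected]

    def test_no_contacts_gives_all_zeros(self, rng):
        donors_xyz = rng.uniform(0, 5, size=(3, 3))
        acceptors_xyz = donors_xyz + 50.0
        frames = [np.vstack([donors_xyz, acceptors_xyz]) for _ in range(4)]
        traj = make_traj(frames)
        counts = hbond_counts(traj, donors=[0, 1, 2], acceptors=[3, 4, 5])
        assert counts.tolist() == [0, 0, 0, 0]

    def test_planted_pairs_counted_exactly(self):
        k = 4
        donors_xyz = np.array([[10.0 * i, 0.0, 0.0] for i in range(k)])
        acceptors_xyz = donors_xyz + np.array([2.8, 0.0, 0.0])  # all inside 3.5
        frames = [np.vstack([donors_xyz, acceptors_xyz])] * 5
        traj = make_traj(frames)
        counts = hbond_counts(traj, donors=range(k), acceptors=range(k, 2 * k))
        assert counts.tolist() == [k] * 5

    def test_monotone_in_distance_cutoff(self, rng):
        coords = rng.uniform(0, 8, size=(10, 3))
        traj = make_traj([coords])
        prev = -1
        for cutoff in (2.0, 3.5, 5.0, 8.0):
            c = hbond_counts(traj, donors=range(5), acceptors=range(5, 10),
                             crit=HBondCriteria(max_donor_acceptor_distance=cutoff))[0]
            assert c >= prev
            prev = c

    def test_angle_cutoff_rejects_bent_geometry(self):
        # D-H points away from A: angle D-H...A ~ 0, far below 150 degrees
        coords = [[0.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [3.0, 0.0, 0.0]]  # D, H, A
        traj = make_traj([coords], names=["N", "H", "O"])
        crit = HBondCriteria(angle_cutoff=150.0)
        counts = hbond_counts(traj, donors=[0], acceptors=[2], crit=crit, hydrogens={0: 1})
        assert counts.tolist() == [0]

    def test_empty_selection_is_an_error(self):
        traj, _ = gen_trajectory(2, 4, 0.1, seed=4)
        with pytest.raises(ValueError):
            hbond_counts(traj, donors=[], acceptors=[1])


class TestEnergy:
    def test_constant_series(self):
        s = EnergySeries([-400.0] * 5, [-100.0] * 5, range(5))
        assert energy_summary(s) == pytest.approx(-500.0)

    def test_alternating_series_cancels(self):
        s = EnergySeries([3.0, -3.0] * 4, [0.0] * 8, range(8))
        assert energy_summary(s) == pytest.approx(0.0)

    def test_mean_recovered_within_standard_error(self):
        rng = stream(37, "test-energy")
        n = 4000
        coul = rng.normal(-600_000.0, 500.0, n)
        lj = rng.normal(-258_589.2, 300.0, n)
        s = EnergySeries(coul, lj, np.arange(n) * 0.01)
        se = math.sqrt(500.0**2 + 300.0**2) / math.sqrt(n)
        assert energy_summary(s) == pytest.approx(-858_589.2, abs=4 * se)

    def test_published_ratio_examples(self):
        assert energy_ratio(-859_009.6, -858_589.2) == 1.0005
        assert energy_ratio(-859_268.4, -858_589.2) == 1.0008
        assert energy_ratio(-5.0, -5.0) == 1.0

    def test_ratio_inverse_product_is_one(self):
        a, b = -859_009.6, -858_589.2
        assert energy_ratio(a, b) * energy_ratio(b, a) == pytest.approx(1.0, abs=1e-3)

    def test_ratio_errors(self):
        with pytest.raises(ValueError):
            energy_ratio(-5.0, 0.0)
        with pytest.raises(ValueError):
            energy_ratio(5.0, -5.0)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            EnergySeries([1.0, 2.0], [1.0], [0.0, 1.0])

    def test_two_column_file_reader(self, tmp_path):
        coul = tmp_path / "coul.txt"
        lj = tmp_path / "lj.txt"
        coul.write_text("# comment\n@ legend\n0.0 -600000.0\n0.01 -600100.0\n")
        lj.write_text("0.0 -258589.2\n0.01 -258489.2\n")
        s = read_energy_series(coul, lj)
        assert len(s.times) == 2
        assert energy_summary(s) == pytest.approx(-858_589.2)
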