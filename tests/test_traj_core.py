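"""Geometry tests: Kabsch against a random-rotation oracle, closed-form Rg/RMSF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from indelflex.synthetic_data import TrajectorySpec, generate_trajectories
from indelflex.traj_core import (Replicate, aggregate_rmsf, radius_of_gyration,
                                 rg_series, rmsd_series, rmsf_profile,
                                 sem_of_max_dif, superpose, superpose_frames,
                                 trim_equilibration)


def random_replicate(n_frames=20, n_atoms=8, seed=0, sigma=0.3):
    rng = np.random.default_rng(seed)
    base = rng.normal(scale=5.0, size=(n_atoms, 3))
    coords = base[None] + rng.normal(scale=sigma, size=(n_frames, n_atoms, 3))
    return Replicate(coords, np.arange(n_frames) * 100.0, np.arange(1, n_atoms + 1))


class TestSuperpose:
    def test_identical_zero(self):
        c = np.random.default_rng(0).normal(size=(10, 3))
        _, rmsd = superpose(c, c)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_zero(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(10, 3))
        rot = Rotation.random(random_state=2).as_matrix()
        moved, rmsd = superpose(c @ rot.T + np.array([1.0, -2.0, 3.0]), c)
        assert rmsd <= 1e-8
        assert np.allclose(moved, c, atol=1e-8)

    def test_minimality_vs_random_rotations(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(10, 3))
        target = rng.normal(size=(10, 3))
        _, rmsd = superpose(mobile, target)
        mc = mobile - mobile.mean(axis=0)
        tc = target - target.mean(axis=0)
        rots = Rotation.random(10_000, random_state=4).as_matrix()
        trials = np.einsum("ni,rij->rnj", mc, rots.transpose(0, 2, 1))
        trial_rmsd = np.sqrt(np.mean(np.sum((trials - tc) ** 2, axis=-1), axis=-1))
        assert rmsd <= trial_rmsd.min() + 1e-12

    def test_proper_rotation(self):
        # mirror-image target must still be matched with det(+1) rotation
        rng = np.random.default_rng(5)
        c = rng.normal(size=(6, 3))
        mirrored = c * np.array([-1.0, 1.0, 1.0])
        moved, rmsd = superpose(c, mirrored)
        assert rmsd > 0.0  # improper match is not allowed

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose(line, line)


class TestRg:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_atoms(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_unit_square(self):
        corners = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        assert radius_of_gyration(corners) == pytest.approx(np.sqrt(2) / 2)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        c = rng.normal(size=(12, 3))
        rot = Rotation.random(random_state=7).as_matrix()
        assert radius_of_gyration(c @ rot.T + 5.0) == pytest.approx(
            radius_of_gyration(c), abs=1e-9)

    def test_series_matches_per_frame(self):
        rep = random_replicate()
        series = rg_series(rep)
        for f in [0, 7, 19]:
            assert series.values[f] == pytest.approx(
                radius_of_gyration(rep.coords[f]))


class TestRmsdSeries:
    def test_static_zero(self):
        rep = random_replicate(sigma=0.0)
        assert np.allclose(rmsd_series(rep).values, 0.0, atol=1e-10)

    def test_rotated_frames_zero(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(10, 3))
        rots = Rotation.random(5, random_state=9).as_matrix()
        coords = np.einsum("ni,fij->fnj", base, rots.transpose(0, 2, 1))
        rep = Replicate(coords, np.arange(5) * 100.0, np.arange(1, 11))
        assert np.all(rmsd_series(rep).values < 1e-8)

    def test_matches_per_frame_kabsch_oracle(self):
        rep = random_replicate(n_frames=5, seed=10)
        series = rmsd_series(rep)
        for f in range(5):
            _, rmsd = superpose(rep.coords[f], rep.coords[0])
            assert series.values[f] == pytest.approx(rmsd, abs=1e-10)


class TestRmsf:
    def test_static_zero(self):
        rep = random_replicate(sigma=0.0)
        assert np.allclose(rmsf_profile(rep), 0.0, atol=1e-12)

    def test_single_oscillating_atom(self):
        # many anchor atoms pin the superposition; one atom oscillates +-eps
        rng = np.random.default_rng(11)
        base = rng.normal(scale=10.0, size=(60, 3))
        eps = 0.05
        frames = np.repeat(base[None], 40, axis=0).copy()
        frames[::2, 0, 0] += eps
        frames[1::2, 0, 0] -= eps
        rep = Replicate(frames, np.arange(40) * 100.0, np.arange(1, 61))
        rmsf = rmsf_profile(rep)
        assert rmsf[0] == pytest.approx(eps, rel=0.05)
        assert np.all(rmsf[1:] < eps * 0.2)

    def test_requires_two_frames(self):
        rep = random_replicate(n_frames=1)
        with pytest.raises(ValueError):
            rmsf_profile(rep)

    def test_parseval_identity(self):
        # mean squared deviation from the average structure equals the mean
        # of squared RMSF over atoms
        rep = random_replicate(seed=12)
        moved = superpose_frames(rep.coords, rep.coords[0])
        mean_pos = moved.mean(axis=0)
        msd = np.mean(np.sum((moved - mean_pos) ** 2, axis=-1))
        rmsf = rmsf_profile(rep)
        assert msd == pytest.approx(np.mean(rmsf ** 2))

    def test_aggregate_stats(self):
        reps = [random_replicate(seed=s) for s in (1, 2, 3)]
        prof = aggregate_rmsf(reps)
        assert prof.per_replicate.shape == (3, 8)
        assert np.allclose(prof.sem, prof.sd / np.sqrt(3))

    def test_rigid_motion_invariance(self):
        rep = random_replicate(seed=13)
        rot = Rotation.random(random_state=14).as_matrix()
        moved = Replicate(np.einsum("fni,ij->fnj", rep.coords, rot.T) + 2.0,
                          rep.times_ps, rep.residue_ids)
        assert np.allclose(rmsf_profile(rep), rmsf_profile(moved), atol=1e-8)


class TestTrim:
    def test_fixed_burn_in_frame_count(self):
        # 3 ns at 100 ps -> 30 frames; trimming 0.4 ns leaves 26
        spec = TrajectorySpec(n_residues=5, duration_ns=3.0,
                              frame_interval_ps=100.0, n_replicates=1,
                              amplitude_profile={"wt": np.full(5, 0.1)}, seed=0)
        rep = generate_trajectories(spec).systems["wt"][0]
        trimmed = trim_equilibration(rep, burn_in=0.4)
        assert trimmed.n_frames == 26

    def test_burn_in_longer_than_trajectory(self):
        rep = random_replicate(n_frames=10)
        with pytest.raises(ValueError):
            trim_equilibration(rep, burn_in=100.0)

    def test_auto_zero_drift(self):
        spec = TrajectorySpec(n_residues=30, duration_ns=50.0,
                              frame_interval_ps=100.0, n_replicates=1,
                              amplitude_profile={"wt": np.full(30, 0.2)}, seed=1)
        rep = generate_trajectories(spec).systems["wt"][0]
        trimmed = trim_equilibration(rep, burn_in="auto")
        assert trimmed.n_frames >= rep.n_frames * 0.95

    def test_auto_with_drift_trims(self):
        spec = TrajectorySpec(n_residues=30, duration_ns=50.0,
                              frame_interval_ps=100.0, n_replicates=1,
                              amplitude_profile={"wt": np.full(30, 0.1)},
                              burn_in_drift=(20.0, 15.0), seed=2)
        rep = generate_trajectories(spec).systems["wt"][0]
        trimmed = trim_equilibration(rep, burn_in="auto")
        assert trimmed.n_frames < rep.n_frames


class TestSemOfMaxDif:
    def test_identical_series_zero(self):
        loc, val = sem_of_max_dif({"a": np.ones(5), "b": np.ones(5)})
        assert val == 0.0

    def test_hand_computation(self):
        loc, val = sem_of_max_dif({"wt": np.array([1.0, 2.0, 5.0]),
                                   "del": np.array([1.0, 2.0, 3.0])},
                                  axis=np.array([1, 2, 3]))
        assert loc == 3
        assert val == pytest.approx(1.0)  # sd({5,3})/sqrt(2) = sqrt(2)/sqrt(2)

    def test_four_equal_systems(self):
        series = {k: np.arange(4.0) for k in "abcd"}
        _, val = sem_of_max_dif(series)
        assert val == 0.0

    def test_axis_mismatch(self):
        with pytest.raises(ValueError):
            sem_of_max_dif({"a": np.ones(3), "b": np.ones(3)}, axis=np.ones(2))


class TestReplicateValidation:
    def test_uneven_times_rejected(self):
        with pytest.raises(ValueError):
            Replicate(np.zeros((3, 4, 3)), np.array([0.0, 1.0, 5.0]),
                      np.arange(1, 5))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Replicate(np.zeros((3, 4, 3)), np.arange(3.0), np.arange(1, 4))
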