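"""Comparison-statistics tests: hand-computed t/BH values and library cross-checks."""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from indelflex.traj_core import ResidueProfile
from indelflex.traj_compare import (SSOccupancy, bh_adjust, compare_occupancy,
                                    compare_systems, contiguous_runs,
                                    loop_flexibility_test, simplify_ss,
                                    ss_occupancy, two_sample_t, window_means)


def profile(matrix, ids=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    ids = np.arange(1, matrix.shape[1] + 1) if ids is None else np.asarray(ids)
    return ResidueProfile(ids, matrix)


class TestWindows:
    def test_five_residues_three_windows(self):
        wins, vals = window_means(profile(np.arange(5.0)))
        assert wins == [(1, 3), (2, 4), (3, 5)]
        assert np.allclose(vals[0], [1.0, 2.0, 3.0])

    def test_gap_skipped(self):
        ids = [151, 152, 156, 157, 158]
        wins, _ = window_means(profile(np.zeros(5), ids=ids))
        assert wins == [(156, 158)]

    def test_constant_profile(self):
        wins, vals = window_means(profile(np.full((2, 6), 3.5)))
        assert np.allclose(vals, 3.5)

    def test_no_window_possible(self):
        with pytest.raises(ValueError):
            window_means(profile(np.zeros(4), ids=[1, 2, 5, 6]))

    def test_contiguous_runs(self):
        runs = contiguous_runs(np.array([1, 2, 3, 7, 8, 12]))
        assert [list(r) for r in runs] == [[1, 2, 3], [7, 8], [12]]


class TestTTest:
    def test_identical_groups(self):
        assert two_sample_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_large_shift(self):
        a = [1.0, 2.0, 3.0]
        b = [101.0, 102.0, 103.0]
        t, p = two_sample_t(a, b)
        assert p < 1e-6

    def test_hand_computed_pooled_t(self):
        t, p = two_sample_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0)
        assert p == pytest.approx(0.3466, abs=2e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=5)
            b = rng.normal(loc=0.5, size=5)
            t, p = two_sample_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_conventions(self):
        assert two_sample_t([1, 1], [1, 1]) == (0.0, 1.0)
        t, p = two_sample_t([1, 1], [2, 2])
        assert p == 0.0 and np.isinf(t)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


def bh_bruteforce(p):
    """Step-up BH by direct enumeration of the adjusted-p definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, i in enumerate(order, start=1):
        candidates = [p[j] * m / (list(order).index(j) + 1)
                      for j in order[rank_pos - 1:]]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBH:
    def test_empty(self):
        adj, rej = bh_adjust([])
        assert adj.size == 0 and rej.size == 0

    def test_textbook_example(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.04], alpha=0.05)
        assert np.allclose(adj, [0.03, 0.03, 0.04])
        assert rej.all()

    def test_none_rejected(self):
        _, rej = bh_adjust([0.5, 0.6])
        assert not rej.any()

    def test_bruteforce_all_small_sets(self):
        rng = np.random.default_rng(1)
        for m in range(1, 6):
            for _ in range(30):
                p = rng.uniform(size=m)
                adj, _ = bh_adjust(p)
                assert np.allclose(adj, bh_bruteforce(list(p)))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=100)
        adj, rej = bh_adjust(p, alpha=0.05)
        sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, sm_adj)
        assert np.array_equal(rej, sm_rej)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        adj, _ = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def four_system_profiles(n_res=20, n_rep=5, seed=0, bump=None):
    """Null RMSF-like profiles; bump=(ids, delta, systems) plants an offset."""
    rng = np.random.default_rng(seed)
    profiles = {}
    for system in ("wt", "del", "wtg", "delg"):
        mat = 1.0 + 0.05 * rng.normal(size=(n_rep, n_res))
        if bump and system in bump[2]:
            ids, delta = bump[0], bump[1]
            mat[:, [i - 1 for i in ids]] += delta
        profiles[system] = ResidueProfile(np.arange(1, n_res + 1), mat)
    return profiles


class TestCompareSystems:
    def test_consistency_is_intersection(self):
        bump = ([5, 6, 7], 3.0, ("del", "delg"))
        profiles = four_system_profiles(seed=4, bump=bump)
        peaks = compare_systems(profiles)
        assert (5, 7) in peaks.consistent_windows
        assert peaks.direction_concordance[(5, 7)]

    def test_discordant_directions_reported(self):
        profiles = four_system_profiles(seed=5)
        # raise in del (vs wt) but lower in delg (vs wtg) -> discordant
        for system, sign in (("del", +1), ("delg", -1)):
            profiles[system].per_replicate[:, 4:7] += sign * 3.0
            profiles[system] = ResidueProfile(profiles[system].residue_ids,
                                              profiles[system].per_replicate)
        peaks = compare_systems(profiles)
        assert (5, 7) in peaks.consistent_windows
        assert not peaks.direction_concordance[(5, 7)]

    def test_table2_scenario_concludes_no_consistent_effect(self):
        # significant in both deletion comparisons, below resolution, discordant
        profiles = four_system_profiles(seed=6)
        for system, sign in (("del", +1), ("delg", -1)):
            mat = profiles[system].per_replicate.copy()
            mat[:, 4:7] += sign * 0.8  # well below the 2.5 A resolution
            profiles[system] = ResidueProfile(profiles[system].residue_ids, mat)
        peaks = compare_systems(profiles)
        assert (5, 7) in peaks.consistent_windows
        assert not peaks.direction_concordance[(5, 7)]
        sig = peaks.for_comparison("wt", "del")
        row = sig[sig["window_start"] == 5].iloc[0]
        assert row["significant"] and not row["above_resolution"]
        assert peaks.conclusion == "no_consistent_effect"

    def test_concordant_above_resolution_flags_effect(self):
        bump = ([5, 6, 7], 4.0, ("del", "delg"))
        peaks = compare_systems(four_system_profiles(seed=7, bump=bump))
        assert peaks.conclusion == "possible_consistent_effect"

    def test_missing_system_rejected(self):
        profiles = four_system_profiles()
        del profiles["delg"]
        with pytest.raises(KeyError):
            compare_systems(profiles)

    def test_windows_skip_deleted_gap(self):
        profiles = four_system_profiles(n_res=12)
        ids = np.array([i for i in range(1, 13) if i not in (5, 6)])
        for s in ("del", "delg"):
            profiles[s] = ResidueProfile(
                ids, profiles[s].per_replicate[:, [i - 1 for i in ids]])
        peaks = compare_systems(profiles)
        starts = set(peaks.for_comparison("wt", "del")["window_start"])
        assert 4 not in starts and 5 not in starts and 6 not in starts

    def test_adjusted_ge_raw_everywhere(self):
        peaks = compare_systems(four_system_profiles(seed=8))
        assert np.all(peaks.table["p_adj"] >= peaks.table["p"] - 1e-15)


class TestLoopTest:
    def test_identical_p_one(self):
        prof = profile(np.ones((3, 10)))
        res = loop_flexibility_test({"wt": prof, "del": prof},
                                    loop_residues=range(3, 8),
                                    pairs=[("wt", "del")])
        assert res[("wt", "del")] == (0.0, 1.0)

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(9)
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            wt = 1.0 + 0.1 * rng.normal(size=(5, 10))
            dl = 3.0 + 0.1 * rng.normal(size=(5, 10))
            res = loop_flexibility_test({"wt": profile(wt), "del": profile(dl)},
                                        loop_residues=range(1, 11),
                                        pairs=[("wt", "del")])
            if res[("wt", "del")][1] < 0.05:
                detected += 1
        assert detected >= 18

    def test_single_residue_loop_equals_residue_test(self):
        rng = np.random.default_rng(10)
        wt = rng.normal(size=(4, 6))
        dl = rng.normal(size=(4, 6))
        res = loop_flexibility_test({"wt": profile(wt), "del": profile(dl)},
                                    loop_residues=[3], pairs=[("wt", "del")])
        assert res[("wt", "del")] == two_sample_t(wt[:, 2], dl[:, 2])

    def test_empty_loop_rejected(self):
        with pytest.raises(ValueError):
            loop_flexibility_test({"wt": profile(np.ones((2, 4))),
                                   "del": profile(np.ones((2, 4)))},
                                  loop_residues=[99], pairs=[("wt", "del")])


class TestSSOccupancy:
    def test_all_helix(self):
        occ = ss_occupancy([["HHH", "HHH"]], residue_ids=[1, 2, 3])
        assert np.allclose(occ.helix, 1.0)
        assert np.allclose(occ.strand, 0.0)

    def test_half_helix(self):
        occ = ss_occupancy([["HCC", "CCC"]], residue_ids=[1, 2, 3])
        assert occ.helix[0] == pytest.approx(0.5)

    def test_alphabet_simplification(self):
        assert simplify_ss("G") == "H"
        assert simplify_ss("B") == "E"
        assert simplify_ss("T") == "C"
        occ = ss_occupancy([["GIE"]], residue_ids=[1, 2, 3])
        assert np.allclose(occ.helix, [1, 1, 0])
        assert np.allclose(occ.strand, [0, 0, 1])

    def test_frequencies_sum_to_one(self):
        occ = ss_occupancy([["HEC", "CHE"], ["EEE", "HHH"]],
                           residue_ids=[1, 2, 3])
        assert np.allclose(occ.helix + occ.strand + occ.other, 1.0)

    def test_planted_occupancy_recovered(self):
        rng = np.random.default_rng(11)
        frames_wt = ["H" if rng.random() < 0.5 else "C" for _ in range(4000)]
        frames_del = ["H" if rng.random() < 0.1 else "C" for _ in range(4000)]
        occ_wt = ss_occupancy([frames_wt], residue_ids=[1])
        occ_del = ss_occupancy([frames_del], residue_ids=[1])
        delta = compare_occupancy(occ_wt, occ_del)
        assert delta["delta_helix"].iloc[0] == pytest.approx(0.4, abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ss_occupancy([["HH"]], residue_ids=[1, 2, 3])
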