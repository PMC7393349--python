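"""Binding profiles, L1 distances, duplicate elimination, proximity test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from asthmanet.dmr import (ProximityResult, binding_vector, distance_matrix,
                           eliminate_near_duplicates, profiles_from_hits,
                           proximity_test, run_dmr_panel)


class TestBindingVector:
    def test_single_centered_hit_is_symmetric_unimodal(self):
        v = binding_vector([50], 101)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert v.argmax() == 50
        assert np.allclose(v[50 - 10:50 + 11], v[50 - 10:50 + 11][::-1])
        assert v[39] == 0.0 and v[61] == 0.0  # 21-bp support

    def test_identical_hit_sets_give_identical_vectors(self):
        a = binding_vector([5, 40], 80)
        b = binding_vector([5, 40], 80)
        assert np.array_equal(a, b)
        assert distance_matrix(np.stack([a, b]))[0, 1] == 0.0

    def test_edge_clipped_hit_still_sums_to_one(self):
        for pos in (0, 1, 99, 100):
            assert binding_vector([pos], 101).sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_hits_rejected(self):
        with pytest.raises(ValueError):
            binding_vector([], 100)

    def test_out_of_range_hit_rejected(self):
        with pytest.raises(ValueError):
            binding_vector([120], 100)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_sum_to_one_for_random_hit_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 300))
        hits = rng.integers(0, n, size=rng.integers(1, 8))
        assert binding_vector(hits, n).sum() == pytest.approx(1.0, abs=1e-9)


class TestDistanceMatrix:
    def test_disjoint_support_attains_two(self):
        a = binding_vector([15], 200)
        b = binding_vector([150], 200)
        assert distance_matrix(np.stack([a, b]))[0, 1] == pytest.approx(2.0)

    def test_close_hits_match_direct_kernel_evaluation(self):
        """Two single-hit profiles 3 bp apart against a hand-coded sum."""
        a = binding_vector([100], 300)
        b = binding_vector([103], 300)
        got = distance_matrix(np.stack([a, b]))[0, 1]
        offs = np.arange(-10, 11)
        k = stats.norm.pdf(offs, 0, 5.0)
        k = k / k.sum()
        grid = np.zeros(300)
        grid2 = np.zeros(300)
        grid[100 + offs] = k
        grid2[103 + offs] = k
        assert got == pytest.approx(np.abs(grid - grid2).sum(), abs=1e-12)

    def test_bounds_and_triangle_inequality(self, rng):
        profiles = np.stack([
            binding_vector(rng.integers(0, 150, size=rng.integers(1, 6)), 150)
            for _ in range(8)])
        d = distance_matrix(profiles)
        assert (d >= -1e-12).all() and (d <= 2.0 + 1e-12).all()
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestEliminateNearDuplicates:
    def test_no_close_pairs_keeps_everything(self, rng):
        d = np.full((4, 4), 1.0) - np.eye(4)
        kept, log = eliminate_near_duplicates(d, list("abcd"), rng=rng)
        assert kept == [0, 1, 2, 3] and log == []

    def test_one_zero_pair_drops_exactly_one(self, rng):
        d = np.full((4, 4), 1.0) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        kept, log = eliminate_near_duplicates(d, list("abcd"), rng=rng)
        assert len(kept) == 3 and len(log) == 1
        assert {log[0]["dropped"], log[0]["kept"]} == {"a", "b"}

    def test_clique_of_four_leaves_exactly_one_survivor(self):
        """However the random choices fall, a mutually-near clique always
        collapses to a single member."""
        d = np.full((6, 6), 1.5) - 1.5 * np.eye(6)
        for i in range(4):
            for j in range(4):
                if i != j:
                    d[i, j] = 0.05
        for seed in range(100):
            kept, _ = eliminate_near_duplicates(
                d, list("abcdef"), rng=np.random.default_rng(seed))
            assert sum(k < 4 for k in kept) == 1
            assert {4, 5}.issubset(kept)

    def test_post_elimination_min_distance_respects_threshold(self, rng):
        for _ in range(50):
            profiles = np.stack([
                binding_vector(rng.integers(0, 100, size=2), 100)
                for _ in range(10)])
            d = distance_matrix(profiles)
            kept, _ = eliminate_near_duplicates(d, [str(i) for i in range(10)],
                                                rng=rng)
            sub = d[np.ix_(kept, kept)]
            iu = np.triu_indices(len(kept), 1)
            if len(iu[0]):
                assert sub[iu].min() >= 0.1


class TestProximityTest:
    def _profiles(self, positions_by_tf, n=400):
        return profiles_from_hits(positions_by_tf, n)

    def test_constant_labels_untestable(self):
        prof = self._profiles({"a": [10], "b": [300]})
        labels = pd.Series({"a": "X", "b": "X"})
        res = proximity_test(prof, labels, n_perm=50, seed=0)
        assert not res.testable and res.p_value is None

    def test_disjoint_halves_give_high_silhouette_and_p_zero(self):
        """Clusters binding disjoint halves approach silhouette 1 (exact
        unity is unattainable: identical profiles are eliminated as
        near-duplicates, so within-cluster distances stay positive)."""
        prof = self._profiles({"a1": [40], "a2": [42], "b1": [340], "b2": [338]})
        labels = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = proximity_test(prof, labels, n_perm=200, seed=0)
        assert res.observed_ss > 0.8
        assert res.p_value == 0.0

    def test_p_value_invariant_to_label_renaming(self):
        rng = np.random.default_rng(4)
        prof = self._profiles({f"t{i}": list(rng.integers(0, 400, 2))
                               for i in range(8)})
        labels = pd.Series({f"t{i}": "A" if i < 4 else "B" for i in range(8)})
        renamed = labels.map({"A": "group-one", "B": "group-two"})
        r1 = proximity_test(prof, labels, n_perm=300, seed=11)
        r2 = proximity_test(prof, renamed, n_perm=300, seed=11)
        assert r1.p_value == r2.p_value

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(9)
        prof = self._profiles({f"t{i}": list(rng.integers(0, 400, 2))
                               for i in range(8)})
        labels = pd.Series({f"t{i}": "A" if i % 2 else "B" for i in range(8)})
        r1 = proximity_test(prof, labels, n_perm=200, seed=5)
        r2 = proximity_test(prof, labels, n_perm=200, seed=5)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_ss, r2.null_ss)


class TestRunDmrPanel:
    def test_empty_dmr_list_gives_empty_table(self, small_sequences):
        pfms = small_sequences[0]
        table, results = run_dmr_panel({}, pfms, pd.Series(dtype=object),
                                       n_perm=10, seed=0)
        assert len(table) == 0 and results == {}

    def test_separated_zones_are_significant(self, small_cfg, small_study,
                                             small_sequences):
        _, truth = small_study
        pfms, _, dmrs, _ = small_sequences
        table, _ = run_dmr_panel(dmrs, pfms, truth.tf_cluster_labels,
                                 n_perm=500, seed=1)
        ok = table[table.flag == "ok"]
        assert len(ok) == len(table)
        assert (ok.p < 0.01).all()

    def test_dmr_with_too_few_bound_tfs_untestable(self, small_sequences):
        pfms, _, _, _ = small_sequences
        one_pfm = {next(iter(pfms)): pfms[next(iter(pfms))]}
        labels = pd.Series({next(iter(pfms)): "A"})
        table, _ = run_dmr_panel({"empty": "ACGT" * 50}, one_pfm, labels,
                                 n_perm=10, seed=0)
        assert (table.flag == "untestable").all()

    def test_panel_byte_reproducible(self, small_cfg, small_study, small_sequences):
        _, truth = small_study
        pfms, _, dmrs, _ = small_sequences
        t1, _ = run_dmr_panel(dmrs, pfms, truth.tf_cluster_labels,
                              n_perm=100, seed=3)
        t2, _ = run_dmr_panel(dmrs, pfms, truth.tf_cluster_labels,
                              n_perm=100, seed=3)
        assert t1.to_csv() == t2.to_csv()
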