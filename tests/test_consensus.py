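import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import immunesig as im
from immunesig.consensus import ConsensusResult, Partition, _cdf_area


def _blobs(k=3, per=12, n_samp=30, sep=8.0, noise=0.3, seed=0):
    """Well-separated feature profiles in k groups."""
    rng = np.random.default_rng(seed)
    rows, names, labels = [], [], []
    centers = rng.normal(0, sep, size=(k, n_samp))
    for c in range(k):
        for i in range(per):
            rows.append(centers[c] + rng.normal(0, noise, n_samp))
            names.append(f"c{c}_f{i}")
            labels.append(c + 1)
    df = pd.DataFrame(rows, index=names, columns=[f"s{j}" for j in range(n_samp)])
    return im.ExpressionMatrix(df, "blobs"), np.array(labels)


class TestConsensusMatrix:
    def test_oracle_equivalence_full_sampling_deterministic_base(self):
        """With item_fraction=1 and a deterministic base clusterer, the
        consensus matrix is exactly the 0/1 co-membership indicator."""
        x, truth_labels = _blobs(k=3, per=8)

        def fixed_kmeans(profiles, k, seed):
            return im.kmeans_cluster(profiles, k, seed=0)  # ignore the seed

        res = im.consensus_cluster(
            x, "kmeans", k_range=[3], n_resamples=20, item_fraction=1.0,
            seed=5, base_clusterer=fixed_kmeans,
        )[3]
        co = (truth_labels[:, None] == truth_labels[None, :]).astype(float)
        assert set(np.unique(res.consensus)) <= {0.0, 1.0}
        np.testing.assert_array_equal(res.consensus, co)

    def test_matrix_invariants(self, small_study):
        mats, truth, _ = small_study
        sub = mats[0].subset_features(
            sorted(set().union(*truth.conserved_modules.values()))
        )
        res = im.consensus_cluster(sub, "kmeans", k_range=[2, 3],
                                   n_resamples=15, seed=2)
        for r in res.values():
            assert np.array_equal(r.consensus, r.consensus.T)
            assert np.all(np.diag(r.consensus) == 1.0)
            assert r.consensus.min() >= 0.0 and r.consensus.max() <= 1.0

    def test_separated_clusters_give_sharp_consensus(self):
        x, labels = _blobs(k=3, per=10, noise=0.1)
        res = im.consensus_cluster(x, "kmeans", k_range=[3],
                                   n_resamples=60, seed=7)[3]
        within = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(len(labels), dtype=bool)
        assert res.consensus[within & off_diag].min() >= 0.95
        assert res.consensus[~within].max() <= 0.05

    def test_noise_data_has_lower_cluster_consensus(self):
        x_sep, _ = _blobs(k=3, per=10, noise=0.1, seed=1)
        rng = np.random.default_rng(1)
        x_noise = im.ExpressionMatrix(
            pd.DataFrame(
                rng.normal(0, 1, size=x_sep.shape),
                index=x_sep.feature_ids, columns=x_sep.sample_ids,
            ),
            "noise",
        )
        r_sep = im.consensus_cluster(x_sep, "kmeans", k_range=[3],
                                     n_resamples=40, seed=3)[3]
        r_noise = im.consensus_cluster(x_noise, "kmeans", k_range=[3],
                                       n_resamples=40, seed=3)[3]
        assert r_noise.mean_cluster_consensus < r_sep.mean_cluster_consensus

    def test_never_cosampled_pair_scored_zero(self):
        x, _ = _blobs(k=2, per=3, n_samp=10)
        res = im.consensus_cluster(x, "kmeans", k_range=[2], n_resamples=1,
                                   item_fraction=0.5, seed=11)[2]
        off_diag = ~np.eye(res.consensus.shape[0], dtype=bool)
        unsampled = (res.co_sample_counts == 0) & off_diag
        assert unsampled.any()
        assert np.all(res.consensus[unsampled] == 0.0)


class TestSelectK:
    def test_planted_three_clusters_selects_three(self):
        x, _ = _blobs(k=3, per=10, noise=0.2, seed=4)
        res = im.consensus_cluster(x, "kmeans", k_range=range(2, 7),
                                   n_resamples=40, seed=4)
        assert im.select_k(res) == 3

    def test_identical_candidates_pick_smaller_k(self):
        x, labels = _blobs(k=2, per=6)
        res2 = im.consensus_cluster(x, "kmeans", k_range=[2],
                                    n_resamples=10, seed=0)[2]
        clone = ConsensusResult(
            dataset=res2.dataset, algorithm=res2.algorithm, k=3,
            item_ids=res2.item_ids, consensus=res2.consensus,
            co_sample_counts=res2.co_sample_counts,
            consensus_partition=res2.consensus_partition,
            cluster_consensus=res2.cluster_consensus,
            item_consensus=res2.item_consensus,
        )
        assert im.select_k({2: res2, 3: clone}) == 2

    def test_single_candidate_returned(self):
        x, _ = _blobs(k=2, per=6)
        res = im.consensus_cluster(x, "kmeans", k_range=[4], n_resamples=10, seed=0)
        assert im.select_k(res) == 4


class TestSOM:
    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            im.som_cluster(np.random.default_rng(0).normal(size=(10, 5)), 1, 0)

    def test_nonfinite_input_rejected(self):
        bad = np.full((5, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            im.som_cluster(bad, 2, 0)

    def test_matches_kmeans_on_separated_blobs(self):
        x, _ = _blobs(k=3, per=10, noise=0.2, seed=6)
        profiles = (x.values - x.values.mean(1, keepdims=True)) / x.values.std(
            1, keepdims=True
        )
        som = Partition(x.feature_ids, im.som_cluster(profiles, 3, seed=1), 3, "som")
        km = Partition(x.feature_ids, im.kmeans_cluster(profiles, 3, seed=1), 3, "kmeans")
        assert im.adjusted_rand(som, km) == 1.0

    def test_fixed_seed_is_deterministic(self):
        x, _ = _blobs(k=3, per=8, seed=2)
        a = im.som_cluster(x.values, 4, seed=9)
        b = im.som_cluster(x.values, 4, seed=9)
        assert np.array_equal(a, b)

    def test_labels_consecutive_from_one(self):
        x, _ = _blobs(k=2, per=6, seed=3)
        labels = im.som_cluster(x.values, 5, seed=1)
        present = sorted(set(labels.tolist()))
        assert present == list(range(1, len(present) + 1))


def _ari_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """ARI from raw pair counting (agreements vs expected)."""
    n = len(a)
    pairs = list(itertools.combinations(range(n), 2))
    s11 = sum(1 for i, j in pairs if a[i] == a[j] and b[i] == b[j])
    sa = sum(1 for i, j in pairs if a[i] == a[j])
    sb = sum(1 for i, j in pairs if b[i] == b[j])
    total = len(pairs)
    expected = sa * sb / total
    max_index = (sa + sb) / 2
    if max_index == expected:
        return 1.0
    return (s11 - expected) / (max_index - expected)


def _all_partitions(items):
    """Every set partition, as label arrays."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        yield [[first]] + [list(b) for b in part]
        for i in range(len(part)):
            clone = [list(b) for b in part]
            clone[i].append(first)
            yield clone


class TestAdjustedRand:
    def _partition(self, labels, ids=None):
        labels = np.asarray(labels)
        ids = ids or [f"i{j}" for j in range(len(labels))]
        return Partition(ids, labels, k=max(2, labels.max()), algorithm="t")

    def test_identical_partitions_score_one(self):
        p = self._partition([1, 1, 2, 2, 3])
        assert im.adjusted_rand(p, p) == 1.0

    def test_one_cluster_versus_singletons_scores_zero(self):
        a = self._partition(np.ones(10, dtype=int), ids=[f"i{j}" for j in range(10)])
        b = self._partition(np.arange(1, 11), ids=[f"i{j}" for j in range(10)])
        assert im.adjusted_rand(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_pairs_of_partitions_match_bruteforce(self):
        """All partition pairs of 5 items: implementation == pair-count
        brute force == sklearn."""
        items = list(range(5))
        label_sets = []
        for part in _all_partitions(items):
            labels = np.empty(len(items), dtype=int)
            for lab, block in enumerate(part, start=1):
                for i in block:
                    labels[i] = lab
            label_sets.append(labels)
        ids = [f"i{j}" for j in items]
        for a in label_sets:
            for b in label_sets:
                got = im.adjusted_rand(self._partition(a, ids), self._partition(b, ids))
                assert got == pytest.approx(_ari_bruteforce(a, b), abs=1e-12)
                assert got == pytest.approx(adjusted_rand_score(a, b), abs=1e-12)

    def test_permutation_null_mean_near_zero(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 5, size=40)
        ids = [f"i{j}" for j in range(40)]
        p = self._partition(base, ids)
        vals = [
            im.adjusted_rand(p, self._partition(rng.permutation(base), ids))
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_mismatched_item_sets_rejected(self):
        a = self._partition([1, 2, 2], ids=["x", "y", "z"])
        b = self._partition([1, 2, 2], ids=["x", "y", "w"])
        with pytest.raises(ValueError, match="item set"):
            im.adjusted_rand(a, b)

    def test_item_order_does_not_matter(self):
        ids = ["a", "b", "c", "d"]
        p = self._partition([1, 1, 2, 2], ids)
        q = Partition(list(reversed(ids)), np.array([2, 2, 1, 1]), 2)
        assert im.adjusted_rand(p, q) == 1.0


class TestCDFArea:
    def test_perfect_two_block_area_is_between_fraction(self):
        # 6 items in 2 equal blocks: 6/15 within pairs at 1, 9/15 at 0
        co = np.zeros((6, 6))
        co[:3, :3] = 1.0
        co[3:, 3:] = 1.0
        assert _cdf_area(co) == pytest.approx(9 / 15)
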