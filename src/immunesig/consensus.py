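"""Resampled consensus clustering of candidate features.

Within each dataset the candidate features (rows) are standardized and
repeatedly subsampled (80 % of items without replacement by default),
each subsample is partitioned by the base algorithm (k-means or a 1×k
line-topology SOM), and the consensus matrix records, for every item
pair, the fraction of co-sampled runs in which the pair co-clustered.
The number of clusters is chosen by the relative increase of the area
under the consensus-entry CDF (the Δ(K) rule), subject to a mean
cluster-consensus floor; agreement between the two base algorithms is
quantified by the adjusted Rand index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .dataio import ExpressionMatrix, logger

__all__ = [
    "Partition",
    "ConsensusResult",
    "consensus_cluster",
    "select_k",
    "adjusted_rand",
    "kmeans_cluster",
    "som_cluster",
]

BaseClusterer = Callable[[np.ndarray, int, int], np.ndarray]


@dataclass
class Partition:
    """A hard partition of items into clusters labeled 1..k."""

    item_ids: list[str]
    labels: np.ndarray
    k: int
    algorithm: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if len(self.labels) != len(self.item_ids):
            raise ValueError("labels and item_ids length mismatch")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in [1..k]")

    def clusters(self) -> dict[int, frozenset]:
        return {
            int(lab): frozenset(
                i for i, l in zip(self.item_ids, self.labels) if l == lab
            )
            for lab in np.unique(self.labels)
        }


@dataclass
class ConsensusResult:
    """Consensus matrix and summary statistics for one (dataset, algorithm, k)."""

    dataset: str
    algorithm: str
    k: int
    item_ids: list[str]
    consensus: np.ndarray
    co_sample_counts: np.ndarray
    consensus_partition: Partition
    cluster_consensus: dict[int, float]
    item_consensus: pd.DataFrame  # items × cluster labels
    params: dict = field(default_factory=dict)

    @property
    def mean_cluster_consensus(self) -> float:
        return float(np.mean(list(self.cluster_consensus.values())))


# ---------------------------------------------------------------------------
# base clusterers


def kmeans_cluster(profiles: np.ndarray, k: int, seed: int) -> np.ndarray:
    """k-means++ with 10 restarts on standardized profiles; labels 1..k."""
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**32))
    return km.fit_predict(profiles) + 1


def som_cluster(
    profiles: np.ndarray,
    k: int,
    seed: int,
    n_epochs: int = 25,
    lr: tuple[float, float] = (0.5, 0.02),
    sigma: tuple[float, float] | None = None,
) -> np.ndarray:
    """Online 1×k line-topology self-organizing map used as a partitioner.

    Node weights are initialized at quantiles of the items' first
    principal-component ordering; training is online with a Gaussian
    neighborhood whose width decays geometrically from ``k/2`` to 0.2
    over epochs.  Items are labeled by their best-matching node; an
    empty node is re-initialized at the item farthest from its current
    node, so the result has exactly ≤ k non-empty clusters, relabeled
    consecutively.
    """
    X = np.asarray(profiles, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite input to SOM")
    if k < 2:
        raise ValueError("k must be at least 2")
    n, d = X.shape
    if k > n:
        raise ValueError("k exceeds the number of items")
    rng = np.random.default_rng(seed % (2**31))
    if sigma is None:
        sigma = (max(k / 2.0, 0.5), 0.2)

    # topological init: nodes at quantiles of the first-PC projection
    centered = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    order = np.argsort(proj, kind="stable")
    picks = order[np.linspace(0, n - 1, k).round().astype(int)]
    W = X[picks].copy()

    node_idx = np.arange(k, dtype=float)
    for epoch in range(n_epochs):
        frac = epoch / max(n_epochs - 1, 1)
        lr_e = lr[0] * (lr[1] / lr[0]) ** frac
        sig_e = sigma[0] * (sigma[1] / sigma[0]) ** frac
        for i in rng.permutation(n):
            x = X[i]
            bmu = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            h = np.exp(-((node_idx - bmu) ** 2) / (2.0 * sig_e**2))
            W += (lr_e * h)[:, None] * (x - W)

    def assign(weights: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    labels0 = assign(W)
    for _ in range(k):
        empty = [j for j in range(k) if not np.any(labels0 == j)]
        if not empty:
            break
        d_own = ((X - W[labels0]) ** 2).sum(axis=1)
        far = int(np.argmax(d_own))
        W[empty[0]] = X[far]
        labels0 = assign(W)

    # relabel consecutively by node index order
    mapping = {j: i + 1 for i, j in enumerate(sorted(set(labels0.tolist())))}
    return np.array([mapping[j] for j in labels0], dtype=int)


_BASE: dict[str, BaseClusterer] = {"kmeans": kmeans_cluster, "som": som_cluster}


# ---------------------------------------------------------------------------
# consensus machinery


def _standardize_rows(data: pd.DataFrame) -> np.ndarray:
    v = data.to_numpy(dtype=float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (v - mu) / sd


def _consensus_partition(
    consensus: np.ndarray, item_ids: list[str], k: int, algorithm: str
) -> Partition:
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=k, criterion="maxclust")
    # relabel 1..k' in order of first occurrence for determinism
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return Partition(item_ids, out, k=max(2, out.max()), algorithm=algorithm)


def _summaries(
    consensus: np.ndarray, part: Partition
) -> tuple[dict[int, float], pd.DataFrame]:
    labels = part.labels
    n = consensus.shape[0]
    uniq = np.unique(labels)
    cluster_cons: dict[int, float] = {}
    item_cons = pd.DataFrame(index=part.item_ids, dtype=float)
    for lab in uniq:
        idx = np.where(labels == lab)[0]
        if len(idx) < 2:
            cluster_cons[int(lab)] = 1.0  # singleton convention
        else:
            block = consensus[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), 1)
            cluster_cons[int(lab)] = float(block[iu].mean())
        sums = consensus[:, idx].sum(axis=1)
        cnt = np.full(n, float(len(idx)))
        in_c = labels == lab
        sums[in_c] -= 1.0  # drop the diagonal term for members of the cluster
        cnt[in_c] -= 1.0
        item_cons[int(lab)] = np.where(cnt > 0, sums / np.maximum(cnt, 1.0), 1.0)
    return cluster_cons, item_cons


def consensus_cluster(
    x: ExpressionMatrix,
    algorithm: str = "kmeans",
    k_range: Sequence[int] = range(2, 11),
    n_resamples: int = 500,
    item_fraction: float = 0.8,
    seed: int = 0,
    base_clusterer: BaseClusterer | None = None,
) -> dict[int, ConsensusResult]:
    """Consensus-cluster the features of ``x`` over a range of k.

    Per resample, ``ceil(item_fraction·n)`` items are drawn without
    replacement and their standardized profiles clustered; co-cluster
    and co-sample counts accumulate across resamples and their ratio is
    the consensus matrix (0 where a pair was never co-sampled).  The
    final partition at each k comes from average-linkage clustering of
    1 − consensus.
    """
    if base_clusterer is None:
        if algorithm not in _BASE:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        base_clusterer = _BASE[algorithm]
    items = x.feature_ids
    n = len(items)
    k_range = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError("k_range must lie within [2, n_items-1]")
    profiles = _standardize_rows(x.data)
    m = int(math.ceil(item_fraction * n))

    cocluster = {k: np.zeros((n, n)) for k in k_range}
    cosample = np.zeros((n, n))
    for r in range(n_resamples):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        for _redraw in range(100):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            if m >= max(k_range):
                break
            logger.info("resample %d redrawn: fewer items than k", r)
        cosample[np.ix_(idx, idx)] += 1.0
        sub = profiles[idx]
        for k in k_range:
            labels = base_clusterer(sub, k, int(rng.integers(2**31)))
            for lab in np.unique(labels):
                sel = idx[labels == lab]
                cocluster[k][np.ix_(sel, sel)] += 1.0

    results: dict[int, ConsensusResult] = {}
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(cosample > 0, cocluster[k] / np.maximum(cosample, 1), 0.0)
        cons = (cons + cons.T) / 2.0
        np.fill_diagonal(cons, 1.0)
        part = _consensus_partition(cons, items, k, algorithm)
        cluster_cons, item_cons = _summaries(cons, part)
        results[k] = ConsensusResult(
            dataset=x.dataset_name,
            algorithm=algorithm,
            k=k,
            item_ids=items,
            consensus=cons,
            co_sample_counts=cosample.copy(),
            consensus_partition=part,
            cluster_consensus=cluster_cons,
            item_consensus=item_cons,
            params={
                "n_resamples": n_resamples,
                "item_fraction": item_fraction,
                "seed": seed,
            },
        )
    return results


def _cdf_area(consensus: np.ndarray) -> float:
    iu = np.triu_indices(consensus.shape[0], 1)
    v = np.sort(consensus[iu])
    if v.size == 0:
        return 0.0
    xs = np.concatenate([[0.0], v, [1.0]])
    cdf = np.concatenate([[0.0], np.arange(1, v.size + 1) / v.size, [1.0]])
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def select_k(
    results: Mapping[int, ConsensusResult],
    consensus_floor: float = 0.8,
    delta_min: float = 0.1,
) -> int:
    """Pick k by the relative CDF-area increase Δ(K), floor-constrained.

    Δ(K) is the relative increase of the area under the consensus-entry
    CDF over the previous k.  Because Δ at the smallest k is the whole
    area and always dominates, the rule is read as an elbow: k advances
    from the smallest candidate while the relative gain stays at least
    ``delta_min`` (so identical consecutive results stop at the smaller
    k), and among the ks reached this way the largest one whose mean
    cluster consensus meets ``consensus_floor`` is returned.
    """
    ks = sorted(results)
    if len(ks) == 1:
        return ks[0]
    area = {k: _cdf_area(results[k].consensus) for k in ks}
    prefix = [ks[0]]
    for prev, k in zip(ks, ks[1:]):
        denom = area[prev] if area[prev] > 0 else 1e-12
        if (area[k] - area[prev]) / denom < delta_min:
            break
        prefix.append(k)
    eligible = [
        k for k in prefix
        if results[k].mean_cluster_consensus >= consensus_floor
    ]
    if not eligible:
        logger.info("select_k: no k passes the consensus floor; using Δ only")
    return max(eligible) if eligible else max(prefix)


# ---------------------------------------------------------------------------
# adjusted Rand index


def adjusted_rand(p: Partition, q: Partition) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    1 for identical partitions; expectation 0 under random labelings.
    """
    if set(p.item_ids) != set(q.item_ids):
        raise ValueError("partitions cover different item sets")
    q_lab = dict(zip(q.item_ids, q.labels))
    a = np.asarray(p.labels)
    b = np.asarray([q_lab[i] for i in p.item_ids])
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(ct, (ai, bi), 1.0)

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) / 2).sum())

    sum_ij = comb2(ct.astype(float))
    sum_a = comb2(ct.sum(axis=1).astype(float))
    sum_b = comb2(ct.sum(axis=0).astype(float))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
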