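"""Co-expression pattern extraction with resampling stability filtering.

The pattern extractor is a correlation-tree clusterer: average-linkage
hierarchical clustering on 1 − Pearson r, cut at a fixed correlation
height, small clusters discarded.  It is deliberately pluggable — any
callable with the same signature can stand in (e.g. a port of a
published pattern-extraction method).

The stability protocol is the one implemented exactly: repeatedly draw
50 % of samples, re-extract patterns, match them to the full-data
reference clusters by maximal Jaccard overlap, and count per-feature
selections; features selected in at least ``retention`` of
``n_iterations`` draws (750/1000 at full scale) are kept in their most
frequent cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .dataio import ExpressionMatrix, FeatureAnnotation, logger
from .enrichment import hypergeometric_test

__all__ = [
    "StableClusterSet",
    "extract_patterns",
    "stability_filter",
    "flag_immune_clusters",
]

Extractor = Callable[[ExpressionMatrix], dict[str, frozenset]]


@dataclass
class StableClusterSet:
    """Clusters surviving the resampling retention rule for one dataset."""

    dataset: str
    clusters: dict[str, frozenset]
    selection_counts: dict[tuple[str, str], int]
    n_iterations: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for cid, members in self.clusters.items():
            if seen & members:
                raise ValueError(f"cluster {cid} overlaps another cluster")
            seen |= members


def _correlation_tree_clusters(
    data: pd.DataFrame, min_cluster_size: int, corr_cut: float
) -> dict[str, frozenset]:
    features = data.index
    variances = data.var(axis=1, ddof=1).to_numpy()
    usable = variances > 0
    if usable.sum() < 2:
        return {}
    sub = data.loc[features[usable]]
    corr = np.corrcoef(sub.to_numpy())
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=1.0 - corr_cut, criterion="distance")
    clusters: list[frozenset] = []
    for lab in np.unique(labels):
        members = frozenset(sub.index[labels == lab])
        if len(members) >= min_cluster_size:
            clusters.append(members)
    # deterministic ids: order by size desc, ties by smallest member id
    clusters.sort(key=lambda m: (-len(m), min(m)))
    return {f"C{i + 1}": m for i, m in enumerate(clusters)}


def extract_patterns(
    x: ExpressionMatrix,
    min_cluster_size: int = 10,
    corr_cut: float = 0.4,
) -> dict[str, frozenset]:
    """Extract major co-expression patterns from one dataset.

    Average-linkage hierarchical clustering on distance 1 − Pearson r,
    tree cut at height ``1 − corr_cut``; clusters smaller than
    ``min_cluster_size`` are discarded.  Returns ``{}`` (with a log
    message) when nothing survives.
    """
    if x.shape[0] < min_cluster_size:
        raise ValueError(
            f"{x.dataset_name}: {x.shape[0]} features < min_cluster_size"
        )
    clusters = _correlation_tree_clusters(x.data, min_cluster_size, corr_cut)
    if not clusters:
        logger.info("extract_patterns(%s): no cluster survives", x.dataset_name)
    return clusters


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def stability_filter(
    x: ExpressionMatrix,
    n_iterations: int = 1000,
    sample_fraction: float = 0.5,
    retention: int = 750,
    seed: int = 0,
    min_cluster_size: int = 10,
    corr_cut: float = 0.4,
    extractor: Extractor | None = None,
) -> StableClusterSet:
    """Retain features whose cluster membership is stable under resampling.

    Per iteration, ``floor(sample_fraction · n_samples)`` samples are
    drawn without replacement, patterns are re-extracted, each resampled
    cluster is matched to the full-data reference cluster of maximal
    Jaccard overlap (ties to the smaller reference id), and the
    (feature, matched cluster) count is incremented.  Features whose
    best count reaches ``retention`` are kept in that cluster.
    """
    if not (0.0 < sample_fraction <= 1.0):
        raise ValueError("sample_fraction must lie in (0, 1]")
    if retention > n_iterations:
        raise ValueError("retention cannot exceed n_iterations")
    if extractor is None:
        def extractor(m: ExpressionMatrix) -> dict[str, frozenset]:
            return extract_patterns(m, min_cluster_size, corr_cut)

    reference = extractor(x)
    if not reference:
        raise ValueError(
            f"{x.dataset_name}: reference run produced no clusters; "
            "lower corr_cut or min_cluster_size"
        )
    # natural order for ids like C1..C12 so "smaller reference id" is numeric
    ref_ids = sorted(reference, key=lambda c: (len(c), c))
    ref_rank = {rid: i for i, rid in enumerate(ref_ids)}

    n = x.shape[1]
    n_draw = int(np.floor(sample_fraction * n))
    counts: dict[tuple[str, str], int] = {}
    cols = np.asarray(x.sample_ids)
    for it in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        chosen = cols[rng.choice(n, size=n_draw, replace=False)]
        sub = ExpressionMatrix(x.data.loc[:, chosen], x.dataset_name)
        for members in extractor(sub).values():
            scores = {rid: _jaccard(members, reference[rid]) for rid in ref_ids}
            # ties broken to the smaller reference id
            best = min(scores, key=lambda rid: (-scores[rid], ref_rank[rid]))
            if scores[best] == 0.0:
                continue
            for f in members:
                counts[(f, best)] = counts.get((f, best), 0) + 1

    retained: dict[str, set] = {cid: set() for cid in reference}
    for f in x.feature_ids:
        per_cluster = {
            cid: counts.get((f, cid), 0) for cid in reference
        }
        best = min(
            per_cluster, key=lambda cid: (-per_cluster[cid], ref_rank[cid])
        )
        if per_cluster[best] >= retention:
            retained[best].add(f)
    clusters = {
        cid: frozenset(m) for cid, m in retained.items() if m
    }
    return StableClusterSet(
        dataset=x.dataset_name,
        clusters=clusters,
        selection_counts=counts,
        n_iterations=n_iterations,
        params={
            "sample_fraction": sample_fraction,
            "retention": retention,
            "min_cluster_size": min_cluster_size,
            "corr_cut": corr_cut,
            "seed": seed,
        },
    )


def flag_immune_clusters(
    clusters: StableClusterSet,
    ann: FeatureAnnotation,
    p_cut: float = 0.001,
    universe: set[str] | None = None,
) -> set[str]:
    """Flag clusters hypergeometrically enriched for an immune term.

    A cluster is flagged iff the minimum upper-tail hypergeometric
    p-value over all immunity-flagged terms is below ``p_cut``.  The
    default universe is the union of annotated features and cluster
    members; pass the dataset's full feature set for a faithful run.
    """
    if not ann.immune_terms:
        raise ValueError("annotation has no immune terms")
    if universe is None:
        uni = set(ann.annotated_features())
        for members in clusters.clusters.values():
            uni |= members
    else:
        uni = set(universe)
    N = len(uni)
    flagged: set[str] = set()
    for cid, members in clusters.clusters.items():
        mem = members & uni
        n = len(mem)
        if n == 0:
            continue
        best = 1.0
        for term in ann.immune_terms:
            term_feats = ann.term_to_features[term] & uni
            K = len(term_feats)
            if K == 0:
                continue
            x_overlap = len(mem & term_feats)
            best = min(best, hypergeometric_test(N, K, n, x_overlap))
        if best < p_cut:
            flagged.add(cid)
    return flagged
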