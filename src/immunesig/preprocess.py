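"""Probe-to-gene collapsing and candidate-universe assembly.

Probe sets mapping to the same gene are averaged only when they actually
co-vary: probes are grouped into maximal cliques of the probe–probe graph
whose edges are Pearson r > ``r_threshold`` (default 0.4), so every
averaged pair satisfies the correlation gate.  Probes failing the gate,
lacking a gene symbol, or with zero variance pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .dataio import ExpressionMatrix, FeatureAnnotation, logger

__all__ = ["ProbeGroup", "collapse_probes", "take_union"]


@dataclass
class ProbeGroup:
    """A set of same-gene probes averaged into one collapsed row."""

    gene: str
    members: list[str]
    collapsed_id: str


def _clique_groups(members: list[str], corr: pd.DataFrame, r_threshold: float) -> list[list[str]]:
    """Partition ``members`` into groups that are cliques of the r>threshold graph.

    Greedy: repeatedly take the largest maximal clique of the remaining
    subgraph (ties broken lexicographically on the sorted member tuple).
    """
    g = nx.Graph()
    g.add_nodes_from(members)
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if corr.loc[a, b] > r_threshold:
                g.add_edge(a, b)
    groups: list[list[str]] = []
    remaining = g
    while remaining.number_of_nodes():
        cliques = [sorted(c) for c in nx.find_cliques(remaining)]
        cliques.sort(key=lambda c: (-len(c), tuple(c)))
        best = cliques[0]
        groups.append(best)
        remaining = remaining.subgraph(
            [n for n in remaining.nodes if n not in set(best)]
        ).copy()
    return groups


def collapse_probes(
    x: ExpressionMatrix,
    ann: FeatureAnnotation,
    r_threshold: float = 0.4,
) -> tuple[ExpressionMatrix, list[ProbeGroup]]:
    """Average same-gene probes whose pairwise Pearson r exceeds the gate.

    Returns the collapsed matrix (collapsed rows replace their members at
    the position of the first member; all other rows unchanged) and the
    list of multi-probe groups that were averaged.
    """
    if not (-1.0 < r_threshold < 1.0):
        raise ValueError("r_threshold must lie in (-1, 1)")
    by_gene: dict[str, list[str]] = {}
    for f in x.feature_ids:
        gene = ann.gene_of(f)
        if gene is not None:
            by_gene.setdefault(gene, []).append(f)

    replaces: dict[str, tuple[str, list[str]]] = {}  # first member -> (new id, members)
    drop: set = set()
    groups: list[ProbeGroup] = []
    data = x.data
    row_order = {f: i for i, f in enumerate(x.feature_ids)}
    for gene in sorted(by_gene):
        members = by_gene[gene]
        if len(members) < 2:
            continue
        variances = data.loc[members].var(axis=1, ddof=1)
        usable = [m for m in members if variances[m] > 0]
        for m in members:
            if variances[m] == 0:
                logger.info(
                    "collapse_probes: zero-variance probe %s (gene %s) passes through",
                    m,
                    gene,
                )
        if len(usable) < 2:
            continue
        corr = data.loc[usable].T.corr()
        gi = 0
        for grp in _clique_groups(usable, corr, r_threshold):
            if len(grp) < 2:
                continue
            gi += 1
            cid = f"{gene}__g{gi}"
            first = min(grp, key=row_order.__getitem__)
            replaces[first] = (cid, grp)
            drop.update(set(grp) - {first})
            groups.append(ProbeGroup(gene=gene, members=sorted(grp), collapsed_id=cid))

    rows = []
    index = []
    for f in x.feature_ids:
        if f in drop:
            continue
        if f in replaces:
            cid, grp = replaces[f]
            rows.append(data.loc[grp].mean(axis=0))
            index.append(cid)
        else:
            rows.append(data.loc[f])
            index.append(f)
    collapsed = pd.DataFrame(rows, index=index)
    collapsed.columns = data.columns
    return ExpressionMatrix(collapsed, x.dataset_name), groups


def expand_to_probes(features: set[str], groups: list[ProbeGroup]) -> frozenset:
    """Map collapsed ids back to their original probe ids."""
    mapping = {g.collapsed_id: g.members for g in groups}
    out: set = set()
    for f in features:
        out.update(mapping.get(f, [f]))
    return frozenset(out)


def take_union(cluster_sets: list[list[set]]) -> list[str]:
    """Union of all cluster member sets across datasets, sorted.

    Clusters are expected in original (pre-collapse) feature ids; the
    result is the candidate universe for consensus clustering.
    """
    out: set = set()
    for clusters in cluster_sets:
        for c in clusters:
            out |= set(c)
    return sorted(out)
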