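"""Cross-dataset cluster intersection and the meta-consensus step.

For one algorithm, every combination of one cluster per dataset is
intersected (the record count is exactly the product of per-dataset
cluster counts); records with at least ``min_size`` members survive, and
the meta step intersects every surviving k-means record with every
surviving SOM record, keeping de-duplicated member sets of at least
``min_size`` — the candidate conserved signatures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .consensus import Partition

__all__ = ["IntersectionRecord", "all_intersections", "filter_by_size", "meta_consensus"]


@dataclass
class IntersectionRecord:
    """One cluster-per-dataset intersection (or a meta-consensus set)."""

    algorithm: str
    cluster_tuple: tuple[int, ...] | None
    members: frozenset
    name: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


def all_intersections(
    partitions: dict[str, Partition], algorithm: str = ""
) -> list[IntersectionRecord]:
    """All Cartesian-product intersections of clusters across datasets.

    Returns one record per element of the product of per-dataset cluster
    label sets (empty member sets included, so ``len(result)`` equals
    the product of cluster counts).  A feature missing from any
    dataset's partition belongs to no cluster there and therefore to no
    intersection.
    """
    datasets = sorted(partitions)
    per_ds_clusters = {ds: partitions[ds].clusters() for ds in datasets}
    label_sets = [sorted(per_ds_clusters[ds]) for ds in datasets]

    # brute-force-friendly construction: group features by their label tuple
    shared = None
    for ds in datasets:
        ids = set(partitions[ds].item_ids)
        shared = ids if shared is None else (shared & ids)
    label_of = {
        ds: dict(zip(partitions[ds].item_ids, partitions[ds].labels))
        for ds in datasets
    }
    by_tuple: dict[tuple[int, ...], set] = {}
    for f in shared or set():
        key = tuple(int(label_of[ds][f]) for ds in datasets)
        by_tuple.setdefault(key, set()).add(f)

    records = []
    for combo in itertools.product(*label_sets):
        members = frozenset(by_tuple.get(tuple(combo), frozenset()))
        name = "x".join(f"{ds}.C{lab}" for ds, lab in zip(datasets, combo))
        records.append(
            IntersectionRecord(
                algorithm=algorithm,
                cluster_tuple=tuple(combo),
                members=members,
                name=name,
            )
        )
    return records


def filter_by_size(
    records: list[IntersectionRecord], min_size: int = 10
) -> list[IntersectionRecord]:
    """Keep records with at least ``min_size`` members, order preserved."""
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    return [r for r in records if r.size >= min_size]


def meta_consensus(
    kmeans_records: list[IntersectionRecord],
    som_records: list[IntersectionRecord],
    min_size: int = 10,
) -> list[IntersectionRecord]:
    """Intersect every k-means record with every SOM record.

    Member sets of at least ``min_size`` survive; identical member sets
    are de-duplicated keeping the lexicographically first pair name.
    When the input partitions are true partitions the surviving sets are
    pairwise disjoint (asserted).
    """
    out: dict[frozenset, IntersectionRecord] = {}
    for km in kmeans_records:
        for som in som_records:
            members = km.members & som.members
            if len(members) < min_size:
                continue
            name = f"meta:{km.name}&{som.name}"
            if members in out:
                if name < out[members].name:
                    out[members] = IntersectionRecord(
                        "meta", None, members, name
                    )
            else:
                out[members] = IntersectionRecord("meta", None, members, name)
    records = sorted(out.values(), key=lambda r: r.name)
    seen: set = set()
    for r in records:
        if seen & r.members:
            raise AssertionError(
                "meta-intersections overlap; inputs were not true partitions"
            )
        seen |= r.members
    return records
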