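"""Hypergeometric gene-set enrichment and signature qualification.

A candidate gene set becomes a qualified immune signature when it meets
three criteria: (i) at least half of its members carry at least one term
annotation, (ii) it contains at least ten unique gene symbols, and
(iii) Benjamini–Hochberg FDR over its term enrichment p-values leaves at
least one immunity-flagged term with q below the cutoff (default 0.05).
The enrichment universe is the candidate-generation feature universe,
not the whole array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .dataio import FeatureAnnotation

__all__ = ["SignatureSet", "hypergeometric_test", "enrich_terms", "qualify_signatures"]


@dataclass
class SignatureSet:
    """Named qualified signatures plus the enrichment evidence behind them."""

    signatures: dict[str, frozenset] = field(default_factory=dict)
    enrichment: pd.DataFrame | None = None  # all candidates × terms
    provenance: dict[str, str] = field(default_factory=dict)  # Sig name -> candidate name

    def __len__(self) -> int:
        return len(self.signatures)


def hypergeometric_test(N: int, K: int, n: int, x: int) -> float:
    """Upper-tail P(X ≥ x) for X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` annotated features, ``n`` set size,
    ``x`` observed overlap.
    """
    if not (0 <= x <= min(K, n) <= N) or n > N or K > N:
        raise ValueError(
            f"invalid hypergeometric bounds: N={N}, K={K}, n={n}, x={x}"
        )
    p = float(hypergeom.sf(x - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def enrich_terms(
    members: frozenset | set,
    ann: FeatureAnnotation,
    universe: set[str],
    set_name: str = "",
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of one gene set, BH-adjusted.

    Rows: one per term with any overlap-eligible membership; columns
    follow the (N, K, n, x, p, q) bookkeeping, plus an immune flag.
    """
    uni = set(universe)
    mem = set(members) & uni
    N, n = len(uni), len(mem)
    rows = []
    for term in sorted(ann.term_to_features):
        term_feats = ann.term_to_features[term] & uni
        K = len(term_feats)
        if K == 0:
            continue
        x = len(mem & term_feats)
        p = hypergeometric_test(N, K, n, x)
        rows.append(
            {
                "set_name": set_name,
                "term_id": term,
                "term_label": ann.term_labels.get(term, ""),
                "immune": term in ann.immune_terms,
                "universe_size": N,
                "annotated": K,
                "set_size": n,
                "overlap": x,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_q"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["fdr_q"] = pd.Series(dtype=float)
    return df


def qualify_signatures(
    candidates: dict[str, frozenset],
    ann: FeatureAnnotation,
    universe: set[str],
    fdr_cut: float = 0.05,
    min_annotated_frac: float = 0.5,
    min_symbols: int = 10,
) -> SignatureSet:
    """Apply the three qualification criteria to candidate gene sets.

    Qualified signatures are renamed ``Sig01..SigM`` in order of their
    best immune-term q-value (ties broken by candidate name), so output
    naming is invariant to candidate input order.
    """
    if not candidates:
        raise ValueError("no candidate sets supplied")
    if not ann.term_to_features:
        raise ValueError("empty annotation")
    annotated = ann.annotated_features()

    tables = []
    accepted: list[tuple[float, str, frozenset]] = []
    for name in sorted(candidates):
        members = frozenset(candidates[name])
        table = enrich_terms(members, ann, universe, set_name=name)
        tables.append(table)
        if not len(members):
            continue
        frac = len(members & annotated) / len(members)
        if frac < min_annotated_frac:
            continue
        symbols = {ann.gene_of(f) for f in members if ann.gene_of(f) is not None}
        if len(symbols) < min_symbols:
            continue
        imm = table[table["immune"]]
        if not len(imm) or imm["fdr_q"].min() >= fdr_cut:
            continue
        accepted.append((float(imm["fdr_q"].min()), name, members))

    accepted.sort(key=lambda t: (t[0], t[1]))
    signatures = {
        f"Sig{i + 1:02d}": members for i, (_, _, members) in enumerate(accepted)
    }
    provenance = {
        f"Sig{i + 1:02d}": name for i, (_, name, _) in enumerate(accepted)
    }
    enrichment = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    return SignatureSet(
        signatures=signatures, enrichment=enrichment, provenance=provenance
    )
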