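"""Leukocyte-group enrichment scores from a reference expression panel.

For each feature, a one-way group-means model is fitted across the
panel's cell-type groups (18 leukocyte subsets by default); every
ordered group pair gets a contrast coefficient (difference of group
means) and a two-sided t p-value using the pooled residual variance.
The enrichment score of a feature in group g is the sum of its
coefficients against all other groups that pass Bonferroni-corrected
significance (alpha over the 153 unordered pairs for 18 groups).
Signature profiles are mean member scores per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, logger
from .enrichment import SignatureSet

__all__ = [
    "ReferencePanel",
    "CellEnrichmentProfile",
    "pairwise_contrasts",
    "enrichment_scores",
    "profile_signatures",
]


@dataclass
class ReferencePanel:
    """Reference expression matrix with a sample → cell-type-group map."""

    expression: ExpressionMatrix
    sample_to_group: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unmapped = [s for s in self.expression.sample_ids if s not in self.sample_to_group]
        if unmapped:
            raise ValueError(f"samples without a group: {unmapped[:5]}")
        if not self.groups:
            seen: list[str] = []
            for s in self.expression.sample_ids:
                g = self.sample_to_group[s]
                if g not in seen:
                    seen.append(g)
            self.groups = seen
        for g in self.groups:
            n = sum(1 for s in self.expression.sample_ids if self.sample_to_group[s] == g)
            if n < 2:
                raise ValueError(f"group {g!r} has {n} sample(s); at least 2 required")

    def group_columns(self) -> dict[str, list[str]]:
        cols: dict[str, list[str]] = {g: [] for g in self.groups}
        for s in self.expression.sample_ids:
            cols[self.sample_to_group[s]].append(s)
        return cols


@dataclass
class CellEnrichmentProfile:
    """Per-feature, per-group summed-coefficient enrichment scores."""

    scores: pd.DataFrame  # features × groups
    alpha: float
    n_contrasts_corrected: int


def _group_stats(
    panel: ReferencePanel, features: list[str]
) -> tuple[pd.DataFrame, pd.Series, np.ndarray, int]:
    """Group means, pooled residual variance and group sizes per feature."""
    cols = panel.group_columns()
    data = panel.expression.data.loc[features]
    means = pd.DataFrame(
        {g: data[cols[g]].mean(axis=1) for g in panel.groups}
    )
    n_g = np.array([len(cols[g]) for g in panel.groups])
    n_total = int(n_g.sum())
    df_resid = n_total - len(panel.groups)
    ss = pd.Series(0.0, index=features)
    for g in panel.groups:
        block = data[cols[g]]
        ss += ((block.sub(means[g], axis=0)) ** 2).sum(axis=1)
    pooled_var = ss / df_resid
    return means, pooled_var, n_g, df_resid


def pairwise_contrasts(
    panel: ReferencePanel, feature: str
) -> dict[tuple[str, str], tuple[float, float]]:
    """All ordered pairwise group contrasts for one feature.

    Coefficient is the difference of group means; the p-value comes from
    a two-sided t statistic with the pooled residual variance of the
    one-way group-means model (shared across all contrasts of the
    feature).  Antisymmetric: coefficient(g, h) = −coefficient(h, g).
    """
    if feature not in panel.expression.data.index:
        raise ValueError(f"feature {feature!r} not in the panel")
    means, pooled_var, n_g, df_resid = _group_stats(panel, [feature])
    mu = means.loc[feature]
    s2 = float(pooled_var.loc[feature])
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, g in enumerate(panel.groups):
        for j, h in enumerate(panel.groups):
            if g == h:
                continue
            coef = float(mu[g] - mu[h])
            se2 = s2 * (1.0 / n_g[i] + 1.0 / n_g[j])
            if se2 == 0.0:
                p = 0.0 if coef != 0.0 else 1.0
                logger.info(
                    "pairwise_contrasts: zero residual variance for %s", feature
                )
            else:
                t = coef / np.sqrt(se2)
                p = float(2.0 * stats.t.sf(abs(t), df_resid))
            out[(g, h)] = (coef, p)
    return out


def enrichment_scores(
    panel: ReferencePanel,
    features: list[str] | set[str] | None = None,
    alpha: float = 0.05,
) -> CellEnrichmentProfile:
    """Summed significant contrast coefficients per (feature, group).

    The Bonferroni family is the set of unordered group pairs of one
    feature (153 pairs for 18 groups): a contrast contributes iff its
    p-value is ≤ alpha / n_pairs.
    """
    if features is None:
        feats = panel.expression.feature_ids
    else:
        missing = set(features) - set(panel.expression.feature_ids)
        if missing:
            raise ValueError(f"features absent from panel: {sorted(missing)[:5]}")
        feats = [f for f in panel.expression.feature_ids if f in set(features)]
    G = len(panel.groups)
    n_pairs = G * (G - 1) // 2
    threshold = alpha / n_pairs

    means, pooled_var, n_g, df_resid = _group_stats(panel, feats)
    mu = means.to_numpy()  # F × G
    s2 = pooled_var.to_numpy()[:, None, None]
    coef = mu[:, :, None] - mu[:, None, :]  # F × G × G, coef[f, g, h]
    se2 = s2 * (1.0 / n_g[None, :, None] + 1.0 / n_g[None, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se2 > 0, coef / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    degenerate = se2 == 0.0
    if degenerate.any():
        pvals = np.where(degenerate & (coef != 0), 0.0, pvals)
        pvals = np.where(degenerate & (coef == 0), 1.0, pvals)
    sig = pvals <= threshold
    np.einsum("fgg->fg", sig)[:] = False  # self-contrasts never contribute
    scores = (coef * sig).sum(axis=2)
    return CellEnrichmentProfile(
        scores=pd.DataFrame(scores, index=feats, columns=panel.groups),
        alpha=alpha,
        n_contrasts_corrected=n_pairs,
    )


def profile_signatures(
    profile: CellEnrichmentProfile, signatures: SignatureSet
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean member score per (signature, group), plus a row-standardized copy."""
    rows = {}
    for name, members in signatures.signatures.items():
        present = [f for f in members if f in profile.scores.index]
        if not present:
            logger.info("profile_signatures: %s has no scored members", name)
            rows[name] = pd.Series(np.nan, index=profile.scores.columns)
            continue
        rows[name] = profile.scores.loc[present].mean(axis=0)
    prof = pd.DataFrame(rows).T
    prof.columns = profile.scores.columns
    sd = prof.std(axis=1).replace(0, np.nan)
    zprof = prof.sub(prof.mean(axis=1), axis=0).div(sd, axis=0)
    return prof, zprof
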