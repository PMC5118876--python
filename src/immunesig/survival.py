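"""Metagene construction, metagene dendrograms and Cox survival analysis.

A metagene collapses a signature to one value per sample in two steps:
probe sets sharing a gene symbol are averaged first (so no gene is
over-represented), then the per-gene values and the remaining
symbol-less probe values are averaged.  Each metagene is tested as a
continuous covariate in a univariate Cox proportional-hazards model
with Efron handling of tied event times, overall and within strata
(categorical levels or tertiles of a continuous stratifier such as a
proliferation metagene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.cluster.hierarchy import average, leaves_list, to_tree
from scipy.spatial.distance import squareform

from .dataio import ClinicalTable, ExpressionMatrix, FeatureAnnotation, logger
from .enrichment import SignatureSet

__all__ = [
    "MetageneTable",
    "MetageneTree",
    "SurvivalReport",
    "compute_metagenes",
    "metagene_dendrogram",
    "cox_univariate",
    "stratified_survival",
    "significance_stars",
    "tertile_bins",
]


@dataclass
class MetageneTable:
    """Signatures × samples metagene matrix for one dataset."""

    data: pd.DataFrame
    dataset: str = ""


@dataclass
class MetageneTree:
    """Average-linkage tree over metagenes (distance 1 − Pearson r)."""

    linkage: np.ndarray
    names: list[str]

    def leaf_order(self) -> list[str]:
        return [self.names[i] for i in leaves_list(self.linkage)]

    def to_newick(self) -> str:
        root = to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.names[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(root) + ";"


@dataclass
class SurvivalReport:
    """Per-(metagene, stratum) univariate Cox results."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = [
        "metagene",
        "stratum",
        "n",
        "events",
        "hazard_ratio",
        "ci_low",
        "ci_high",
        "p_value",
        "poor_outcome",
        "stars",
    ]


def compute_metagenes(
    x: ExpressionMatrix,
    signatures: SignatureSet,
    ann: FeatureAnnotation,
) -> MetageneTable:
    """Two-step averaging of signature members into per-sample metagenes."""
    rows = {}
    for name, members in signatures.signatures.items():
        present = sorted(set(members) & set(x.data.index))
        dropped = set(members) - set(present)
        if dropped:
            logger.info(
                "compute_metagenes(%s): %d member(s) absent from %s",
                name,
                len(dropped),
                x.dataset_name,
            )
        if not present:
            logger.info("compute_metagenes: %s has no members in %s", name, x.dataset_name)
            continue
        by_gene: dict[str, list[str]] = {}
        loners: list[str] = []
        for f in present:
            gene = ann.gene_of(f)
            if gene is None:
                loners.append(f)
            else:
                by_gene.setdefault(gene, []).append(f)
        parts = [x.data.loc[probes].mean(axis=0) for probes in by_gene.values()]
        parts += [x.data.loc[f] for f in loners]
        rows[name] = pd.concat(parts, axis=1).mean(axis=1)
    table = pd.DataFrame(rows).T
    table.columns = x.sample_ids
    return MetageneTable(table, x.dataset_name)


def metagene_dendrogram(m: MetageneTable) -> MetageneTree:
    """Average-linkage tree on 1 − Pearson r between metagene rows."""
    if m.data.shape[0] < 2:
        raise ValueError("at least 2 metagenes required")
    sd = m.data.std(axis=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant metagene row: {constant.index[0]!r}")
    corr = np.corrcoef(m.data.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    return MetageneTree(linkage=link, names=list(m.data.index))


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def cox_univariate(
    values: pd.Series,
    clin: ClinicalTable,
    standardize: bool = False,
    label: str = "metagene",
    stratum: str = "All",
) -> dict:
    """Univariate Cox PH fit of survival on one metagene (Efron ties).

    Returns one report row: hazard ratio per 1-unit metagene, Wald 95 %
    CI and p-value; ``poor_outcome`` flags hazard ratio > 1 (inverse
    association).
    """
    common = [s for s in values.index if s in set(clin.sample_ids)]
    if not common:
        raise ValueError("no samples shared between metagene and clinical table")
    v = values.loc[common].astype(float)
    if standardize:
        v = (v - v.mean()) / v.std()
    df = pd.DataFrame(
        {
            "time": clin.data.loc[common, "time"].astype(float),
            "event": clin.data.loc[common, "event"].astype(int),
            "mg": v,
        }
    )
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events in the survival data")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event",
            fit_options={"precision": 1e-10})
    summ = cph.summary.loc["mg"]
    hr = float(np.exp(summ["coef"]))
    return {
        "metagene": label,
        "stratum": stratum,
        "n": len(df),
        "events": n_events,
        "hazard_ratio": hr,
        "ci_low": float(np.exp(summ["coef lower 95%"])),
        "ci_high": float(np.exp(summ["coef upper 95%"])),
        "p_value": float(summ["p"]),
        "poor_outcome": hr > 1.0,
        "stars": significance_stars(float(summ["p"])),
    }


def cox_beta(
    values: pd.Series, clin: ClinicalTable, ties: str = "efron"
) -> float:
    """Point estimate of the Cox coefficient under a chosen tie method.

    Both tie methods go through scikit-survival's Newton solver (tight
    tolerance, no standard errors) so that Efron-vs-Breslow comparisons
    isolate the tie-handling term; the full inferential fit lives in
    :func:`cox_univariate`.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    common = [s for s in values.index if s in set(clin.sample_ids)]
    if not common:
        raise ValueError("no samples shared between metagene and clinical table")
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    y = np.array(
        [
            (bool(clin.data.loc[s, "event"]), float(clin.data.loc[s, "time"]))
            for s in common
        ],
        dtype=[("event", bool), ("time", float)],
    )
    est = CoxPHSurvivalAnalysis(alpha=0.0, ties=ties, n_iter=200, tol=1e-12)
    est.fit(values.loc[common].to_numpy()[:, None], y)
    return float(est.coef_[0])


def tertile_bins(values: pd.Series) -> pd.Series:
    """low/med/high tertile labels by sample quantiles, ties to the lower bin."""
    v = values.astype(float)
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    labels = pd.Series("high", index=v.index)
    labels[v <= q2] = "med"
    labels[v <= q1] = "low"
    return labels


def stratified_survival(
    m: MetageneTable,
    clin: ClinicalTable,
    strata_spec: list[tuple[str, str]] | None = None,
    standardize: bool = False,
) -> SurvivalReport:
    """Univariate Cox per (metagene, stratum).

    ``strata_spec`` entries are ``(column, mode)`` with mode ``levels``
    (each category is a stratum) or ``tertiles`` (continuous column
    binned to low/med/high).  The unstratified "All" rows are always
    included.  A stratum with no events is reported with missing
    estimates rather than dropped.
    """
    strata_spec = strata_spec or []
    strata: list[tuple[str, pd.Index]] = [("All", clin.data.index)]
    for column, mode in strata_spec:
        if column not in clin.data.columns:
            raise ValueError(f"stratum column {column!r} missing from clinical table")
        col = clin.data[column]
        if mode == "tertiles":
            bins = tertile_bins(col)
            for level in ("low", "med", "high"):
                strata.append((f"{column} ({level})", bins.index[bins == level]))
        elif mode == "levels":
            for level in sorted(col.dropna().unique().astype(str)):
                strata.append(
                    (f"{column} = {level}", col.index[col.astype(str) == level])
                )
        else:
            raise ValueError(f"unknown stratum mode {mode!r}")

    rows = []
    for name in m.data.index:
        values = m.data.loc[name]
        for label, samples in strata:
            sub = clin.data.loc[clin.data.index.intersection(samples)]
            try:
                subclin = ClinicalTable(sub, time_unit=clin.time_unit)
                row = cox_univariate(
                    values, subclin, standardize=standardize,
                    label=name, stratum=label,
                )
            except ValueError as err:  # degenerate stratum: report, do not drop
                logger.info(
                    "stratified_survival: %s / %s: %s", name, label, err
                )
                row = {
                    "metagene": name,
                    "stratum": label,
                    "n": len(sub),
                    "events": int(sub["event"].sum()) if len(sub) else 0,
                    "hazard_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "poor_outcome": False,
                    "stars": "",
                }
            rows.append(row)
    return SurvivalReport(pd.DataFrame(rows, columns=SurvivalReport.COLUMNS))
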