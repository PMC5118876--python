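"""End-to-end orchestration: simulate/load → signatures → survival.

The pipeline is staged and fully seeded; given the same configuration
and seed it writes byte-identical primary outputs.  Configuration is a
plain mapping (YAML-friendly).  Two input modes exist: ``simulate``
(the synthetic study with planted ground truth) and ``inputs`` (paths
to user-supplied matrices, annotation, reference panel and clinical
tables).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import (
    cellscores,
    consensus as cc,
    dataio,
    enrichment,
    intersect,
    preprocess,
    stability,
    survival as surv,
    synthetic,
)
from .dataio import ClinicalTable, ExpressionMatrix, FeatureAnnotation, logger

__all__ = ["default_config", "run_pipeline", "PipelineResult", "jaccard"]


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def default_config() -> dict:
    """Desk-scale defaults: the planted five-dataset synthetic study."""
    return {
        "seed": 0,
        "simulate": {
            "n_datasets": 5,
            "n_samples": 150,
            "n_conserved": 3,
            "n_private": 2,
            "module_size": 40,
            "n_background": 300,
            "noise_sd": 0.6,
            "annotation": {"n_decoy_terms": 50},
            "reference_panel": {"effect": 2.0, "noise_sd": 0.5},
            "survival": {
                "betas": {"CM1": -0.5, "CM2": 0.0, "CM3": 0.3},
                "baseline_rate": 0.2,
                "censor_rate": 0.1,
            },
        },
        "stages": {
            "collapse": {"enabled": True, "r_threshold": 0.4},
            "stability": {
                "n_iterations": 100,
                "sample_fraction": 0.5,
                "retention": 75,
                "min_cluster_size": 10,
                "corr_cut": 0.4,
                "p_cut": 0.001,
            },
            "consensus": {
                "k_min": 2,
                "k_max": 8,
                "n_resamples": 100,
                "item_fraction": 0.8,
                "consensus_floor": 0.8,
                "k_override": {},
            },
            "intersect": {"min_size": 10},
            "qualify": {
                "fdr": 0.05,
                "min_annotated_frac": 0.5,
                "min_symbols": 10,
            },
            "cellscore": {"enabled": True, "alpha": 0.05},
            "survival": {"enabled": True, "strata": [], "standardize": False},
        },
    }


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    config: dict
    datasets: list[ExpressionMatrix] = field(default_factory=list)
    annotation: FeatureAnnotation | None = None
    truth: synthetic.SimTruth | None = None
    panel: cellscores.ReferencePanel | None = None
    clinical: dict[str, ClinicalTable] = field(default_factory=dict)
    stable: dict[str, stability.StableClusterSet] = field(default_factory=dict)
    immune_flags: dict[str, set] = field(default_factory=dict)
    union_features: list[str] = field(default_factory=list)
    consensus_results: dict = field(default_factory=dict)
    selected_k: dict = field(default_factory=dict)
    partitions: dict = field(default_factory=dict)
    records: dict = field(default_factory=dict)
    meta_records: list = field(default_factory=list)
    signatures: enrichment.SignatureSet | None = None
    cell_profile: cellscores.CellEnrichmentProfile | None = None
    signature_profiles: pd.DataFrame | None = None
    metagenes: dict[str, surv.MetageneTable] = field(default_factory=dict)
    survival_reports: dict[str, surv.SurvivalReport] = field(default_factory=dict)
    outdir: Path | None = None

    def recovery_jaccards(self) -> dict[str, float]:
        """Best Jaccard of each qualified signature to a planted module."""
        if self.truth is None or self.signatures is None:
            return {}
        out = {}
        for name, members in self.signatures.signatures.items():
            out[name] = max(
                (jaccard(members, mod) for mod in self.truth.conserved_modules.values()),
                default=0.0,
            )
        return out


def _simulate_inputs(cfg: dict, seed: int, res: PipelineResult) -> None:
    sim = cfg["simulate"]
    keys = (
        "n_datasets",
        "n_samples",
        "n_conserved",
        "n_private",
        "module_size",
        "n_background",
        "noise_sd",
    )
    matrices, truth = synthetic.simulate_datasets(
        **{k: sim[k] for k in keys if k in sim}, seed=seed
    )
    ann = synthetic.simulate_annotation(
        truth, seed=seed, **sim.get("annotation", {})
    )
    panel_x, sample_to_group, _markers = synthetic.simulate_reference_panel(
        seed=seed, truth=truth, **sim.get("reference_panel", {})
    )
    res.datasets = matrices
    res.truth = truth
    res.annotation = ann
    res.panel = cellscores.ReferencePanel(panel_x, sample_to_group)

    surv_cfg = sim.get("survival")
    if surv_cfg:
        betas = surv_cfg.get("betas", {})
        for i, x in enumerate(matrices):
            mg = pd.DataFrame(
                {
                    mod: truth.factors[(x.dataset_name, mod)]
                    for mod in sorted(truth.conserved_modules)
                },
                index=x.sample_ids,
            ).T
            res.clinical[x.dataset_name] = synthetic.simulate_survival(
                mg,
                betas,
                baseline_rate=surv_cfg.get("baseline_rate", 0.2),
                censor_rate=surv_cfg.get("censor_rate", 0.1),
                seed=seed + 7919 * (i + 1),
            )


def _load_inputs(cfg: dict, res: PipelineResult) -> None:
    inputs = cfg["inputs"]
    res.datasets = [
        dataio.read_expression(d["path"], d.get("name", ""))
        for d in inputs["datasets"]
    ]
    ann_cfg = inputs.get("annotation")
    if ann_cfg is None:
        raise ValueError("stability stage: missing annotation input")
    terms = dataio.read_gene_sets(ann_cfg["terms_gmt"])
    symbols = {}
    if "symbols_tsv" in ann_cfg:
        tab = pd.read_csv(ann_cfg["symbols_tsv"], sep="\t", index_col=0)
        symbols = tab.iloc[:, 0].astype(str).to_dict()
    immune = set()
    if "immune_terms" in ann_cfg:
        immune = set(
            Path(ann_cfg["immune_terms"]).read_text().split()
        )
    res.annotation = FeatureAnnotation(
        feature_to_gene=symbols,
        term_to_features={t: frozenset(m) for t, m in terms.items()},
        immune_terms=frozenset(immune),
    )
    panel_cfg = inputs.get("reference_panel")
    if panel_cfg:
        panel_x = dataio.read_expression(panel_cfg["path"], "reference_panel")
        gm = pd.read_csv(panel_cfg["group_map"], sep="\t", index_col=0)
        res.panel = cellscores.ReferencePanel(
            panel_x, gm.iloc[:, 0].astype(str).to_dict()
        )
    for entry in inputs.get("clinical", []):
        res.clinical[entry["dataset"]] = dataio.read_clinical(
            entry["path"], entry.get("time_unit", "years")
        )


def run_pipeline(
    config: Mapping[str, Any] | None = None,
    outdir: str | Path | None = None,
    write_plots: bool = False,
) -> PipelineResult:
    """Run every enabled stage and (optionally) write per-stage outputs."""
    cfg = _merge(default_config(), config or {})
    if "inputs" in cfg and config and "inputs" in config:
        cfg.pop("simulate", None)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    res = PipelineResult(config=cfg)

    if "inputs" in cfg:
        _load_inputs(cfg, res)
    else:
        _simulate_inputs(cfg, seed, res)

    if stages["survival"]["enabled"] and not res.clinical:
        raise ValueError("survival stage: no clinical table configured")
    if stages["cellscore"]["enabled"] and res.panel is None:
        raise ValueError("cellscore stage: no reference panel configured")

    ann = res.annotation
    # --- probe collapsing -------------------------------------------------
    collapsed: list[ExpressionMatrix] = []
    probe_groups: dict[str, list[preprocess.ProbeGroup]] = {}
    if stages["collapse"]["enabled"]:
        for x in res.datasets:
            cx, groups = preprocess.collapse_probes(
                x, ann, r_threshold=stages["collapse"]["r_threshold"]
            )
            collapsed.append(cx)
            probe_groups[x.dataset_name] = groups
    else:
        collapsed = list(res.datasets)
        probe_groups = {x.dataset_name: [] for x in res.datasets}

    # --- stability filtering + immune flagging ----------------------------
    st = stages["stability"]
    immune_sets_per_ds: list[list[set]] = []
    for x in collapsed:
        stable = stability.stability_filter(
            x,
            n_iterations=st["n_iterations"],
            sample_fraction=st["sample_fraction"],
            retention=st["retention"],
            seed=seed,
            min_cluster_size=st["min_cluster_size"],
            corr_cut=st["corr_cut"],
        )
        res.stable[x.dataset_name] = stable
        flags = stability.flag_immune_clusters(
            stable, ann, p_cut=st["p_cut"], universe=set(x.feature_ids)
        )
        res.immune_flags[x.dataset_name] = flags
        # back to original probe ids before taking the cross-dataset union
        expanded = [
            set(preprocess.expand_to_probes(
                set(stable.clusters[cid]), probe_groups[x.dataset_name]
            ))
            for cid in sorted(flags)
        ]
        immune_sets_per_ds.append(expanded)
    res.union_features = preprocess.take_union(immune_sets_per_ds)
    if not res.union_features:
        raise ValueError("consensus stage: no immune-flagged stable clusters found")

    # --- consensus clustering ---------------------------------------------
    co = stages["consensus"]
    k_range = list(range(co["k_min"], co["k_max"] + 1))
    algorithms = ("kmeans", "som")
    for x in res.datasets:
        sub = x.subset_features(res.union_features)
        for alg in algorithms:
            results = cc.consensus_cluster(
                sub,
                algorithm=alg,
                k_range=k_range,
                n_resamples=co["n_resamples"],
                item_fraction=co["item_fraction"],
                seed=seed + (1 if alg == "som" else 0),
            )
            res.consensus_results[(x.dataset_name, alg)] = results
            k_sel = co.get("k_override", {}).get(x.dataset_name) or cc.select_k(
                results, consensus_floor=co["consensus_floor"]
            )
            res.selected_k[(x.dataset_name, alg)] = k_sel
            res.partitions[(x.dataset_name, alg)] = results[
                k_sel
            ].consensus_partition

    # --- intersections and meta-consensus ---------------------------------
    mi = stages["intersect"]
    filtered: dict[str, list] = {}
    for alg in algorithms:
        parts = {
            ds: res.partitions[(ds, alg)]
            for ds in [x.dataset_name for x in res.datasets]
        }
        records = intersect.all_intersections(parts, algorithm=alg)
        res.records[alg] = records
        filtered[alg] = intersect.filter_by_size(records, min_size=mi["min_size"])
    res.meta_records = intersect.meta_consensus(
        filtered["kmeans"], filtered["som"], min_size=mi["min_size"]
    )

    # --- qualification -----------------------------------------------------
    qa = stages["qualify"]
    candidates = {r.name: r.members for r in res.meta_records}
    if not candidates:
        logger.info("qualification: no meta-intersections survived")
        res.signatures = enrichment.SignatureSet()
    else:
        res.signatures = enrichment.qualify_signatures(
            candidates,
            ann,
            universe=set(res.union_features),
            fdr_cut=qa["fdr"],
            min_annotated_frac=qa["min_annotated_frac"],
            min_symbols=qa["min_symbols"],
        )

    # --- cell-type enrichment scores ---------------------------------------
    if stages["cellscore"]["enabled"] and len(res.signatures):
        members = sorted(
            set().union(*res.signatures.signatures.values())
            & set(res.panel.expression.feature_ids)
        )
        if members:
            res.cell_profile = cellscores.enrichment_scores(
                res.panel, members, alpha=stages["cellscore"]["alpha"]
            )
            res.signature_profiles, _ = cellscores.profile_signatures(
                res.cell_profile, res.signatures
            )

    # --- metagenes and survival --------------------------------------------
    if len(res.signatures):
        for x in res.datasets:
            res.metagenes[x.dataset_name] = surv.compute_metagenes(
                x, res.signatures, ann
            )
        if stages["survival"]["enabled"]:
            sv = stages["survival"]
            for x in res.datasets:
                clin = res.clinical.get(x.dataset_name)
                if clin is None:
                    raise ValueError(
                        f"survival stage: missing clinical table for {x.dataset_name}"
                    )
                res.survival_reports[x.dataset_name] = surv.stratified_survival(
                    res.metagenes[x.dataset_name],
                    clin,
                    strata_spec=[tuple(s) for s in sv.get("strata", [])],
                    standardize=sv.get("standardize", False),
                )

    if outdir is not None:
        res.outdir = Path(outdir)
        _write_outputs(res, write_plots=write_plots)
    return res


def _write_outputs(res: PipelineResult, write_plots: bool = False) -> None:
    out = res.outdir
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "params.json", "w") as fh:
        json.dump(res.config, fh, indent=2, sort_keys=True, default=str)

    for ds, stable in res.stable.items():
        rows = [
            {"cluster": cid, "feature": f, "immune_flagged": cid in res.immune_flags[ds]}
            for cid in sorted(stable.clusters)
            for f in sorted(stable.clusters[cid])
        ]
        pd.DataFrame(rows).to_csv(out / f"stable_clusters_{ds}.tsv", sep="\t", index=False)
        counts = pd.DataFrame(
            [
                {"feature": f, "cluster": c, "count": n}
                for (f, c), n in sorted(stable.selection_counts.items())
            ]
        )
        counts.to_csv(out / f"selection_counts_{ds}.tsv", sep="\t", index=False)
    (out / "union_features.txt").write_text("\n".join(res.union_features) + "\n")

    summary_rows = []
    for (ds, alg), results in res.consensus_results.items():
        for k, r in results.items():
            summary_rows.append(
                {
                    "dataset": ds,
                    "algorithm": alg,
                    "k": k,
                    "mean_cluster_consensus": r.mean_cluster_consensus,
                    "selected": k == res.selected_k[(ds, alg)],
                }
            )
    pd.DataFrame(summary_rows).to_csv(out / "consensus_summary.tsv", sep="\t", index=False)
    for (ds, alg), k in res.selected_k.items():
        r = res.consensus_results[(ds, alg)][k]
        pd.DataFrame(r.consensus, index=r.item_ids, columns=r.item_ids).to_csv(
            out / f"consensus_{ds}_{alg}_k{k}.tsv", sep="\t", float_format="%.6g"
        )
        if write_plots:
            from .plotting import consensus_heatmap

            consensus_heatmap(r, out / f"consensus_{ds}_{alg}_k{k}.png")

    for alg, records in res.records.items():
        rows = [
            {"name": r.name, "size": r.size, "members": ";".join(sorted(r.members))}
            for r in records
            if r.size > 0
        ]
        pd.DataFrame(rows).to_csv(out / f"intersections_{alg}.tsv", sep="\t", index=False)
    dataio.write_gene_sets(
        {r.name: r.members for r in res.meta_records},
        out / "meta_intersections.gmt",
    )
    if res.signatures is not None:
        dataio.write_gene_sets(
            res.signatures.signatures,
            out / "signatures.gmt",
            descriptions=res.signatures.provenance,
        )
        if res.signatures.enrichment is not None and len(res.signatures.enrichment):
            res.signatures.enrichment.to_csv(
                out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
            )
    if res.cell_profile is not None:
        res.cell_profile.scores.to_csv(
            out / "cell_scores.tsv", sep="\t", float_format="%.6g"
        )
    if res.signature_profiles is not None:
        res.signature_profiles.to_csv(
            out / "signature_profiles.tsv", sep="\t", float_format="%.6g"
        )
    for ds, mg in res.metagenes.items():
        mg.data.to_csv(out / f"metagenes_{ds}.tsv", sep="\t", float_format="%.17g")
        if mg.data.shape[0] >= 2:
            tree = surv.metagene_dendrogram(mg)
            (out / f"dendrogram_{ds}.nwk").write_text(tree.to_newick() + "\n")
    for ds, report in res.survival_reports.items():
        report.table.to_csv(
            out / f"survival_{ds}.tsv", sep="\t", index=False, float_format="%.17g"
        )
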