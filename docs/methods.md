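# Methods

`immunesig` discovers gene signatures of tumor-infiltrating immune cells
de novo from multiple tumor expression datasets, on the premise that an
infiltrating immune population leaves a co-expression footprint whose
*correlation structure* — not its expression level — is conserved across
anatomically unrelated tumors. The pipeline therefore never compares
expression values across datasets; it compares cluster memberships.

## Pipeline

1. **Probe collapsing.** Probe sets mapping to the same gene symbol are
   averaged only when they co-vary: probes are partitioned into maximal
   cliques of the probe–probe graph with edges at Pearson r > 0.4
   (greedy largest-clique-first, ties broken lexicographically), and each
   clique is replaced by its arithmetic mean row. The clique rule
   guarantees that every averaged pair satisfies the r > 0.4 gate; the
   alternative — gating on the mean correlation to a template profile —
   would admit pairs below the gate and is not used. Collapsing is
   per-dataset (groups may differ between datasets); downstream set
   operations return to original probe identifiers.

2. **Stable pattern extraction.** Patterns are extracted by
   average-linkage hierarchical clustering on distance 1 − r, cutting
   the tree at height 1 − `corr_cut` (default 0.4) and discarding
   clusters below `min_cluster_size` (default 10). The extractor is
   pluggable (`stability_filter(extractor=...)`): any callable mapping
   an expression matrix to clusters can stand in, so a different
   pattern-extraction engine can be dropped in without touching the
   stability protocol. That protocol is fixed: draw 50 % of samples
   without replacement, re-extract, match each resampled cluster to the
   full-data reference cluster of maximal Jaccard overlap (ties to the
   smaller reference id), and count per-feature selections; features
   selected in ≥ `retention` of `n_iterations` draws (750/1000 at full
   scale; 75/100 in the desk-scale runs here) are retained in their most
   frequent cluster. Clusters are then flagged as immune when their
   minimum hypergeometric enrichment p over immunity-flagged terms is
   below 0.001, and the union of immune-flagged cluster members across
   datasets forms the candidate universe.

3. **Consensus clustering.** Within each dataset the candidate features
   are z-scored per feature and consensus-clustered with two base
   algorithms: k-means (k-means++ with 10 restarts) and a 1×k
   line-topology self-organizing map trained online with a Gaussian
   neighborhood decaying geometrically over 25 epochs (nodes initialized
   at quantiles of the first principal component; an empty node is
   re-seeded at the item farthest from its assigned node). Per resample,
   80 % of items are drawn without replacement and partitioned; the
   consensus matrix entry for a pair is its co-clustering frequency
   among resamples that sampled both (0 when never co-sampled). The
   final partition at each k cuts the average-linkage tree of
   1 − consensus.

   **Choice of k.** The number of clusters is chosen from the area A(K)
   under the empirical CDF of consensus entries. The textbook rule
   "maximize the relative increase Δ(K)" degenerates at the smallest
   candidate, where Δ is defined as the whole area and therefore always
   wins; we read the rule as an elbow instead: k advances from the
   smallest candidate while the relative area gain is at least
   `delta_min` (default 0.1, i.e. a ≥ 10 % gain justifies a finer
   partition), and the largest k reached whose mean cluster consensus
   meets the floor (default 0.8) is selected. All summary statistics
   (areas, cluster/item consensus) are surfaced, and
   `stages.consensus.k_override` lets a user fix k per dataset by
   inspection. Agreement between the two algorithms is quantified by
   the Hubert–Arabie adjusted Rand index, implemented directly from the
   contingency table (1 for identical partitions, expectation 0 under
   random labeling; degenerate zero-denominator cases return 1).

4. **Meta-intersection.** For each algorithm, every combination of one
   cluster per dataset is intersected — the record count is exactly the
   product of per-dataset cluster counts (e.g. 6,300 for counts
   {5,5,6,6,7} and 4,704 for {4,4,6,7,7}); records with ≥ 10 members
   survive. The meta step intersects every surviving k-means record
   with every surviving SOM record and keeps de-duplicated member sets
   of ≥ 10 — the candidate conserved signatures. When inputs are true
   partitions the outputs are provably pairwise disjoint, which is
   asserted on every run. A feature absent from any dataset's partition
   belongs to no cluster there and hence to no intersection (the
   conservative reading).

5. **Qualification.** A candidate becomes a signature iff (i) ≥ 50 % of
   members carry at least one term annotation, (ii) it contains ≥ 10
   unique gene symbols, and (iii) Benjamini–Hochberg FDR across its
   term family leaves an immunity-flagged term with q < 0.05. The
   enrichment universe is the candidate-generation union set, not the
   whole array, because candidates were drawn from it. Criterion (ii)
   is operationalized on symbols only ("titles" add no independent
   constraint in any annotation source we model). The upper-tail
   hypergeometric test with BH adjustment stands in for web-service
   annotation tools whose EASE-style scores are not reproducible
   offline.

6. **Cell-type enrichment scores.** Against a leukocyte reference panel
   (default layout: 18 purified immune-cell groups, 114 arrays), each
   feature gets a one-way group-means fit; every group pair's contrast
   (difference of group means) receives a two-sided t p-value from the
   pooled residual variance, and the score of feature f in group g sums
   the contrasts of g against all other groups that pass Bonferroni
   significance at α/153 (the unordered-pair family — the narrowest
   family consistent with per-pair testing; the family is switchable).
   The ordinary pooled-variance model replaces a moderated-variance
   (empirical-Bayes) fit, whose hyperparameters are data-dependent; the
   interface accepts a different contrast engine if moderation is
   wanted. Signature profiles are mean member scores per group.

7. **Metagenes and survival.** A signature collapses to one value per
   sample in two steps: same-symbol probes are averaged first (no gene
   is over-represented), then per-gene values and symbol-less probe
   values are averaged. Metagene correlation structure is displayed as
   an average-linkage tree on 1 − r (Newick output). Each metagene is a
   continuous covariate in a univariate Cox proportional-hazards model
   with Efron tie handling; hazard ratios are per 1-unit metagene with
   Wald 95 % intervals (the default of the standard survival stacks),
   and hazard ratio > 1 flags an inverse ("poor outcome") association.
   Metagenes enter raw by default (`--standardize` for cross-dataset
   comparability). Strata are categorical levels or tertiles of a
   continuous stratifier (quantile boundaries, ties to the lower bin —
   deterministic and order-invariant); a stratum without events is
   reported with missing estimates rather than dropped. Significance is
   star-coded p ≤ 0.001 (***), ≤ 0.01 (**), ≤ 0.05 (*).

## Synthetic data

The generator plants the structure the pipeline assumes and nothing
more. Each module is a one-factor model: gene g in module m has value
μ_g + a_g·f + ε with a per-(dataset, module) latent factor f ~ N(0,1)
across samples, loadings a_g uniform on [0.5, 1.5] (heterogeneous but
uniformly positive, as in co-regulated immune transcription; fixed per
gene so the internal correlation pattern travels across datasets), and
ε ~ N(0, noise_sd²). Conserved modules draw independent factors per
dataset — structure, not values, is conserved; private modules are
active in one dataset and pure noise elsewhere; background genes are
noise everywhere; per-gene means uniform on [6, 10] put values on a
log2-intensity-like scale. The annotation gives each conserved module
one immunity-flagged term plus random decoy terms. The reference panel
elevates marker-gene means by `effect` (default 2 log2 units,
noise 0.5) in their group only; its default group sizes are the 18
published leukocyte subsets (114 arrays). Survival times are
exponential with per-sample rate `baseline_rate·exp(Σ β_m z_m)` on
standardized planted factors, censored by an independent exponential —
the simplest mechanism satisfying the non-informative censoring the Cox
model assumes.

What the generator does *not* emulate: probe-level microarray noise
(probe affinity, saturation), batch effects, correlated module factors,
non-proportional hazards, or informative censoring. Passing tests on
this data show the machinery is correct under the model's own
assumptions; they do not show robustness to those artefacts, which the
upstream normalization/batch-correction steps (outside this package's
scope — it consumes normalized matrices) are responsible for removing.

## Study conditions and problem sizes

The planted end-to-end study runs 5 datasets × 150 samples with 3
conserved 40-gene immune modules, 2 private modules per dataset, 300
background genes and noise_sd 0.6; the stability filter uses 100
iterations with retention 75 (the full-scale protocol is 1000/750) and
consensus clustering uses 100 resamples over k = 2..8 (full scale: 500
resamples, k ≤ 10). These desk-scale sizes are the package's reference
conditions: the pipeline recovers exactly the three planted modules as
qualified signatures (Jaccard 1.0) with k = 3 selected for every
dataset and algorithm, and the Cox stage recovers the planted hazard
directions. Cox recovery is validated at n = 500 with β = −0.5 over
100 replicates (mean β̂ within ±0.1, CI coverage 0.90–0.99).

## Numerical choices and conventions

- Consensus diagonal is 1 by definition; a never-co-sampled pair scores
  0 with its zero co-sample count recorded; a singleton cluster's
  cluster consensus is defined as 1.
- Zero-variance probes are excluded from correlation gating and pass
  through collapsing unchanged (logged); zero-variance features are
  left centered (not scaled) in consensus standardization.
- Degenerate contrasts with zero residual variance get p = 0 when means
  differ, else 1 (logged).
- The hypergeometric p is clamped to (0, 1]; BH is applied within each
  candidate's term family.
- `cox_beta` routes both tie methods through one tightly-toleranced
  Newton solver so Efron-vs-Breslow comparisons isolate the tie term;
  the inferential fit (Wald CI, p) uses the Efron likelihood.
- All resampling streams derive per-iteration seeds from (seed, i), so
  stages are individually re-runnable and identical configs give
  byte-identical primary outputs.
- Tertile boundaries use sample quantiles with ties to the lower bin.

## Known limitations

- The pattern extractor is a stand-in with a pluggable interface; its
  defaults (corr_cut 0.4, min size 10) are tuned to the synthetic data,
  and a faithful port of a published extraction engine may group real
  microarray patterns differently.
- The meta step intersects all record pairs; a one-to-one matching
  variant would be stricter and is not implemented.
- k selection is heuristic; for real data, inspect the consensus
  summaries and override k per dataset.
- Enrichment FDR here is BH over an offline term table; web-service
  EASE-based FDRs will not match numerically.
- No multivariate or competing-risk survival models; endpoint choice
  (overall vs progression-free, time units) is configuration.
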