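# immunesig

De novo discovery of immune gene signatures that are conserved across
solid tumor types, from bulk expression data.

Tumors are infiltrated by immune cells, and each infiltrating
population leaves a transcriptional footprint: a set of genes whose
*co-expression structure* recurs in breast, colon, lung, ovarian and
prostate tumors alike, even though absolute expression levels differ.
`immunesig` implements the full discovery pipeline for such signatures
and a survival stage that tests whether they carry prognostic
information. It is aimed at computational biologists who have several
normalized (log2, batch-corrected) tumor expression matrices and want
conserved immune modules, their cell-type attribution, and their
association with patient outcome.

## Method

Per dataset *d*, features are clustered and only resampling-stable
members are kept: patterns are extracted by average-linkage clustering
on 1 − r, the extraction is repeated on random 50 % sample draws, and a
gene is retained when it lands in the same (Jaccard-matched) cluster in
at least 750 of 1000 draws. Clusters hypergeometrically enriched
(p < 0.001) for immunity-related terms contribute their genes to a
candidate universe U (the union across datasets).

Within each dataset, U is consensus-clustered (Monti-style) with two
base algorithms — k-means and a 1×k self-organizing map — over
k = 2..10, subsampling 80 % of items for 500 rounds; the consensus
matrix M(i,j) is the co-clustering frequency of genes i, j among rounds
sampling both, and k is chosen from the CDF-area statistics of M.
With clusters C<sub>i</sub><sup>(d)</sup> per dataset, all
cross-dataset intersections

&nbsp;&nbsp;&nbsp;&nbsp;C<sub>i</sub><sup>(1)</sup> ∩ C<sub>j</sub><sup>(2)</sup> ∩ … ∩ C<sub>m</sub><sup>(D)</sup>

are enumerated per algorithm (Π<sub>d</sub> k<sub>d</sub> records),
filtered to ≥ 10 probes, and the k-means and SOM survivors are
intersected pairwise into *meta-intersections*. A meta-intersection
qualifies as an immune signature iff ≥ 50 % of members are annotated,
it has ≥ 10 unique gene symbols, and BH-FDR leaves an immune term with
q < 0.05.

Signatures are then (a) profiled against a leukocyte reference panel
(18 purified immune-cell groups): each gene's enrichment score in group
g is the sum of significant pairwise group-mean contrasts
Σ<sub>h≠g</sub> (μ̂<sub>g</sub> − μ̂<sub>h</sub>)·1[p ≤ α/153]
(Bonferroni over the 153 group pairs); and (b) collapsed to per-sample
*metagenes* (same-gene probes averaged first, then all values averaged)
which enter univariate Cox proportional-hazards models, h(t|z) =
h₀(t)·exp(βz), with Efron tie handling, overall and within clinical
strata (including tertiles of a continuous stratifier such as a
proliferation metagene).

A synthetic-data module plants conserved modules, private modules,
background genes, a marker-bearing reference panel and
proportional-hazards survival, so the whole pipeline is verifiable
against ground truth at desk scale.

## Worked example

```python
import immunesig as im

# five synthetic tumor datasets, three planted 40-gene immune modules
res = im.run_pipeline({"seed": 1}, outdir="out")

print(len(res.signatures))            # 3
print(res.recovery_jaccards())        # {'Sig01': 1.0, 'Sig02': 1.0, 'Sig03': 1.0}
print(res.selected_k[("DS1", "kmeans")])  # 3
print(res.survival_reports["DS1"].table[["metagene", "hazard_ratio", "p_value"]])
#   metagene  hazard_ratio   p_value
# 0    Sig01      0.620844  0.000129
# 1    Sig02      1.023679  0.815324
# 2    Sig03      1.362368  0.000667
```

The pipeline recovers exactly the three planted modules (Jaccard 1.0 to
truth) and selects k = 3 in every dataset for both algorithms. The
survival table shows the planted effects: the module simulated with
log-hazard −0.5 comes out protective (hazard ratio 0.62 per metagene
unit, p = 1.3·10⁻⁴), the null module is flat (HR ≈ 1), and the module
planted with +0.3 shows the inverse, poor-outcome association
(HR 1.36). `out/` contains per-stage artifacts: stable clusters and
selection counts, consensus matrices and summaries, intersection
tables, `signatures.gmt`, cell-type score and profile tables, metagene
tables with Newick dendrograms, and star-coded survival reports.

The same stages are available as CLI subcommands (`immunesig simulate`,
`collapse`, `stable-patterns`, `consensus`, `intersect`, `qualify`,
`cellscore`, `metagene`, `survival`, `run-all`), reading and writing
TSV/GCT matrices, GMT gene sets, TSV clinical tables and YAML configs.

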