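# ddr — data-driven reference tiers for cross-platform expression analysis

`ddr` identifies differentially expressed genes and builds single-sample
disease classifiers whose features survive a change of expression platform
(RNA-seq to microarray, lab to lab). It is aimed at transcriptomics analysts
who need biomarkers trained on one dataset to score an individual new sample
from another, without multi-sample batch correction.

## The method

Most expression values are only meaningful relative to the rest of their
sample. `ddr` makes that relativity explicit:

1. **Reference genes.** From the housekeeping genes of a dataset, select the
   most stable ones by the product score PS<sub>i</sub> = COV<sub>i</sub> ·
   MFC<sub>i</sub>, where COV<sub>i</sub> = σ<sub>i</sub>/μ<sub>i</sub> is the
   coefficient of variation of gene *i*'s CPM values and MFC<sub>i</sub> =
   max<sub>k</sub>/min<sub>k</sub> its maximum fold change, choosing one
   low-PS gene per stratum of the log2 expression axis (default spacing ≈ 2
   log2 units). Counts are first TMM-normalized and converted to CPM;
   pre-normalized microarray matrices are used as-is.
2. **Tiers.** In each sample *k*, the *n* reference values
   r<sub>1</sub><sup>(k)</sup> < … < r<sub>n</sub><sup>(k)</sup> cut the
   axis into *n*+1 intervals (r<sub>0</sub> = 0, r<sub>n+1</sub> = ∞); a gene
   whose expression falls between r<sub>j</sub> and r<sub>j+1</sub> is in
   tier *j*. Tiers are invariant under any strictly increasing per-sample
   transform — the formal statement of platform independence.
3. **Differential expression.** Per gene, a condition × tier contingency
   table is tested with the exact (Freeman–Halton) test under the
   multivariate-hypergeometric null; p-values are Benjamini–Hochberg
   adjusted. Genes are ranked by FDR and by the Expression Distance
   ED = Σ<sub>j</sub> j·n<sub>A<sub>j</sub></sub>/n<sub>A</sub> −
   Σ<sub>j</sub> j·n<sub>B<sub>j</sub></sub>/n<sub>B</sub>,
   the difference in mean tier index between conditions (sign = direction of
   regulation).
4. **Classification.** Selected biomarkers' tier vectors feed an RBF-kernel
   SVM (C = 1; one-vs-one / one-vs-rest for multi-class), evaluated by Monte
   Carlo cross-validation (1000 stratified 90/10 splits). Because a single
   sample's tiers are computed entirely within that sample, the model scores
   one sample at a time, on any platform where the reference genes are
   measured.

A benchmarking harness (subset-vs-full precision/recall, mock-comparison FDR,
Szymkiewicz–Simpson overlap of DEG lists) and a synthetic-data generator
(negative-binomial counts, planted housekeeping/DE genes, simulated second
platforms) complete the package.

## Worked example

```python
import numpy as np
import ddr

cfg = ddr.SimulationConfig(seed=1)            # 2000 genes, 30 vs 30 samples, 50 DE genes
counts, metadata, truth = ddr.simulate_counts(cfg)

cpm = ddr.normalize(counts)                   # TMM scale factors + counts per million
refs = ddr.select_references(ddr.stability_scores(cpm),
                             housekeeping=sorted(truth.housekeeping))
print("references:", refs.gene_ids)
print("log2 mean CPM:", np.round(np.log2(refs.mean_expr), 2))

results = ddr.run_de(cpm, metadata, refs, "A", "B", seed=1)
top = results[0]
print(f"top gene {top.gene_id}: p={top.p_value:.3g} fdr={top.fdr:.3g} ed={top.ed:+.2f}")
sig = [r for r in results if r.fdr < 0.1]
hits = {r.gene_id for r in sig} & set(truth.de_genes)
print(f"{len(sig)} genes at FDR<0.1, {len(hits)}/50 planted recovered")

tiers = ddr.assign_tiers(cpm, refs)
table = ddr.build_feature_table(tiers, [r.gene_id for r in sig[:4]], metadata)
report = ddr.mccv_evaluate(table, scheme="binary", iterations=1000, seed=1)
print(f"MCCV accuracy over 1000 stratified 90/10 splits: {report.accuracy:.3f}")
```

Output:

```
references: ['HK01', 'HK02', 'HK03', 'HK04', 'HK05']
log2 mean CPM: [ 2.02  4.06  6.04  8.04 10.06]
top gene DE026: p=1.69e-17 fdr=3.38e-14 ed=+1.03
52 genes at FDR<0.1, 50/50 planted recovered
MCCV accuracy over 1000 stratified 90/10 splits: 1.000
```

The five planted housekeeping genes are recovered as references at their
intended ~2-log2 spacing; all 50 planted four-fold-change genes are found at
FDR < 0.1 (with 2 false positives); and the four strongest biomarkers'
tier vectors separate the two conditions perfectly under cross-validation.

The same workflows are available from a shell via the `ddr` command
(`simulate`, `normalize`, `select-refs`, `tier`, `detest`, `markers`,
`features`, `train`, `predict`, `evaluate`, `benchmark`, and `run` for the
full pipeline from a YAML config).

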