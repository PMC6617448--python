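# methylhub

Integrated analysis of promoter DNA methylation and gene expression in
paired tumor/normal cohorts, with PPI-network hub-gene prioritization and
survival stratification.

## The problem

In many cancers, aberrant promoter methylation drives expression changes:
promoter hypomethylation can activate oncogenes, promoter hypermethylation
can silence tumor suppressors. Given a 450K-array beta-value matrix and an
RNA-seq expression matrix over matched tumor/normal pairs, this package

1. preprocesses both matrices (cross-reactive/SNP/sex-chromosome probe
   removal, missingness filtering, kNN imputation, promoter-window probe
   assignment, FPKM→TPM conversion),
2. calls **DEGs** (paired t-test on log2 TPM, median-ratio fold change,
   p < 0.05 and |log2 FC| > 1) and promoter **DMPs** (paired t-test on beta,
   p < 0.05), consolidating direction-consistent DMPs into **DMGs**,
3. classifies **EI genes** (epigenetically induced: promoter hypomethylated,
   expression up, significantly negative methylation–expression correlation)
   and **ES genes** (the converse),
4. finds **hub genes** in a protein–protein-interaction network by a
   per-gene neighborhood enrichment statistic, and
5. compares survival between expression-defined patient strata with
   Kaplan–Meier curves and the log-rank test.

It is written for computational biologists who want the whole chain — or any
single stage — as tested, scriptable Python, with a synthetic-data module
that generates cohorts with known planted structure so every stage can be
validated without access to protected patient data.

## The core statistic

For a network gene *g* with *m* neighbors, of which *a* are EI/ES genes,
out of *K* EI/ES genes among *N* network genes, neighborhood enrichment is
Fisher's exact test on the 2×2 table

```
            EI/ES   other
neighbor      a     m − a
rest        K − a   N − m − K + a
```

whose one-sided p-value is the hypergeometric tail
P(X ≥ a), X ~ Hypergeom(N, K, m). The focal gene is excluded from its own
neighborhood and from *K*. Hub genes satisfy Benjamini–Hochberg
FDR < 0.05 with a ≥ 5 EI/ES neighbors. The same hypergeometric tail backs
gene-set over-representation in the `enrichment` module.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (21 matched pairs, 2000 genes, 10 EI + 10 ES planted, a 2000-node
scale-free interaction network with 4 planted hubs):

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_differential.py
python analysis/04_integrate.py
python analysis/05_hubs.py
python analysis/06_enrichment.py
python analysis/07_survival.py
```

which prints, stage by stage:

```
probes: 3576 raw -> 3500 after filtering -> 3458 in promoters
DEGs: 10 up + 10 down of 2000 genes
DMPs: 219 of 3458 promoter probes
DMGs: 197 (4 discordant)
final calls: 10 EI, 10 ES
planted EI recovered: 10/10, planted ES recovered: 10/10
hubs called: ['G0270', 'G0879', 'G1205', 'G1586']
planted hubs recovered: 4/4, false hubs: 0
log-rank chi2 = 6.626, p = 0.0101
```

All 20 planted EI/ES genes and all 4 planted hubs are recovered with no
false hub calls; the 219 significant DMPs include the planted promoter
probes plus the expected ~5% false positives among the ~3400 null probes
(uncorrected p < 0.05 is deliberate at this stage — FDR control is applied
at the hub stage). The final log-rank p compares simulated survival between
the 10 high- and 11 low-expression tumors of the top hub gene.

`analysis/05_hubs.py` also recomputes, from their printed contingency
counts, the published four-hub reference statistics the network test is
validated against (neighborhood proportions such as 10/135 = 0.0740740 and
Fisher p-values 1.89e-05 … 1.88e-04, all FDR < 0.05).

The same pipeline is scriptable from the shell via the `methylhub` CLI
(`simulate`, `preprocess`, `diff`, `integrate`, `hubs`, `enrich`,
`survival`, and `run` for the whole chain with a YAML config).

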