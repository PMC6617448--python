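# Methods

## Analysis model

The pipeline assumes a paired design: each patient contributes one tumor and
one matched normal sample profiled on both a 450K-style methylation array
(beta values in [0, 1]) and RNA-seq (FPKM or TPM, non-negative). All
differential testing is within-pair, which removes between-patient baseline
variation and is the reason a cohort of ~21 pairs has usable power.

**Preprocessing.** Probes flagged cross-reactive or SNP-overlapping and
probes on chrX/chrY are removed, as are probes missing in more than 70% of
samples ("more than" read strictly: a probe missing in exactly 70% is
kept). Remaining gaps are filled by k-nearest-probe imputation: donors are
the k = 10 nearest probes by Euclidean distance over commonly observed
samples (mean-squared form, so probes with different overlap sizes are
comparable); the imputed value is the mean of the donors' values in the
missing sample, skipping donors unobserved there; a probe with no overlap
with any other probe falls back to its row mean. The missingness filter is
per-probe, which is standard 450K practice; a per-sample variant is
available behind a flag. Input betas are assumed already normalized
(SWAN/BMIQ-level normalization is array-specific and out of scope).
Promoter windows are TSS −1500 bp to +500 bp, strand-aware, endpoints
inclusive (the phrase "1500 bp upstream to 500 bp downstream" names closed
endpoints); a probe may fall in several genes' windows and then counts for
each. Coordinates are 1-based inclusive; BED-style input is shifted on
ingest. FPKM→TPM is per-sample renormalization to a column sum of 10⁶,
which preserves within-sample rank order.

**Differential calling.** Expression effect size is
log2((median_T + ε)/(median_N + ε)) with ε = 1 TPM, medians over the
matched samples; the test is a two-sided paired t-test on log2(TPM + 1).
The fold-change threshold is stated in log2 units, so testing on the log
scale is the coherent default; raw-scale testing is available by flag.
Methylation effect size is the median beta difference; the test is a
two-sided paired t-test on beta (M-value testing by flag). Thresholds are
strict (p < 0.05, |log2 FC| > 1). A feature whose paired differences have
zero variance gets p = 1 and a warning flag rather than NaN. **No
multiple-testing correction is applied at the DEG/DMP stage**; the design
controls error rates downstream, at the hub stage, and the uncorrected
stage-wise rate is verified by the null-calibration tests.

**DMG consolidation and EI/ES calling.** A gene's significant promoter DMPs
must agree in sign to define a differentially methylated gene; mixed-sign
promoters are "discordant" and excluded. EI candidates are genes with
expression up and promoter methylation down; ES candidates the converse.
The final filter correlates each valid DMP's beta with the gene's
expression across all samples — tumor and normal jointly, which maximizes n
at this cohort scale and spans the dynamic range that drives the
correlation (tumor-only mode by flag). Spearman correlation is the default
(robust to the beta/TPM scale mismatch; Pearson by flag), two-sided p with
the sign requirement r < 0. With several valid DMPs, all must correlate
negatively and the smallest-p DMP is recorded.

**Hub statistic.** See README for the contingency table. Two sidings are
implemented: the one-sided hypergeometric enrichment tail P(X ≥ a)
(default — enrichment is directional, a = 0 gives p = 1 exactly, and p is
monotone in a) and the two-sided Fisher exact p, which is what reproduces
the published four-hub reference table this statistic is validated against
(for its three strongest rows the two sidings agree to printed precision;
the fourth row distinguishes them). The published proportion column
(10/135) fixes the table reading: the printed "neighborhood" count excludes
the EI neighbors, so total degree is their sum. FDR is Benjamini–Hochberg
over all nodes with degree ≥ 1; hubs need FDR < 0.05 (0.01 selectable) and
≥ 5 EI/ES neighbors. The label set for K is configurable (EI-only, ES-only,
or EI∪ES; EI∪ES default).

**Enrichment and survival.** Over-representation uses the same
hypergeometric tail over user-supplied GMT collections, BH-corrected, with
the universe defaulting to the expression matrix's genes; term crosstalk
edges connect significant terms with gene-set Jaccard ≥ 0.5 (inclusive).
Survival uses a median split of expression (strictly-above-median = high;
ties low), the product-limit Kaplan–Meier estimator, and the standard
two-group log-rank chi-square — all implemented from first principles and
cross-checked against an independent survival library in the tests. Cox
regression is deliberately out of scope: the substantive quantity here is
the nonparametric separation of the strata.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the physics of the assay.

- **Betas in logit space.** Each probe has a baseline beta; noise is added
  on the M-value (logit2) scale and mapped back through the logistic, so
  values stay strictly inside (0, 1) with no clipping atoms at the
  boundaries. The M-space noise scale is the requested beta-space SD
  divided by the local logistic slope, so the realized beta-space SD is
  ≈ `noise_sd_beta` away from the boundaries.
- **Planted effects.** EI genes get a tumor beta shift of −|beta_shift| on
  every promoter probe and +|expr_log2fc| in log2 expression; ES genes the
  converse (`beta_shift`/`expr_log2fc` are magnitudes). Defaults:
  21 pairs, 2000 genes, 10 EI + 10 ES, |Δβ| = 0.3, |log2 FC| = 2,
  noise SDs 0.05 (beta) and 0.5 (log2 expression) — a strong-effect,
  modest-noise regime typical of validated 450K/RNA-seq tumor-normal hits.
- **Methylation–expression coupling.** Within planted genes, a shared
  per-(gene, sample) latent factor enters the methylation noise with weight
  +√0.5 and the expression noise with weight −√0.5, inducing a negative
  per-sample correlation of about −0.5 on top of the group shift, without
  distorting either marginal. Null genes have independent noise.
- **Promoter architecture.** Probes per promoter are drawn from a
  distribution massed on one probe (default {1: 0.55, 2: 0.25, 3: 0.12,
  4: 0.08}), matching the observation that most differentially methylated
  promoters carry a single DMP. Decoy content exercises preprocessing:
  ~1% cross-reactive and ~0.5% SNP-flagged probes, 20 sex-chromosome
  probes, ~2% of null genes with an extra out-of-window probe, sporadic
  missing values (0.5% of null-probe entries) and three probes with 80%
  missingness. Planted genes are kept clean so truth labels stay
  unambiguous.
- **Network.** Barabási–Albert preferential attachment (m = 3 over 2000
  nodes) gives the heavy-tailed degree distribution; the planted hubs are
  the highest-degree non-planted nodes, rewired so that `hub_ei_frac`
  (default 0.5) of their neighbors are planted EI/ES genes (capped by the
  planted count), preserving graph simplicity.
- **Survival.** Event times are exponential — the simplest model in which
  the configured hazard ratio (default 3 for the high-expression group,
  baseline 0.02/month) is exact. Censoring is independent with probability
  `censor_rate` (default 0.2); a censored record's time is a uniform
  fraction of its event time.
- **Determinism.** All draws derive from `SimConfig.seed` through
  per-component child generators; identical configs give byte-identical
  outputs.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: Infinium type-I/II probe chemistry and
dye-bias, tumor purity and copy-number contamination, batch structure,
heavy-tailed count noise in RNA-seq, correlated probes within CpG islands
beyond the planted promoter block, biological pathway structure in the PPI,
and non-proportional hazards.

## Numerical and design choices

- Pseudocounts: ε = 1 TPM before logs and in the median ratio; ε = 10⁻⁶
  guards beta logits.
- The hypergeometric tail is a single shared implementation
  (`stats.hypergeom_tail`) used by both the hub and enrichment modules; the
  test suite checks it against a direct log-factorial summation oracle
  exhaustively for all (N ≤ 200, K, m, a) instances at 10⁻¹² and against an
  exact integer-combinatorics oracle on random spot checks.
- Paired t-tests are computed vectorized from the mean and SD of paired
  differences plus the t CDF, matching `scipy.stats.ttest_rel` to 10⁻¹²;
  this keeps the zero-variance→p = 1 rule explicit.
- The neighbor-count threshold is a ≥ 5 (at the reference table's scale the
  "> 5" and "≥ 5" readings select the same genes, every reference hub
  having ≥ 8 hits).
- Validation problem sizes: recovery and null-calibration experiments run
  20 seeds at the default study scale (2000 genes, ~3500 probes,
  2000-node network), chosen as the smallest scale at which stage-wise
  false-positive fractions are estimated with SE ≤ 0.5 percentage points.

## Known limitations

- The correlation filter tests one DMP at a time; it does not model joint
  promoter methylation, and a promoter with several weakly negative DMPs
  can be dropped where a combined test would retain it.
- BH FDR assumes positive dependence at worst; neighborhood statistics of
  adjacent nodes share edges and are mildly dependent. The null-calibration
  experiment shows the realized false hub rate is conservative under this
  dependence.
- The kNN imputer is O(rows² · missing-rows) in the worst case; it is
  intended for post-filtering matrices (≤ a few 10⁵ probes with sparse
  missingness), not raw arrays.
- Paired t-tests on beta values are approximate for strongly boundary-
  concentrated probes; M-value testing is provided for that regime.
- The median expression split is a convention; optimal-cutpoint methods
  would give different strata and are not implemented.
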