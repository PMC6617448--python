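"""Synthetic paired methylation/expression cohorts with planted structure.

The generator emulates the statistical structure the downstream analysis
assumes: matched tumor/normal pairs; planted epigenetically induced (EI)
genes whose promoters lose methylation while expression rises, planted
epigenetically suppressed (ES) genes with the converse pattern, and null
genes with no systematic shift; a scale-free protein-interaction network
with planted hub nodes whose neighborhoods are enriched for the planted
genes; and exponential survival times whose hazard depends on an
expression-defined group.

Beta values are generated in logit (M-value) space and mapped back through
the logistic, so they stay inside [0, 1] without clipping.  Within planted
genes, per-sample methylation and expression deviations share a latent
factor with opposite signs, inducing the negative coupling the correlation
filter screens for while preserving both marginals.

Every function is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd

from .config import SimConfig
from .matrix import PairedMatrix

# share of the per-sample noise variance carried by the shared latent factor
# in planted genes; the induced methylation-expression correlation is about
# -LATENT_WEIGHT on top of the group-shift signal
LATENT_WEIGHT = 0.5

# fractions of decoy content that exercises the preprocessing filters
CROSS_REACTIVE_FRAC = 0.01
SNP_FLAG_FRAC = 0.005
SEX_CHROM_GENES = 20
NON_PROMOTER_FRAC = 0.02
MISSING_RATE = 0.005
N_HIGH_NA_PROBES = 3

BASELINE_HAZARD = 0.02  # events per month in the low-expression group


def _logit2(b):
    return np.log2(b / (1.0 - b))


def _expit2(m):
    return 1.0 / (1.0 + 2.0 ** (-m))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _sample_ids(config: SimConfig):
    pair_ids = [f"P{i:03d}" for i in range(1, config.n_pairs + 1)]
    tumor = [f"{p}_T" for p in pair_ids]
    normal = [f"{p}_N" for p in pair_ids]
    pairing = pd.DataFrame(
        {
            "pair_id": pair_ids * 2,
            "status": ["tumor"] * config.n_pairs + ["normal"] * config.n_pairs,
        },
        index=pd.Index(tumor + normal, name="sample"),
    )
    return tumor, normal, pairing


def simulate_methylation_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, PairedMatrix, PairedMatrix, pd.DataFrame]:
    """Generate (annotation, beta matrix, expression matrix, truth table).

    The truth table is gene-indexed with a ``label`` column in
    {"EI", "ES", "null"}.  Planted EI genes carry a tumor-normal beta shift
    of -|beta_shift| on every promoter probe and +|expr_log2fc| in log2
    expression; ES genes the converse.  The annotation also contains decoy
    content for the preprocessing stage: cross-reactive and SNP-flagged
    probes, sex-chromosome probes, probes outside any promoter window, a few
    probes with >70% missing values, and sporadic missing entries elsewhere
    (planted genes stay clean so truth labels are unambiguous).
    """
    rng = _rng(config, 1)
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    labels = np.array(["null"] * config.n_genes, dtype=object)
    planted_idx = rng.choice(
        config.n_genes, size=config.n_ei_planted + config.n_es_planted, replace=False
    )
    labels[planted_idx[: config.n_ei_planted]] = "EI"
    labels[planted_idx[config.n_ei_planted :]] = "ES"
    truth = pd.DataFrame({"label": labels}, index=pd.Index(genes, name="gene"))

    shift = abs(config.beta_shift)
    lfc = abs(config.expr_log2fc)

    # --- annotation -------------------------------------------------------
    ks = sorted(config.probes_per_promoter_dist)
    probs = np.array([config.probes_per_promoter_dist[k] for k in ks], dtype=float)
    n_probes_per_gene = rng.choice(ks, size=config.n_genes, p=probs / probs.sum())

    rows = []
    probe_gene_idx = []
    counter = 0
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi % 22 + 1}"
        strand = "+" if gi % 2 == 0 else "-"
        tss = 100_000 + 10_000 * (gi // 22 + 1)
        for _ in range(int(n_probes_per_gene[gi])):
            counter += 1
            offset = int(rng.integers(-1500, 501))
            pos = tss + offset if strand == "+" else tss - offset
            rows.append((f"cg{counter:07d}", chrom, pos, strand, gene, tss, False, False))
            probe_gene_idx.append(gi)
        # occasional probe outside the promoter window (dropped at assignment)
        if labels[gi] == "null" and rng.random() < NON_PROMOTER_FRAC:
            counter += 1
            offset = int(rng.integers(3000, 10_000))
            pos = tss + offset if strand == "+" else tss - offset
            rows.append((f"cg{counter:07d}", chrom, pos, strand, gene, tss, False, False))
            probe_gene_idx.append(gi)
    # sex-chromosome decoys (filtered before any assignment)
    for j in range(SEX_CHROM_GENES):
        counter += 1
        rows.append(
            (f"cg{counter:07d}", "chrX" if j % 2 else "chrY", 50_000 + 1000 * j, "+",
             f"SEXG{j:03d}", 50_000 + 1000 * j, False, False)
        )
        probe_gene_idx.append(-1)
    ann = pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "pos", "strand", "gene", "tss",
                 "cross_reactive", "snp_flag"],
    )
    # flag decoys only on null/sex genes so planted promoters stay intact
    gene_idx = np.array(probe_gene_idx)
    flaggable = np.array(
        [gi < 0 or labels[gi] == "null" for gi in gene_idx]
    )
    u = rng.random(len(ann))
    ann.loc[flaggable & (u < CROSS_REACTIVE_FRAC), "cross_reactive"] = True
    u = rng.random(len(ann))
    ann.loc[flaggable & (u < SNP_FLAG_FRAC), "snp_flag"] = True

    # --- beta matrix ------------------------------------------------------
    tumor, normal, pairing = _sample_ids(config)
    n_s = 2 * config.n_pairs
    n_probes = len(ann)
    is_tumor = np.array([True] * config.n_pairs + [False] * config.n_pairs)

    # shared latent factor per (gene, sample), opposite-signed in expression
    z = rng.standard_normal((config.n_genes, n_s))

    base = rng.uniform(0.2, 0.8, size=n_probes)
    planted_mask = gene_idx >= 0
    ei_probe = planted_mask & (np.take(labels, np.clip(gene_idx, 0, None)) == "EI")
    es_probe = planted_mask & (np.take(labels, np.clip(gene_idx, 0, None)) == "ES")
    # keep shifted means away from the boundaries
    base[ei_probe] = rng.uniform(0.1 + shift, 0.9, size=ei_probe.sum())
    base[es_probe] = rng.uniform(0.1, 0.9 - shift, size=es_probe.sum())

    target = np.tile(base[:, None], (1, n_s))
    target[np.ix_(ei_probe, is_tumor)] -= shift
    target[np.ix_(es_probe, is_tumor)] += shift

    w = math.sqrt(LATENT_WEIGHT)
    eps = rng.standard_normal((n_probes, n_s))
    noise_unit = eps.copy()
    coupled = ei_probe | es_probe
    gi_c = gene_idx[coupled]
    noise_unit[coupled] = w * z[gi_c, :] + math.sqrt(1 - LATENT_WEIGHT) * eps[coupled]

    # noise applied in M space, scaled so its beta-space sd is ~noise_sd_beta
    slope = np.log(2.0) * target * (1.0 - target)  # d beta / d M
    m_vals = _logit2(target) + (config.noise_sd_beta / slope) * noise_unit
    beta_vals = _expit2(m_vals)

    beta_df = pd.DataFrame(beta_vals, index=ann["probe_id"].to_numpy(), columns=tumor + normal)

    # sporadic missingness on null-gene probes, plus a few high-NA junk probes
    null_probe = planted_mask & ~coupled
    miss = (rng.random((n_probes, n_s)) < MISSING_RATE) & null_probe[:, None]
    vals = beta_df.to_numpy()
    vals[miss] = np.nan
    beta_df = pd.DataFrame(vals, index=beta_df.index, columns=beta_df.columns)
    junk_rows = []
    for j in range(N_HIGH_NA_PROBES):
        counter += 1
        pid = f"cg{counter:07d}"
        junk_rows.append((pid, "chr1", 99_000 + j, "+", "G0001", 100_000 + 10_000, False, False))
        row = rng.uniform(0.2, 0.8, size=n_s)
        n_na = int(math.ceil(0.8 * n_s))
        row[rng.choice(n_s, size=n_na, replace=False)] = np.nan
        beta_df.loc[pid] = row
    ann = pd.concat(
        [ann, pd.DataFrame(junk_rows, columns=ann.columns)], ignore_index=True
    )

    beta = PairedMatrix(beta_df, pairing)

    # --- expression matrix ------------------------------------------------
    mu = rng.normal(5.0, 1.5, size=config.n_genes)
    x = np.tile(mu[:, None], (1, n_s))
    x[np.ix_(labels == "EI", is_tumor)] += lfc
    x[np.ix_(labels == "ES", is_tumor)] -= lfc
    e2 = rng.standard_normal((config.n_genes, n_s))
    unit = e2.copy()
    planted_gene = labels != "null"
    unit[planted_gene] = (
        -w * z[planted_gene] + math.sqrt(1 - LATENT_WEIGHT) * e2[planted_gene]
    )
    x = x + config.noise_sd_expr * unit
    expr_df = pd.DataFrame(2.0**x, index=pd.Index(genes, name="gene"), columns=tumor + normal)
    expr = PairedMatrix(expr_df, pairing.copy())

    return ann, beta, expr, truth


def simulate_ppi(config: SimConfig, truth: pd.DataFrame) -> tuple[nx.Graph, pd.DataFrame]:
    """Scale-free PPI with planted hubs enriched for planted EI/ES genes.

    A Barabasi-Albert graph over ``ppi_n_nodes`` is relabeled with the gene
    names (plus EXTxxxx filler nodes when the network is larger than the
    gene panel).  The ``n_hubs_planted`` highest-degree non-planted nodes are
    then rewired so at least ``hub_ei_frac`` of their neighbors are planted
    EI/ES genes (capped by the number of planted genes).  Returns the graph
    and a node-indexed truth table with an ``is_hub`` column.
    """
    if config.ppi_attach_m >= config.ppi_n_nodes:
        raise ValueError(
            "invalid SimConfig field 'ppi_attach_m': must be < ppi_n_nodes"
        )
    rng = _rng(config, 2)
    genes = list(truth.index)
    names = genes + [f"EXT{i:04d}" for i in range(config.ppi_n_nodes - len(genes))]
    g0 = nx.barabasi_albert_graph(
        config.ppi_n_nodes, config.ppi_attach_m,
        seed=int(rng.integers(2**31)),
    )
    perm = rng.permutation(config.ppi_n_nodes)
    g = nx.relabel_nodes(g0, {i: names[perm[i]] for i in g0.nodes})

    planted = set(truth.index[truth["label"] != "null"])
    hub_truth = pd.DataFrame(
        {"is_hub": False}, index=pd.Index(sorted(g.nodes), name="node")
    )
    candidates = sorted(
        (n for n in g.nodes if n not in planted),
        key=lambda n: (-g.degree(n), n),
    )
    hubs = candidates[: config.n_hubs_planted]
    for hub in hubs:
        hub_truth.loc[hub, "is_hub"] = True
        neigh = set(g.neighbors(hub))
        want = min(math.ceil(config.hub_ei_frac * len(neigh)), len(planted))
        have = len(neigh & planted)
        pool = sorted(planted - neigh - {hub})
        swappable = sorted(neigh - planted - set(hubs))
        n_swap = min(want - have, len(pool), len(swappable))
        if n_swap > 0:
            drop = rng.choice(len(swappable), size=n_swap, replace=False)
            add = rng.choice(len(pool), size=n_swap, replace=False)
            for di, ai in zip(drop, add):
                g.remove_edge(hub, swappable[di])
                g.add_edge(hub, pool[ai])
    return g, hub_truth


def simulate_survival(groups: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Exponential survival times with a group-dependent hazard.

    ``groups`` maps sample -> {"high", "low"}.  Low-group hazard is
    ``BASELINE_HAZARD`` per month; high-group hazard is multiplied by
    ``hazard_ratio``.  Each record is independently censored with
    probability ``censor_rate`` at a uniform fraction of its event time.
    """
    bad = set(groups) - {"high", "low"}
    if bad:
        raise ValueError(f"unknown expression groups: {sorted(bad)}")
    rng = _rng(config, 3)
    hazard = np.where(groups.to_numpy() == "high",
                      BASELINE_HAZARD * config.hazard_ratio, BASELINE_HAZARD)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(groups)) < config.censor_rate
    time = np.where(censored, t_event * rng.random(len(groups)), t_event)
    return pd.DataFrame(
        {
            "sample": groups.index,
            "time": time,
            "event": (~censored).astype(int),
            "group": groups.to_numpy(),
        }
    ).set_index("sample")


def write_fixture(outdir, config: SimConfig) -> dict:
    """Generate everything and write the TSV fixture files into ``outdir``.

    Returns a dict of the generated in-memory objects (annotation, beta,
    expr, truth, ppi, hub_truth) for callers that keep going in memory.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    ann, beta, expr, truth = simulate_methylation_expression(config)
    ppi, hub_truth = simulate_ppi(config, truth)
    ann.to_csv(os.path.join(outdir, "annotation.tsv"), sep="\t", index=False)
    beta.to_tsv(os.path.join(outdir, "beta.tsv"))
    expr.to_tsv(os.path.join(outdir, "expression.tsv"))
    truth.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t")
    hub_truth.to_csv(os.path.join(outdir, "truth_hubs.tsv"), sep="\t")
    with open(os.path.join(outdir, "ppi_edges.tsv"), "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in ppi.edges):
            fh.write(f"{u}\t{v}\n")
    return {
        "annotation": ann,
        "beta": beta,
        "expr": expr,
        "truth": truth,
        "ppi": ppi,
        "hub_truth": hub_truth,
    }
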