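"""End-to-end orchestration of the integrated methylation/expression analysis.

Stage order follows the analysis design: probe filtering -> kNN imputation ->
promoter assignment -> TPM conversion -> DEG/DMP calling -> DMG
consolidation -> EI/ES classification -> subnet mapping -> neighborhood
Fisher hub calling.  ``run_pipeline`` keeps everything in memory (used by the
tests and the acceptance script); ``run_all`` drives it from files and writes
every stage table plus a manifest with config hash and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import networkx as nx
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .differential import call_degs, call_dmps, consolidate_dmgs, dmp_count_distribution
from .integration import correlation_filter, pair_candidates, summarize_ei_es
from .matrix import PairedMatrix
from .network import call_hubs, extract_subnet, load_ppi, neighborhood_fisher_all
from .preprocess import (
    assign_promoter_probes,
    filter_probes,
    fpkm_to_tpm,
    impute_knn,
    load_annotation,
)


def run_pipeline(
    ann: pd.DataFrame,
    beta: PairedMatrix,
    expr: PairedMatrix,
    ppi: nx.Graph,
    config: PipelineConfig | None = None,
    expr_is_tpm: bool = False,
) -> dict:
    """Run every stage in memory and return all intermediate tables."""
    cfg = config or PipelineConfig()
    beta_f = filter_probes(beta, ann, na_frac_max=cfg.na_frac_max)
    beta_i = impute_knn(beta_f, k=cfg.k_knn)
    assignments = assign_promoter_probes(ann, cfg.upstream, cfg.downstream)
    promoter_probes = [
        p for p in beta_i.feature_ids if p in set(assignments["probe_id"])
    ]
    beta_p = beta_i.subset_features(promoter_probes)
    tpm = expr if expr_is_tpm else fpkm_to_tpm(expr)

    degs = call_degs(tpm, alpha=cfg.alpha_deg, lfc_min=cfg.lfc_min)
    dmps = call_dmps(beta_p, alpha=cfg.alpha_dmp)
    dmgs = consolidate_dmgs(dmps, assignments)
    candidates = pair_candidates(degs, dmgs)
    calls = correlation_filter(
        candidates, beta_p, tpm, method=cfg.corr_method, alpha=cfg.alpha_corr
    )
    summary = summarize_ei_es(calls)

    if cfg.hub_label_set == "both":
        label_genes = set(summary["EI"]) | set(summary["ES"])
    else:
        label_genes = set(summary[cfg.hub_label_set])
    subnet, subnet_report = extract_subnet(ppi, label_genes)
    hub_stats = neighborhood_fisher_all(
        ppi, label_genes, alternative=cfg.hub_alternative
    )
    hubs = call_hubs(hub_stats, fdr_max=cfg.fdr_max, min_hits=cfg.min_hits)

    return {
        "config": cfg,
        "beta_promoter": beta_p,
        "tpm": tpm,
        "assignments": assignments,
        "degs": degs,
        "dmps": dmps,
        "dmgs": dmgs,
        "dmp_histogram": dmp_count_distribution(dmgs),
        "candidates": candidates,
        "calls": calls,
        "summary": summary,
        "subnet": subnet,
        "subnet_report": subnet_report,
        "hub_stats": hubs,
        "hub_genes": list(hubs.index[hubs["is_hub"]]),
    }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    beta_path,
    expr_path,
    annotation_path,
    ppi_path,
    outdir,
    config: PipelineConfig | None = None,
    expr_is_tpm: bool = False,
) -> dict:
    """File-to-file pipeline run; writes stage TSVs and a JSON manifest.

    Validates input paths before any computation; reruns with the same inputs
    and config produce byte-identical outputs.
    """
    cfg = config or PipelineConfig()
    for p in (beta_path, expr_path, annotation_path, ppi_path):
        if not os.path.exists(p):
            raise FileNotFoundError(f"input file not found: {p}")
    os.makedirs(outdir, exist_ok=True)

    ann = load_annotation(annotation_path)
    beta = PairedMatrix.from_tsv(beta_path)
    expr = PairedMatrix.from_tsv(expr_path)
    ppi = load_ppi(ppi_path)
    res = run_pipeline(ann, beta, expr, ppi, cfg, expr_is_tpm=expr_is_tpm)

    tables = {
        "degs.tsv": res["degs"],
        "dmps.tsv": res["dmps"],
        "dmgs.tsv": res["dmgs"].assign(
            valid_dmp_ids=res["dmgs"]["valid_dmp_ids"].map(",".join)
        )
        if len(res["dmgs"])
        else res["dmgs"],
        "eies_calls.tsv": res["calls"],
        "hub_stats.tsv": res["hub_stats"],
    }
    outputs = {}
    for name, df in tables.items():
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t")
        outputs[name] = _sha256(path)

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "summary": {
            "n_EI": res["summary"]["n_EI"],
            "n_ES": res["summary"]["n_ES"],
            "subnet": res["subnet_report"],
            "hub_genes": res["hub_genes"],
            "dmp_histogram": res["dmp_histogram"],
        },
        "outputs": outputs,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return res
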