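#!/usr/bin/env python
"""Classify EI and ES genes and score the calls against the planted truth.

EI = expression up + promoter methylation down + significant negative
Spearman correlation between the valid DMP's beta and the gene's expression
across all samples; ES = the converse.  Writes results/integration/.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from methylhub.integration import correlation_filter, pair_candidates, summarize_ei_es
from methylhub.matrix import PairedMatrix

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    out = ROOT / "integration"
    out.mkdir(parents=True, exist_ok=True)
    degs = pd.read_csv(ROOT / "differential" / "degs.tsv", sep="\t", index_col=0)
    dmgs = pd.read_csv(ROOT / "differential" / "dmgs.tsv", sep="\t", index_col=0)
    dmgs["valid_dmp_ids"] = dmgs["valid_dmp_ids"].map(lambda s: s.split(","))
    beta = PairedMatrix.from_tsv(ROOT / "preprocess" / "beta_promoter.tsv")
    tpm = PairedMatrix.from_tsv(ROOT / "preprocess" / "tpm.tsv")

    candidates = pair_candidates(degs, dmgs)
    calls = correlation_filter(candidates, beta, tpm)
    calls.to_csv(out / "eies_calls.tsv", sep="\t")
    s = summarize_ei_es(calls)

    truth = pd.read_csv(ROOT / "fixture" / "truth_genes.tsv", sep="\t",
                        index_col=0, keep_default_na=False)
    planted_ei = set(truth.index[truth["label"] == "EI"])
    planted_es = set(truth.index[truth["label"] == "ES"])
    print(f"candidates after direction pairing: {len(candidates)}")
    print(f"final calls: {s['n_EI']} EI, {s['n_ES']} ES")
    print(f"planted EI recovered: {len(set(s['EI']) & planted_ei)}/{len(planted_ei)}, "
          f"planted ES recovered: {len(set(s['ES']) & planted_es)}/{len(planted_es)}")
    with open(out / "ei_genes.txt", "w") as fh:
        fh.write("\n".join(s["EI"]) + "\n")
    with open(out / "es_genes.txt", "w") as fh:
        fh.write("\n".join(s["ES"]) + "\n")


if __name__ == "__main__":
    main()
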