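#!/usr/bin/env python
"""Call DEGs and promoter DMPs, consolidate DMPs into DMGs.

Paired t-tests across the 21 matched pairs; expression effect = log2 median
tumor/normal TPM ratio (threshold |log2FC| > 1, p < 0.05), methylation
effect = median beta difference (p < 0.05).  Genes whose significant
promoter DMPs disagree in sign are marked discordant and dropped downstream.
Writes results/differential/.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from methylhub.differential import (
    call_degs,
    call_dmps,
    consolidate_dmgs,
    dmp_count_distribution,
)
from methylhub.matrix import PairedMatrix

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    out = ROOT / "differential"
    out.mkdir(parents=True, exist_ok=True)
    tpm = PairedMatrix.from_tsv(ROOT / "preprocess" / "tpm.tsv")
    beta = PairedMatrix.from_tsv(ROOT / "preprocess" / "beta_promoter.tsv")
    assignments = pd.read_csv(ROOT / "preprocess" / "promoter_assignments.tsv", sep="\t")

    degs = call_degs(tpm)
    dmps = call_dmps(beta)
    dmgs = consolidate_dmgs(dmps, assignments)
    hist = dmp_count_distribution(dmgs)

    degs.to_csv(out / "degs.tsv", sep="\t")
    dmps.to_csv(out / "dmps.tsv", sep="\t")
    dmgs.assign(valid_dmp_ids=dmgs["valid_dmp_ids"].map(",".join)).to_csv(
        out / "dmgs.tsv", sep="\t"
    )

    up = int((degs["significant"] & (degs["direction"] == "up")).sum())
    down = int((degs["significant"] & (degs["direction"] == "down")).sum())
    print(f"DEGs: {up} up + {down} down of {len(degs)} genes")
    print(f"DMPs: {int(dmps['significant'].sum())} of {len(dmps)} promoter probes")
    print(f"DMGs: {len(dmgs)} ({int((dmgs['direction'] == 'discordant').sum())} discordant)")
    print(f"genes per promoter-DMP count: {hist}")


if __name__ == "__main__":
    main()
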