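#!/usr/bin/env python
"""Filter probes, impute missing betas, map promoters, convert FPKM to TPM.

Reads results/fixture/, writes analysis-ready matrices to
results/preprocess/: promoter-probe beta matrix (flagged/sex-chromosome/
high-missingness probes removed, remaining gaps kNN-imputed) and a TPM
expression matrix.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from methylhub.matrix import PairedMatrix
from methylhub.preprocess import (
    assign_promoter_probes,
    filter_probes,
    fpkm_to_tpm,
    impute_knn,
    load_annotation,
)

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    out = ROOT / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    ann = load_annotation(ROOT / "fixture" / "annotation.tsv")
    beta = PairedMatrix.from_tsv(ROOT / "fixture" / "beta.tsv")
    n0 = len(beta.feature_ids)
    beta = filter_probes(beta, ann)
    n1 = len(beta.feature_ids)
    beta = impute_knn(beta)
    assignments = assign_promoter_probes(ann)
    keep = [p for p in beta.feature_ids if p in set(assignments["probe_id"])]
    beta = beta.subset_features(keep)
    beta.to_tsv(out / "beta_promoter.tsv")
    assignments.to_csv(out / "promoter_assignments.tsv", sep="\t", index=False)
    tpm = fpkm_to_tpm(PairedMatrix.from_tsv(ROOT / "fixture" / "expression.tsv"))
    tpm.to_tsv(out / "tpm.tsv")
    print(f"probes: {n0} raw -> {n1} after filtering -> {len(keep)} in promoters")
    print(f"expression: {len(tpm.feature_ids)} genes, columns renormalized to TPM")


if __name__ == "__main__":
    main()
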