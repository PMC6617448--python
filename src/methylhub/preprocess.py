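"""Probe filtering, imputation, promoter assignment and TPM conversion.

Input betas are assumed already normalized (e.g. SWAN/BMIQ upstream); no
array-level normalization is performed here.  Coordinates are 1-based
inclusive throughout; BED-style 0-based input must be converted on ingest
(``load_annotation(..., coord_system="bed")``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import PairedMatrix

ANNOTATION_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "strand",
    "gene",
    "tss",
    "cross_reactive",
    "snp_flag",
]

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def load_annotation(path, coord_system: str = "onebased") -> pd.DataFrame:
    """Read a probe annotation TSV (schema: probe_id, chrom, pos, strand, gene,
    tss, cross_reactive, snp_flag).  ``coord_system="bed"`` shifts 0-based
    ``pos``/``tss`` to 1-based."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if coord_system == "bed":
        ann = ann.assign(pos=ann["pos"] + 1, tss=ann["tss"] + 1)
    elif coord_system != "onebased":
        raise ValueError(f"unknown coord_system: {coord_system!r}")
    if ann["probe_id"].duplicated().any():
        raise ValueError("duplicated probe_id in annotation")
    if (ann["pos"] < 1).any() or (ann["tss"] < 1).any():
        raise ValueError("coordinates must be >= 1 (1-based)")
    ann["cross_reactive"] = ann["cross_reactive"].astype(bool)
    ann["snp_flag"] = ann["snp_flag"].astype(bool)
    return ann


def filter_probes(
    beta: PairedMatrix,
    ann: pd.DataFrame,
    na_frac_max: float = 0.70,
    per_sample: bool = False,
) -> PairedMatrix:
    """Remove unreliable probes from a beta matrix.

    Dropped: probes flagged cross-reactive or SNP-overlapping, probes on the
    sex chromosomes, and probes whose missing fraction across samples is
    strictly greater than ``na_frac_max``.  Probe order is preserved.
    ``per_sample=True`` additionally drops samples missing in more than
    ``na_frac_max`` of probes (off by default; the per-probe reading is
    standard 450K practice).
    """
    if not 0.0 <= na_frac_max <= 1.0:
        raise ValueError("na_frac_max must be in [0, 1]")
    flagged = ann.loc[
        ann["cross_reactive"] | ann["snp_flag"] | ann["chrom"].isin(SEX_CHROMS),
        "probe_id",
    ]
    vals = beta.values
    if per_sample:
        sample_na = vals.isna().mean(axis=0)
        vals = vals.loc[:, sample_na <= na_frac_max]
    keep_flag = ~vals.index.isin(set(flagged))
    na_frac = vals.isna().mean(axis=1).to_numpy()
    keep = keep_flag & (na_frac <= na_frac_max)
    if not keep.any():
        raise ValueError("no probes survive filtering")
    return PairedMatrix(vals.loc[keep], beta.pairing.copy())


def impute_knn(beta: PairedMatrix, k: int = 10) -> PairedMatrix:
    """Fill missing beta values by k-nearest-probe averaging.

    For each probe with missing entries, the k nearest other probes by
    Euclidean distance over commonly observed samples donate: the imputed
    value is the mean of the k nearest donors' values in the missing sample
    (donors without an observed value there are skipped in favor of the next
    nearest).  A probe with no overlapping observations with any other probe
    falls back to its own row mean.  Observed entries are returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = beta.values.to_numpy(float).copy()
    obs = ~np.isnan(X)
    if obs.all():
        return PairedMatrix(beta.values.copy(), beta.pairing.copy())
    if (~obs).all(axis=1).any():
        bad = beta.feature_ids[(~obs).all(axis=1)][:5].tolist()
        raise ValueError(f"fully missing rows cannot be imputed: {bad}")
    need = np.where(~obs.all(axis=1))[0]
    X0 = np.where(obs, X, 0.0)
    for i in need:
        # mean squared difference over commonly observed samples, so rows
        # with different overlap sizes are comparable
        common = obs & obs[i]
        n_common = common.sum(axis=1)
        diff2 = (X0 - X0[i]) ** 2 * common
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(diff2.sum(axis=1) / n_common)
        dist[i] = np.inf
        dist[n_common == 0] = np.inf
        order = np.argsort(dist, kind="stable")
        row_mean = X[i, obs[i]].mean()
        for j in np.where(~obs[i])[0]:
            donors = [r for r in order if np.isfinite(dist[r]) and obs[r, j]][:k]
            X[i, j] = X[donors, j].mean() if donors else row_mean
    out = pd.DataFrame(X, index=beta.values.index, columns=beta.values.columns)
    return PairedMatrix(out, beta.pairing.copy())


def assign_promoter_probes(
    ann: pd.DataFrame, upstream: int = 1500, downstream: int = 500
) -> pd.DataFrame:
    """Map probes to promoter windows (TSS -upstream .. +downstream, strand-aware).

    Returns a DataFrame (probe_id, gene, offset) where ``offset`` is the
    signed distance from the TSS in transcription direction (negative =
    upstream).  Window endpoints are inclusive on both ends; probes outside
    every window are dropped.  A probe may map to several genes.
    """
    bad = set(ann["strand"]) - {"+", "-"}
    if bad:
        probes = ann.loc[ann["strand"].isin(bad), "probe_id"].tolist()
        raise ValueError(f"unknown strand for probes {probes[:5]}: {sorted(bad)}")
    offset = np.where(
        ann["strand"] == "+", ann["pos"] - ann["tss"], ann["tss"] - ann["pos"]
    )
    keep = (offset >= -upstream) & (offset <= downstream)
    out = pd.DataFrame(
        {
            "probe_id": ann.loc[keep, "probe_id"].to_numpy(),
            "gene": ann.loc[keep, "gene"].to_numpy(),
            "offset": offset[keep].astype(int),
        }
    )
    return out.reset_index(drop=True)


def fpkm_to_tpm(expr: PairedMatrix) -> PairedMatrix:
    """Rescale each sample so values sum to 1e6 (FPKM -> TPM).

    tpm_ij = fpkm_ij / sum_i fpkm_ij * 1e6.  Rank order within each sample is
    preserved; an all-zero sample column is an error.
    """
    vals = expr.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    colsum = vals.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"all-zero expression column(s): {list(zero.index)[:5]}")
    out = vals.div(colsum, axis=1) * 1e6
    return PairedMatrix(out, expr.pairing.copy())
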