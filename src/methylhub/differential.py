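"""Differential expression (DEG) and differential methylation (DMP/DMG) calls.

Both calls use a two-sided paired t-test across matched tumor/normal pairs and
a median-ratio (expression) or median-difference (methylation) effect size.
No multiple-testing correction is applied at this stage — features are called
at raw p < alpha, with FDR control deferred to the hub-enrichment stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import PairedMatrix
from .stats import paired_t

EXPR_PSEUDOCOUNT = 1.0  # TPM units
BETA_PSEUDOCOUNT = 1e-6  # guards the (unused-by-default) beta ratio


def call_degs(
    expr: PairedMatrix,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Call differentially expressed genes from a paired expression matrix.

    Effect size: log2 of the ratio of tumor to normal median expression over
    the matched samples, with pseudocount ``EXPR_PSEUDOCOUNT`` added to both
    medians.  p: two-sided paired t-test on log2(value + pseudocount) per pair
    (``log_scale=False`` tests the raw scale instead).  A gene is significant
    iff p < ``alpha`` and \\|log2fc\\| > ``lfc_min`` (both strict).

    Returns a DataFrame indexed by gene with columns median_tumor,
    median_normal, log2fc, p_value, direction, significant, zero_variance.
    """
    t_vals, n_vals = expr.tumor_normal_arrays()
    if t_vals.shape[1] < 2:
        raise ValueError("need at least 2 complete pairs")
    if (t_vals < 0).any() or (n_vals < 0).any():
        raise ValueError("expression must be non-negative")
    med_t = np.median(t_vals, axis=1)
    med_n = np.median(n_vals, axis=1)
    log2fc = np.log2(med_t + EXPR_PSEUDOCOUNT) - np.log2(med_n + EXPR_PSEUDOCOUNT)
    if log_scale:
        x, y = np.log2(t_vals + EXPR_PSEUDOCOUNT), np.log2(n_vals + EXPR_PSEUDOCOUNT)
    else:
        x, y = t_vals, n_vals
    _, p, zero_var = paired_t(x, y)
    sig = (p < alpha) & (np.abs(log2fc) > lfc_min)
    return pd.DataFrame(
        {
            "median_tumor": med_t,
            "median_normal": med_n,
            "log2fc": log2fc,
            "p_value": p,
            "direction": np.where(log2fc > 0, "up", "down"),
            "significant": sig,
            "zero_variance": zero_var,
        },
        index=expr.feature_ids.rename("gene"),
    )


def call_dmps(
    beta: PairedMatrix, alpha: float = 0.05, m_values: bool = False
) -> pd.DataFrame:
    """Call differentially methylated positions from a paired beta matrix.

    Effect size: delta_beta = median(tumor) − median(normal).  p: two-sided
    paired t-test on beta values (``m_values=True`` tests on
    log2(beta/(1−beta)) instead; the effect size stays on the beta scale).
    Significant iff p < alpha (strict).
    """
    t_vals, n_vals = beta.tumor_normal_arrays()
    if t_vals.shape[1] < 2:
        raise ValueError("need at least 2 complete pairs")
    med_t = np.median(t_vals, axis=1)
    med_n = np.median(n_vals, axis=1)
    delta = med_t - med_n
    if m_values:
        eps = BETA_PSEUDOCOUNT
        x = np.log2((t_vals + eps) / (1 - t_vals + eps))
        y = np.log2((n_vals + eps) / (1 - n_vals + eps))
    else:
        x, y = t_vals, n_vals
    _, p, zero_var = paired_t(x, y)
    return pd.DataFrame(
        {
            "median_tumor": med_t,
            "median_normal": med_n,
            "delta_beta": delta,
            "p_value": p,
            "direction": np.where(delta > 0, "up", "down"),
            "significant": p < alpha,
            "zero_variance": zero_var,
        },
        index=beta.feature_ids.rename("probe_id"),
    )


def consolidate_dmgs(dmps: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Collapse significant promoter DMPs into differentially methylated genes.

    A gene whose significant promoter DMPs all share one direction gets that
    direction with ``n_dmps`` = their count and their ids as valid DMPs; a
    gene with mixed-sign DMPs is marked ``discordant`` (excluded downstream).
    Genes with zero significant DMPs are omitted.
    """
    sig = dmps.loc[dmps["significant"].astype(bool)]
    merged = assignments.merge(
        sig[["direction"]], left_on="probe_id", right_index=True, how="inner"
    )
    rows = []
    for gene, grp in merged.groupby("gene", sort=True):
        dirs = set(grp["direction"])
        direction = dirs.pop() if len(dirs) == 1 else "discordant"
        probe_ids = sorted(grp["probe_id"].unique())
        rows.append(
            {
                "gene": gene,
                "n_dmps": len(probe_ids),
                "direction": direction,
                "valid_dmp_ids": probe_ids,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_dmps", "direction", "valid_dmp_ids"]).set_index("gene") if rows else pd.DataFrame(
        columns=["n_dmps", "direction", "valid_dmp_ids"], index=pd.Index([], name="gene")
    )


def dmp_count_distribution(dmgs: pd.DataFrame) -> dict[int, int]:
    """Histogram {n_dmps: gene count} over direction-consistent DMGs."""
    if len(dmgs) == 0:
        return {}
    consistent = dmgs[dmgs["direction"] != "discordant"]
    counts = consistent["n_dmps"].value_counts().sort_index()
    return {int(k): int(v) for k, v in counts.items()}
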