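"""EI/ES gene classification.

Epigenetically induced (EI) genes are promoter-hypomethylated and
overexpressed in tumors; epigenetically suppressed (ES) genes are the
converse.  Candidates come from opposite-direction DEG/DMG calls and are
retained only when promoter methylation and expression are significantly
negatively correlated across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import PairedMatrix


def pair_candidates(degs: pd.DataFrame, dmgs: pd.DataFrame) -> pd.DataFrame:
    """Genes significant in both views with opposite directions.

    expr up + meth down -> EI candidate; expr down + meth up -> ES candidate.
    Discordant DMGs are excluded.  Returns (gene-indexed) deg_direction,
    dmg_direction, candidate_category, valid_dmp_ids.
    """
    sig_degs = degs.loc[degs["significant"].astype(bool)]
    consistent = dmgs[dmgs["direction"].isin(["up", "down"])]
    common = sig_degs.index.intersection(consistent.index)
    deg_dir = sig_degs.loc[common, "direction"]
    dmg_dir = consistent.loc[common, "direction"]
    opposite = deg_dir != dmg_dir
    genes = common[opposite]
    category = np.where(deg_dir[opposite] == "up", "EI", "ES")
    return pd.DataFrame(
        {
            "deg_direction": deg_dir[opposite],
            "dmg_direction": dmg_dir[opposite],
            "candidate_category": category,
            "valid_dmp_ids": consistent.loc[genes, "valid_dmp_ids"],
        },
        index=genes.rename("gene"),
    )


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    return float(r), float(p)


def correlation_filter(
    candidates: pd.DataFrame,
    beta: PairedMatrix,
    expr: PairedMatrix,
    method: str = "spearman",
    alpha: float = 0.05,
    tumor_only: bool = False,
) -> pd.DataFrame:
    """Retain candidates whose promoter methylation anticorrelates with expression.

    Per gene, each valid promoter DMP's beta is correlated with the gene's
    expression across all samples (tumor and normal jointly by default, which
    maximizes n at typical paired-cohort sizes; ``tumor_only=True``
    restricts).  The gene is classified EI/ES iff every valid DMP correlates
    negatively and the best (smallest-p) DMP reaches ``corr_p < alpha``
    (two-sided p with the sign requirement corr < 0).  Genes whose beta or
    expression vector is constant are dropped with reason ``constant_vector``.

    Returns a gene-indexed frame: category ({EI, ES, none}), deg_direction,
    dmg_direction, corr, corr_p, valid_dmp_used, drop_reason.
    """
    if tumor_only:
        samples = [s for s in beta.sample_ids if beta.pairing.loc[s, "status"] == "tumor"]
    else:
        samples = [s for s in beta.sample_ids]
    samples = [s for s in samples if s in set(expr.sample_ids)]
    if len(samples) < 3:
        raise ValueError("need >= 3 samples shared between beta and expression")
    rows = []
    for gene, cand in candidates.iterrows():
        e = expr.values.loc[gene, samples].to_numpy(float)
        best = None  # (p, r, probe)
        all_negative = True
        reason = ""
        for probe in cand["valid_dmp_ids"]:
            b = beta.values.loc[probe, samples].to_numpy(float)
            if np.ptp(b) == 0 or np.ptp(e) == 0:
                reason = "constant_vector"
                all_negative = False
                break
            r, p = _correlate(b, e, method)
            if not r < 0:
                all_negative = False
            if best is None or p < best[0]:
                best = (p, r, probe)
        retained = (
            best is not None
            and all_negative
            and best[1] < 0
            and best[0] < alpha
        )
        rows.append(
            {
                "gene": gene,
                "category": cand["candidate_category"] if retained else "none",
                "deg_direction": cand["deg_direction"],
                "dmg_direction": cand["dmg_direction"],
                "corr": best[1] if best is not None else np.nan,
                "corr_p": best[0] if best is not None else np.nan,
                "valid_dmp_used": best[2] if best is not None else "",
                "drop_reason": reason if reason else ("" if retained else "correlation_filter"),
            }
        )
    cols = ["category", "deg_direction", "dmg_direction", "corr", "corr_p", "valid_dmp_used", "drop_reason"]
    if not rows:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="gene"))
    out = pd.DataFrame(rows).set_index("gene")
    out.loc[out["category"] != "none", "drop_reason"] = ""
    return out[cols]


def summarize_ei_es(calls: pd.DataFrame) -> dict:
    """Counts of EI and ES genes and their gene lists."""
    ei = sorted(calls.index[calls["category"] == "EI"])
    es = sorted(calls.index[calls["category"] == "ES"])
    assert not set(ei) & set(es)
    return {"n_EI": len(ei), "n_ES": len(es), "EI": ei, "ES": es}
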