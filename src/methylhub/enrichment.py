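"""Gene-set over-representation and term-crosstalk edges.

Works on user-supplied GMT collections (GO/KEGG term databases themselves are
not bundled).  The hypergeometric tail is the same implementation used by the
hub-gene neighborhood test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, hypergeom_tail


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe.

    ``sets`` maps term id -> (term name, frozenset of genes); every stored
    set is non-empty and a subset of ``universe``.
    """

    sets: dict[str, tuple[str, frozenset]]
    universe: frozenset

    @classmethod
    def from_gmt(cls, path, universe=None) -> "GeneSetCollection":
        """Parse a GMT file (term, description, then tab-separated genes).

        When ``universe`` is given, sets are intersected with it and empty
        results dropped; otherwise the universe is the union of all sets.
        """
        raw: dict[str, tuple[str, frozenset]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {lineno}: need term, description, >=1 gene")
                term, desc, genes = fields[0], fields[1], frozenset(g for g in fields[2:] if g)
                if not genes:
                    raise ValueError(f"{path}: line {lineno}: empty gene set {term!r}")
                raw[term] = (desc, genes)
        if universe is None:
            universe = frozenset().union(*(g for _, g in raw.values()))
        else:
            universe = frozenset(universe)
            raw = {
                t: (d, g & universe) for t, (d, g) in raw.items() if g & universe
            }
        return cls(raw, universe)


def over_representation(
    query, gsc: GeneSetCollection, alpha_fdr: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against a collection.

    Per term: p = P(X >= k), X ~ Hypergeom(N, K, n) with N = universe size,
    K = term size, n = query size (after restriction to the universe),
    k = overlap.  BH FDR across terms; rows sorted by ascending p.
    """
    query = set(query)
    dropped = query - gsc.universe
    query &= gsc.universe
    if not query:
        raise ValueError("query empty after restriction to the universe")
    N, n = len(gsc.universe), len(query)
    rows = []
    for term, (name, genes) in gsc.sets.items():
        k = len(query & genes)
        rows.append((term, name, k, n, len(genes), N))
    df = pd.DataFrame(rows, columns=["term", "name", "k", "n", "K", "N"]).set_index("term")
    df["p"] = hypergeom_tail(df["k"].to_numpy(), N, df["K"].to_numpy(), n)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["fdr"] < alpha_fdr
    df.attrs["n_query_dropped"] = len(dropped)
    return df.sort_values("p")


def term_jaccard_edges(
    results: pd.DataFrame, gsc: GeneSetCollection, j_min: float = 0.5
) -> pd.DataFrame:
    """Crosstalk edges between significant terms with Jaccard >= j_min.

    J(A, B) = |A n B| / |A u B| over the terms' gene sets; the boundary is
    inclusive.  Returns (term_a, term_b, jaccard) with term_a < term_b.
    """
    if len(results) == 0:
        raise ValueError("no enrichment results provided")
    terms = sorted(results.index[results["significant"]]) if "significant" in results else sorted(results.index)
    rows = []
    for i, ta in enumerate(terms):
        a = gsc.sets[ta][1]
        for tb in terms[i + 1 :]:
            b = gsc.sets[tb][1]
            union = len(a | b)
            j = len(a & b) / union if union else 0.0
            if j >= j_min:
                rows.append((ta, tb, j))
    return pd.DataFrame(rows, columns=["term_a", "term_b", "jaccard"])
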