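"""PPI-neighborhood enrichment and hub-gene calling.

For every network gene, the direct-neighbor set is tested for enrichment of
EI/ES genes against the whole network by Fisher's exact test on

    [[a, m - a], [K - a, N - m - K + a]]

with a = EI/ES neighbors, m = degree, K = EI/ES genes present in the network
and N = network size.  Hubs are nodes with FDR < fdr_max and a >= min_hits
EI/ES neighbors.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .stats import bh_fdr, fisher_two_sided, hypergeom_tail


def load_ppi(path) -> nx.Graph:
    """Read a two-column (HIPPIE-style) edge list into an undirected graph.

    Extra columns are ignored; duplicate edges are merged; self-loops are
    dropped (their count is recorded as ``G.graph["n_self_loops"]``).
    """
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: malformed edge at line {lineno}: {line!r}")
            u, v = fields[0], fields[1]
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty network")
    g.graph["n_self_loops"] = n_loops
    return g


def extract_subnet(net: nx.Graph, eies_genes: set) -> tuple[nx.Graph, dict]:
    """Induced subgraph on the EI/ES genes plus a mapping report.

    The report counts genes mapped into the network, genes with at least one
    interaction *within* the subnet, and the subnet's mean neighbor count.
    """
    mapped = sorted(set(eies_genes) & set(net.nodes))
    sub = net.subgraph(mapped).copy()
    degs = [d for _, d in sub.degree()]
    report = {
        "n_input": len(set(eies_genes)),
        "n_mapped": len(mapped),
        "n_with_interactions": int(sum(d >= 1 for d in degs)),
        "mean_degree": float(np.mean(degs)) if degs else 0.0,
    }
    return sub, report


def degree_distribution(net: nx.Graph) -> pd.DataFrame:
    """Exact (degree, node count) histogram with a heavy-tail summary.

    The monotone-decay check (node counts non-increasing over the upper half
    of occupied degrees) is reported in ``df.attrs["tail_monotone_frac"]``,
    not enforced.
    """
    degs = pd.Series(dict(net.degree()), dtype=int)
    hist = degs.value_counts().sort_index()
    df = pd.DataFrame({"degree": hist.index.to_numpy(), "n_nodes": hist.to_numpy()})
    if len(df) > 1:
        tail = df["n_nodes"].to_numpy()[len(df) // 2 :]
        steps = np.diff(tail)
        df.attrs["tail_monotone_frac"] = float((steps <= 0).mean()) if len(steps) else 1.0
    else:
        df.attrs["tail_monotone_frac"] = 1.0
    return df


def neighborhood_fisher(
    net: nx.Graph,
    eies_genes: set,
    gene,
    alternative: str = "greater",
) -> dict:
    """Fisher enrichment of EI/ES genes in one gene's direct neighborhood.

    The focal gene is excluded from its own neighborhood and, when itself
    EI/ES, from the marked total K.  ``alternative``: ``"greater"`` is the
    one-sided enrichment tail P(X >= a); ``"two-sided"`` the two-sided
    Fisher exact p.  Degree-0 genes get p = 1.
    """
    if gene not in net:
        raise KeyError(f"gene not in network: {gene}")
    present = set(eies_genes) & set(net.nodes)
    neighbors = set(net.neighbors(gene)) - {gene}
    a = len(neighbors & present)
    m = len(neighbors)
    K = len(present - {gene})
    N = net.number_of_nodes()
    if m == 0:
        p = 1.0
    elif alternative == "greater":
        p = float(hypergeom_tail(a, N, K, m))
    elif alternative == "two-sided":
        p = fisher_two_sided(a, N, K, m)
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return {
        "gene": gene,
        "a": a,
        "b": m - a,
        "K": K,
        "N": N,
        "neighborhood_frac": a / m if m else 0.0,
        "fisher_p": p,
    }


def neighborhood_fisher_all(
    net: nx.Graph,
    eies_genes: set,
    genes=None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Vectorized :func:`neighborhood_fisher` over many genes.

    ``genes`` defaults to all network nodes with degree >= 1 (the tested
    family over which FDR is later controlled).
    """
    present = set(eies_genes) & set(net.nodes)
    N = net.number_of_nodes()
    if genes is None:
        genes = [g for g, d in net.degree() if d >= 1]
    rows = []
    for g in genes:
        neigh = set(net.neighbors(g)) - {g}
        a = len(neigh & present)
        m = len(neigh)
        rows.append((g, a, m - a, len(present - {g}), m))
    df = pd.DataFrame(rows, columns=["gene", "a", "b", "K", "m"]).set_index("gene")
    if alternative == "greater":
        # group by K (differs only by focal-gene membership) for vector calls
        p = np.ones(len(df))
        for K, grp in df.groupby("K"):
            p[df.index.get_indexer(grp.index)] = hypergeom_tail(
                grp["a"].to_numpy(), N, int(K), grp["m"].to_numpy()
            )
    else:
        p = np.array(
            [
                fisher_two_sided(int(r.a), N, int(r.K), int(r.m))
                for r in df.itertuples()
            ]
        )
    p = np.where(df["m"].to_numpy() == 0, 1.0, p)
    out = df.assign(
        N=N,
        neighborhood_frac=np.where(df["m"] > 0, df["a"] / df["m"].replace(0, 1), 0.0),
        fisher_p=np.minimum(p, 1.0),
    ).drop(columns=["m"])
    return out


def call_hubs(
    stats: pd.DataFrame, fdr_max: float = 0.05, min_hits: int = 5
) -> pd.DataFrame:
    """BH-adjust the neighborhood Fisher p-values and flag hubs.

    A hub satisfies fdr < ``fdr_max`` and a >= ``min_hits`` EI/ES neighbors.
    Returns the input with ``fdr`` and ``is_hub`` columns, hubs sorted first
    by ascending fisher_p.
    """
    out = stats.copy()
    out["fdr"] = bh_fdr(out["fisher_p"].to_numpy()) if len(out) else []
    out["is_hub"] = (out["fdr"] < fdr_max) & (out["a"] >= min_hits)
    return out.sort_values(["is_hub", "fisher_p"], ascending=[False, True])
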