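"""Hub-gene identification on a protein-protein interaction graph.

Betweenness centrality counts, for every node, the shortest paths between
other node pairs that pass through it (fractional credit when several
equal-length paths exist).  Genes with high betweenness bridge otherwise
separate modules and are reported as network hubs.  Both the raw
unordered-pair-count convention and the 2/((n-1)(n-2)) normalized value are
reported, since tools differ in which they print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .io import GraphEdgeList

CENTRALITY_COLUMNS = ["gene", "betweenness", "betweenness_norm", "degree", "rank"]


@dataclass
class CentralityTable:
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CENTRALITY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"centrality table missing columns: {missing}")
        self.table = self.table[CENTRALITY_COLUMNS].reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _centrality_frame(g: nx.Graph) -> pd.DataFrame:
    n = g.number_of_nodes()
    raw = nx.betweenness_centrality(g, normalized=False)
    norm = nx.betweenness_centrality(g, normalized=True) if n > 2 else {v: 0.0 for v in g}
    rows = [
        {
            "gene": v,
            "betweenness": raw[v],
            "betweenness_norm": norm[v],
            "degree": g.degree(v),
        }
        for v in g.nodes
    ]
    df = pd.DataFrame(rows, columns=CENTRALITY_COLUMNS[:-1])
    # rank by betweenness, ties by degree then gene id (deterministic)
    df = df.sort_values(
        by=["betweenness", "degree", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


def betweenness(edges: GraphEdgeList) -> CentralityTable:
    """Exact shortest-path betweenness for every node in the graph.

    Disconnected graphs are handled naturally: pairs in different components
    contribute nothing.  An empty graph yields an empty table.
    """
    g = edges.to_networkx()
    if g.number_of_nodes() == 0:
        return CentralityTable(pd.DataFrame(columns=CENTRALITY_COLUMNS))
    return CentralityTable(_centrality_frame(g))


def hub_genes(
    edges: GraphEdgeList, genes, top_k: int = 20
) -> CentralityTable:
    """Top hub genes by betweenness on the subgraph induced by ``genes``.

    Typical use: rank the cross-species concordant genes on the PPI network
    to find central proteins.  If ``top_k`` exceeds the induced node count,
    all nodes are returned with a warning.
    """
    genes = set(genes)
    g = edges.to_networkx().subgraph(genes).copy()
    if g.number_of_nodes() == 0:
        return CentralityTable(pd.DataFrame(columns=CENTRALITY_COLUMNS))
    df = _centrality_frame(g)
    if top_k > len(df):
        warnings.warn(
            f"top_k={top_k} exceeds induced subgraph size {len(df)}; returning all"
        )
        top_k = len(df)
    return CentralityTable(df.head(top_k))
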