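"""miRNA-target x differential-protein network integration.

Edges connect a differentially expressed miRNA to a differentially expressed
protein whose gene is among the miRNA's predicted targets. An edge is flagged
concordant when the two directions oppose (up-miRNA with down-protein or
vice versa), the pattern expected if the miRNA represses the protein's
transcript. Both concordant and discordant edges are kept; filtering is an
explicit option.
"""

from __future__ import annotations

import pandas as pd

EDGE_COLUMNS = ["mirna_id", "protein_id", "mirna_direction", "protein_direction", "concordant"]


def build_network(
    demirnas: pd.DataFrame,
    targets: pd.DataFrame,
    deps: pd.DataFrame,
    symbol_map: dict[str, str] | None = None,
    concordant_only: bool = False,
) -> pd.DataFrame:
    """Bipartite edge list between DE miRNAs and DE proteins they target.

    Parameters
    ----------
    demirnas:
        Differential miRNA table indexed by feature id with a ``direction``
        column; only rows with direction != "ns" are used.
    targets:
        Target table with columns mirna_id, gene_id (e.g. from
        ``predict_targets`` or a user-supplied export).
    deps:
        Differential protein table indexed by protein id with a ``direction``
        column; only rows with direction != "ns" are used.
    symbol_map:
        Optional gene_id -> protein_id mapping; by default gene and protein
        identifiers are matched by exact symbol after uppercasing.

    Returns the edge list sorted by (mirna_id, protein_id) with the
    concordance flag (True iff directions oppose).
    """
    de_mir = demirnas.loc[demirnas["direction"] != "ns", "direction"]
    de_prot = deps.loc[deps["direction"] != "ns", "direction"]
    prot_by_key = {str(p).upper(): p for p in de_prot.index}

    def to_protein(gene_id: str):
        if symbol_map is not None and gene_id in symbol_map:
            mapped = symbol_map[gene_id]
            return mapped if mapped in de_prot.index else None
        return prot_by_key.get(str(gene_id).upper())

    rows = []
    pairs = targets[targets["mirna_id"].isin(de_mir.index)][["mirna_id", "gene_id"]]
    for mirna_id, gene_id in pairs.drop_duplicates().itertuples(index=False):
        protein_id = to_protein(gene_id)
        if protein_id is None:
            continue
        md, pdir = de_mir[mirna_id], de_prot[protein_id]
        rows.append(
            {
                "mirna_id": mirna_id,
                "protein_id": protein_id,
                "mirna_direction": md,
                "protein_direction": pdir,
                "concordant": md != pdir,
            }
        )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS).drop_duplicates(["mirna_id", "protein_id"])
    if concordant_only:
        edges = edges[edges["concordant"]]
    return edges.sort_values(["mirna_id", "protein_id"]).reset_index(drop=True)


def edge_summary(edges: pd.DataFrame) -> dict:
    """Per-miRNA distinct DE-protein partner counts plus the total edge count."""
    dedup = edges.drop_duplicates(["mirna_id", "protein_id"])
    counts = dedup.groupby("mirna_id")["protein_id"].nunique().to_dict()
    return {
        "per_mirna": {str(k): int(v) for k, v in sorted(counts.items())},
        "n_edges": int(len(dedup)),
        "n_concordant": int(dedup["concordant"].sum()) if len(dedup) else 0,
    }


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Export the bipartite network as GraphML (node kind + edge concordance)."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(f"miRNA:{row.mirna_id}", kind="miRNA", direction=row.mirna_direction)
        g.add_node(f"protein:{row.protein_id}", kind="protein", direction=row.protein_direction)
        g.add_edge(
            f"miRNA:{row.mirna_id}",
            f"protein:{row.protein_id}",
            concordant=bool(row.concordant),
        )
    nx.write_graphml(g, path)
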