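"""GMT gene-set collections and the shared-gene gene-set graph.

Significant gene sets become nodes (annotated with their regulation
direction), and two sets are joined by an undirected edge when they share at
least ``min_shared`` genes, with the shared-gene count as the edge weight.
Sets that share many genes therefore sit in densely connected neighbourhoods
of the graph; the layout itself is a rendering concern and is left to
whatever tool consumes the GraphML output.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["read_gmt", "write_gmt", "build_geneset_graph", "write_graphml"]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a tab-delimited GMT file: set name, description, member genes."""
    gene_sets: dict[str, list[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"malformed GMT line {line_no}: expected name, description, >=1 gene"
            )
        name = fields[0]
        if name in gene_sets:
            raise ValueError(f"duplicate gene set name in GMT: {name!r}")
        gene_sets[name] = [g for g in fields[2:] if g]
    return gene_sets


def write_gmt(
    gene_sets: dict[str, list[str]], path: str | Path, description: str = "na"
) -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, description, *genes]) for name, genes in gene_sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def build_geneset_graph(
    significant: pd.DataFrame,
    memberships: dict[str, list[str]],
    min_shared: int = 1,
    category_keywords: dict[str, list[str]] | None = None,
) -> nx.Graph:
    """Shared-gene graph over the significant gene sets.

    ``significant`` is a per-set result table (e.g. from
    :func:`radscreen.transcriptomics.differential_gene_sets`) restricted to —
    or carrying a ``significant`` flag for — the sets to plot; ``memberships``
    maps every one of those sets to its member genes. Edge weight is the
    pairwise intersection size; pairs sharing fewer than ``min_shared`` genes
    get no edge. Optional ``category_keywords`` ({tag: [substring, ...]})
    annotate nodes whose set name contains a keyword (case-insensitive).
    """
    if "significant" in significant.columns:
        significant = significant[significant["significant"]]
    node_ids = list(significant.index)

    missing = [s for s in node_ids if s not in memberships]
    if missing:
        raise ValueError(f"no membership list for gene sets: {missing[:5]}")

    graph = nx.Graph()
    for set_id in node_ids:
        attrs = {"n_genes": len(memberships[set_id])}
        for col in ("direction", "mean_difference", "p_adjusted"):
            if col in significant.columns:
                attrs[col] = significant.loc[set_id, col]
        if category_keywords:
            tags = [
                tag
                for tag, words in category_keywords.items()
                if any(w.lower() in set_id.lower() for w in words)
            ]
            attrs["category"] = ";".join(tags) if tags else ""
        graph.add_node(set_id, **attrs)

    members = {s: set(memberships[s]) for s in node_ids}
    for i, a in enumerate(node_ids):
        for b in node_ids[i + 1 :]:
            shared = len(members[a] & members[b])
            if shared >= max(1, min_shared):
                graph.add_edge(a, b, weight=shared)
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    sanitized = nx.Graph()
    sanitized.add_nodes_from(
        (n, {k: _graphml_value(v) for k, v in d.items()}) for n, d in graph.nodes(data=True)
    )
    sanitized.add_edges_from(
        (u, v, {k: _graphml_value(w) for k, w in d.items()})
        for u, v, d in graph.edges(data=True)
    )
    nx.write_graphml(sanitized, path)
    return path


def _graphml_value(value):
    # GraphML supports only plain scalar types
    try:
        import numpy as np

        if isinstance(value, np.generic):
            return value.item()
    except ImportError:  # pragma: no cover
        pass
    return value
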