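"""Residue-level stabilization-center connectivity graphs.

SC dynamics of all subunits over a run are summarized into one graph:
nodes are chain-aggregated residue labels (e.g. "65C"), an edge is an SC
observed between two residue positions, node weight counts SC
participations (instances over subunit pairs), and edge weight is the
stability fraction averaged over the subunit instances of that SC. Cys
nodes are flagged so the disulfide-centred connectivity patterns stand out.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .core import GJDockError
from .interactions import residue_label


def build_sc_graph(table: pd.DataFrame, per_chain: bool = False) -> nx.Graph:
    """Collapse a stability table into a residue-level SC graph.

    Each table row (one residue pair on one subunit-pair instance)
    contributes one participation to each of its residues; multi-instance
    edges carry the mean stability fraction and the instance count.
    With ``per_chain`` nodes keep their chain prefix instead of being
    aggregated by residue number.

    Node attributes: ``weight`` (participations), ``is_cys``.
    Edge attributes: ``weight`` (mean fraction), ``n_instances``.
    """
    g = nx.Graph()
    if table.empty:
        return g
    required = {"res_a", "name_a", "res_b", "name_b", "fraction"}
    missing = required - set(table.columns)
    if missing:
        raise GJDockError(f"stability table lacks column(s) {sorted(missing)}")

    def node_key(row, side: str) -> str:
        label = residue_label(int(row[f"res_{side}"]), str(row[f"name_{side}"]))
        if per_chain:
            return f"{row[f'chain_{side}']}:{label}"
        return label

    edge_fracs: dict[tuple[str, str], list[float]] = {}
    node_count: dict[str, int] = {}
    node_cys: dict[str, bool] = {}
    for _, row in table.iterrows():
        na, nb = node_key(row, "a"), node_key(row, "b")
        for n, res_name in ((na, row["name_a"]), (nb, row["name_b"])):
            node_count[n] = node_count.get(n, 0) + 1
            node_cys[n] = node_cys.get(n, False) or str(res_name) == "CYS"
        key = tuple(sorted((na, nb)))
        edge_fracs.setdefault(key, []).append(float(row["fraction"]))
    for n, w in node_count.items():
        g.add_node(n, weight=w, is_cys=bool(node_cys[n]))
    for (na, nb), fracs in edge_fracs.items():
        g.add_edge(na, nb, weight=sum(fracs) / len(fracs),
                   n_instances=len(fracs))
    return g


def connected_modules(graph: nx.Graph, min_node_weight: int = 0) -> list[set[str]]:
    """Connected components after dropping nodes below a weight threshold."""
    keep = [n for n, d in graph.nodes(data=True)
            if d.get("weight", 0) >= min_node_weight]
    sub = graph.subgraph(keep)
    return [set(c) for c in nx.connected_components(sub)]


def export_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the graph as GraphML or an edge-list TSV (attributes preserved)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        rows = [{
            "node_a": a, "node_b": b,
            "weight": d["weight"], "n_instances": d["n_instances"],
            "is_cys_a": graph.nodes[a].get("is_cys", False),
            "is_cys_b": graph.nodes[b].get("is_cys", False),
        } for a, b, d in graph.edges(data=True)]
        pd.DataFrame(
            rows, columns=["node_a", "node_b", "weight", "n_instances",
                           "is_cys_a", "is_cys_b"],
        ).to_csv(path, sep="\t", index=False)
    else:
        raise GJDockError(f"unknown graph format {format!r}")


def import_graph(path: str | Path) -> nx.Graph:
    """Read back a GraphML export (node/edge attributes typed)."""
    g = nx.read_graphml(str(path))
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(str(n), weight=int(d.get("weight", 0)),
                     is_cys=bool(d.get("is_cys", False)))
    for a, b, d in g.edges(data=True):
        out.add_edge(str(a), str(b), weight=float(d.get("weight", 0.0)),
                     n_instances=int(d.get("n_instances", 1)))
    return out
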