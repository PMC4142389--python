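"""Export coexpression networks of mapped pairs as SIF / GraphML.

Each gene set x pair class yields an undirected graph: nodes are genes,
edges the mapped pairs, carrying both groups' coexpression levels and the
class label. A node attribute flags genes shared between several sets'
networks.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

SIF_RELATION = "coexpressed_with"
FORMATS = ("sif", "graphml")


def build_network(set_name: str, mapped: set[tuple[str, str]],
                  table: pd.DataFrame, class_label: str = "normal_specific_strong"
                  ) -> nx.Graph:
    """Undirected graph over the endpoint genes of the mapped pairs.

    Edge attributes (c_normal, c_disease, class label) are copied from the
    pair table; an empty pair set yields a valid empty network.
    """
    g = nx.Graph(name=set_name, pair_class=class_label)
    if not mapped:
        logger.info("set %r: empty mapped pair set, emitting empty network", set_name)
        return g
    idx = table.set_index(["gene_i", "gene_j"])
    for u, v in sorted(mapped):
        if u == v:
            raise ValueError(f"self-loop pair ({u}, {u})")
        if (u, v) not in idx.index:
            raise KeyError(f"pair ({u}, {v}) absent from the coexpression table")
        row = idx.loc[(u, v)]
        g.add_edge(u, v,
                   c_normal=float(row["c_normal"]),
                   c_disease=float(row["c_disease"]),
                   pair_class=class_label)
    nx.set_node_attributes(g, False, "member_of_both_networks")
    return g


def flag_shared_genes(networks: list[nx.Graph]) -> None:
    """Mark genes appearing in more than one network (in place)."""
    seen: dict[str, int] = {}
    for net in networks:
        for node in net.nodes:
            seen[node] = seen.get(node, 0) + 1
    for net in networks:
        for node in net.nodes:
            net.nodes[node]["member_of_both_networks"] = seen[node] > 1


def write_network(net: nx.Graph, path: str | Path, format: str = "sif") -> None:
    """Write a network as SIF (one ``A coexpressed_with B`` line per edge)
    or GraphML (round-trippable, attributes preserved)."""
    fmt = format.lower()
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(net.edges):
                fh.write(f"{u}\t{SIF_RELATION}\t{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown format {format!r}; supported: {FORMATS}")


def export_mapped_networks(set_pairs: dict[str, set[tuple[str, str]]],
                           cls: pd.DataFrame, out_dir: str | Path,
                           class_label: str = "normal_specific_strong",
                           formats: tuple[str, ...] = FORMATS) -> list[Path]:
    """Build and write one network per gene set for the chosen pair class.

    ``set_pairs`` maps set name -> its annotated pairs; only pairs carrying
    the requested class flag become edges. Files are named
    ``<set>__<class>.<ext>``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    flagged = cls[cls[class_label]]
    class_universe = set(zip(flagged["gene_i"], flagged["gene_j"]))
    graphs = {}
    for set_name in sorted(set_pairs):
        mapped = set_pairs[set_name] & class_universe
        graphs[set_name] = build_network(set_name, mapped, cls, class_label)
    flag_shared_genes(list(graphs.values()))
    written: list[Path] = []
    for set_name, g in graphs.items():
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in set_name)
        for fmt in formats:
            p = out_dir / f"{safe}__{class_label}.{fmt}"
            write_network(g, p, fmt)
            written.append(p)
    return written
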