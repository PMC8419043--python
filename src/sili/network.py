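"""Typed bipartite / three-layer network construction and serialisation.

Nodes are typed TSG / DT / drug; edges are typed "sl" (TSG-DT) or
"targets" (drug-DT). Construction validates the bipartite constraints; the
exporters (GraphML, SIF, edge TSV) write nodes and edges in deterministic
order so identical inputs yield byte-identical files.
"""
from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import ValidationError

NODE_TYPES = ("TSG", "DT", "drug")
EDGE_TYPES = {"sl": ("TSG", "DT"), "targets": ("drug", "DT")}


def build_network(
    candidates: pd.DataFrame, triples: pd.DataFrame | None = None
) -> nx.Graph:
    """Build the TSG-DT (and optionally drug-layer) network.

    ``candidates`` needs columns tsg/target and may carry statistics (ras,
    fs_score, hazard_ratio...) copied onto SL edges. ``triples`` needs
    tsg/target/drug and may carry median_auc_diff, copied onto drug nodes
    and targets edges.
    """
    g = nx.Graph()
    for _, row in candidates.iterrows():
        tsg, dt = str(row["tsg"]), str(row["target"])
        if tsg == dt:
            raise ValidationError(f"self-loop candidate {tsg}")
        g.add_node(tsg, node_type="TSG")
        g.add_node(dt, node_type="DT")
        attrs = {"edge_type": "sl"}
        for col in ("fs_score", "log2_fold_change", "spearman_rho", "hazard_ratio", "ras", "q"):
            if col in row.index and pd.notna(row[col]):
                attrs[col] = float(row[col])
        g.add_edge(tsg, dt, **attrs)
    if triples is not None:
        for _, row in triples.iterrows():
            dt, drug = str(row["target"]), str(row["drug"])
            if dt not in g or g.nodes[dt].get("node_type") != "DT":
                raise ValidationError(f"triple references unknown target {dt}")
            g.add_node(drug, node_type="drug")
            if "median_auc_diff" in row.index and pd.notna(row["median_auc_diff"]):
                g.nodes[drug]["median_auc_diff"] = float(row["median_auc_diff"])
            g.add_edge(drug, dt, edge_type="targets")
    _validate(g)
    # RAS-best per node, then degrees (after the full edge set is known)
    for node in g.nodes:
        ras_vals = [
            d["ras"] for _, _, d in g.edges(node, data=True) if "ras" in d
        ]
        if ras_vals:
            g.nodes[node]["ras_best"] = max(ras_vals)
        g.nodes[node]["degree"] = g.degree(node)
    return g


def _validate(g: nx.Graph) -> None:
    for u, v, data in g.edges(data=True):
        et = data.get("edge_type")
        if et not in EDGE_TYPES:
            raise ValidationError(f"untyped edge {u}-{v}")
        want = set(EDGE_TYPES[et])
        got = {g.nodes[u].get("node_type"), g.nodes[v].get("node_type")}
        if got != want:
            raise ValidationError(f"edge {u}-{v} of type {et} joins {sorted(got)}")
        if u == v:
            raise ValidationError(f"self-loop at {u}")


def _ordered_copy(g: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    for node in sorted(g.nodes):
        out.add_node(node, **g.nodes[node])
    for u, v in sorted(tuple(sorted(e)) for e in g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    return out


def export_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(_ordered_copy(g), str(path))


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))


def export_sif(g: nx.Graph, path) -> None:
    """Cytoscape SIF lines: source <tab> relation <tab> target.

    SL edges are written TSG -> DT, target edges drug -> DT.
    """
    lines = []
    for u, v, data in g.edges(data=True):
        et = data["edge_type"]
        src_type = EDGE_TYPES[et][0]
        src, dst = (u, v) if g.nodes[u]["node_type"] == src_type else (v, u)
        lines.append(f"{src}\t{et}\t{dst}")
    Path(path).write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))


def export_edge_tsv(g: nx.Graph, path) -> None:
    """Edge list TSV with all edge attributes, SL edges sorted by RAS descending."""
    rows = []
    for u, v, data in g.edges(data=True):
        et = data["edge_type"]
        src_type = EDGE_TYPES[et][0]
        src, dst = (u, v) if g.nodes[u]["node_type"] == src_type else (v, u)
        rows.append({"source": src, "edge_type": et, "target": dst, **{
            k: v2 for k, v2 in data.items() if k != "edge_type"
        }})
    df = pd.DataFrame(rows)
    if not df.empty:
        if "ras" not in df.columns:
            df["ras"] = float("nan")
        df = df.sort_values(
            ["edge_type", "ras", "source", "target"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
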