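"""Gene Ontology semantic similarity (Wang's graph-based measure) and the
functional-similarity (FS) score used as the pipeline's first screen.

The FS score of a gene pair is the geometric mean of the gene-level
semantic similarities in the molecular-function (MF) and cellular-component
(CC) aspects; pairs with FS > 0.5 are treated as functionally close.

Wang's measure assigns each ancestor ``a`` of a term ``t`` an S-value: the
maximum, over directed paths from ``t`` up to ``a``, of the product of edge
weights (is_a 0.8, part_of 0.6), with S(t)=1. The similarity of two terms is
the summed S-values of their shared ancestors (and the terms themselves if
shared) divided by the two total S-masses. Gene-level similarity combines
term similarities by best-match averaging (BMA).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import SiliError

log = logging.getLogger(__name__)

ASPECTS = ("MF", "CC", "BP")
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}
_NAMESPACE_TO_ASPECT = {
    "molecular_function": "MF",
    "cellular_component": "CC",
    "biological_process": "BP",
}
_ASPECT_TO_NAMESPACE = {v: k for k, v in _NAMESPACE_TO_ASPECT.items()}
_GAF_ASPECT = {"F": "MF", "C": "CC", "P": "BP"}


class OntologyError(SiliError):
    pass


@dataclass
class OntologyGraph:
    """Term DAG (edges child -> parent) with per-aspect gene annotations.

    graph: networkx DiGraph; edge attribute ``relation`` in {is_a, part_of}.
    aspect: term -> aspect label.
    annotations: aspect -> gene -> frozenset of terms.
    """

    graph: nx.DiGraph
    aspect: dict[str, str]
    annotations: dict[str, dict[str, frozenset]] = field(default_factory=dict)
    edge_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EDGE_WEIGHTS))

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OntologyError("ontology graph contains a cycle")
        for t in self.graph.nodes:
            if t not in self.aspect:
                raise OntologyError(f"term {t} has no aspect label")
        for asp, genes in self.annotations.items():
            for g, terms in genes.items():
                missing = [t for t in terms if t not in self.graph]
                if missing:
                    raise OntologyError(f"gene {g} annotated to unknown terms {missing[:3]}")
        self._svalue_cache: dict[str, dict[str, float]] = {}

    def terms_in_aspect(self, aspect: str) -> list[str]:
        return [t for t in self.graph.nodes if self.aspect[t] == aspect]

    def roots(self, aspect: str) -> list[str]:
        return [
            t
            for t in self.terms_in_aspect(aspect)
            if self.graph.out_degree(t) == 0
        ]

    def annotations_for(self, gene: str, aspect: str) -> frozenset:
        return self.annotations.get(aspect, {}).get(gene, frozenset())

    # -- Wang S-values -----------------------------------------------------
    def s_values(self, term: str) -> dict[str, float]:
        """S-value of every ancestor of ``term`` (term itself included, S=1)."""
        if term in self._svalue_cache:
            return self._svalue_cache[term]
        if term not in self.graph:
            raise OntologyError(f"unknown term {term}")
        closure = nx.descendants(self.graph, term) | {term}  # ancestors (child->parent)
        sub = self.graph.subgraph(closure)
        s = {term: 1.0}
        for node in nx.topological_sort(sub):
            if node not in s:
                continue
            for _, parent, data in sub.out_edges(node, data=True):
                w = self.edge_weights.get(data.get("relation", "is_a"), 0.0)
                cand = w * s[node]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        self._svalue_cache[term] = s
        return s


def term_similarity(t1: str, t2: str, graph: OntologyGraph) -> float:
    """Wang similarity of two terms from the same aspect, in [0, 1]."""
    if graph.aspect[t1] != graph.aspect[t2]:
        raise OntologyError(
            f"cross-aspect comparison: {t1} ({graph.aspect[t1]}) vs {t2} ({graph.aspect[t2]})"
        )
    s1 = graph.s_values(t1)
    s2 = graph.s_values(t2)
    common = set(s1) & set(s2)
    denom = sum(s1.values()) + sum(s2.values())
    if not common:
        return 0.0
    return sum(s1[t] + s2[t] for t in common) / denom


def gene_similarity(
    gene_a: str, gene_b: str, aspect: str, graph: OntologyGraph
) -> float:
    """Best-match-average gene similarity in one aspect; NaN if unannotated."""
    ta = sorted(graph.annotations_for(gene_a, aspect))
    tb = sorted(graph.annotations_for(gene_b, aspect))
    if not ta or not tb:
        return float("nan")
    sims = [[term_similarity(x, y, graph) for y in tb] for x in ta]
    row_max = [max(row) for row in sims]
    col_max = [max(sims[i][j] for i in range(len(ta))) for j in range(len(tb))]
    return (sum(row_max) + sum(col_max)) / (len(ta) + len(tb))


@dataclass(frozen=True)
class FSRecord:
    gene_a: str
    gene_b: str
    sim_mf: float
    sim_cc: float
    fs_score: float
    passes: bool


def fs_score(
    gene_a: str, gene_b: str, graph: OntologyGraph, threshold: float = 0.5
) -> FSRecord:
    """FS = sqrt(sim_MF * sim_CC); the screen passes when FS > threshold.

    Pairs with a missing aspect annotation get FS = NaN and fail the screen.
    """
    sim_mf = gene_similarity(gene_a, gene_b, "MF", graph)
    sim_cc = gene_similarity(gene_a, gene_b, "CC", graph)
    if math.isnan(sim_mf) or math.isnan(sim_cc):
        fs = float("nan")
        ok = False
    else:
        fs = math.sqrt(sim_mf * sim_cc)
        ok = fs > threshold
    return FSRecord(gene_a, gene_b, sim_mf, sim_cc, fs, ok)


def fs_table(pairs, graph: OntologyGraph, threshold: float = 0.5) -> pd.DataFrame:
    rows = [fs_score(a, b, graph, threshold) for a, b in pairs]
    return pd.DataFrame(
        {
            "gene_a": [r.gene_a for r in rows],
            "gene_b": [r.gene_b for r in rows],
            "sim_mf": [r.sim_mf for r in rows],
            "sim_cc": [r.sim_cc for r in rows],
            "fs_score": [r.fs_score for r in rows],
            "fs_pass": [r.passes for r in rows],
        }
    )


# -- OBO / GAF input-output -----------------------------------------------

def read_obo(path) -> tuple[nx.DiGraph, dict[str, str]]:
    """Read an OBO 1.2 ontology into (child->parent DiGraph, aspect map)."""
    import obonet

    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    aspect = {}
    for node, data in multi.nodes(data=True):
        g.add_node(node)
        ns = data.get("namespace", "molecular_function")
        aspect[node] = _NAMESPACE_TO_ASPECT.get(ns, "MF")
    for child, parent, rel in multi.edges(keys=True):
        if rel in ("is_a", "part_of"):
            g.add_edge(child, parent, relation=rel)
    return g, aspect


def read_gaf(path) -> dict[str, dict[str, frozenset]]:
    """Read a GAF 2.x annotation file into aspect -> gene -> terms.

    Uses columns 2 (gene), 4 (qualifier; NOT rows dropped), 5 (term) and
    9 (aspect).
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("!"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            continue
        gene, qualifier, term, asp = parts[1], parts[3], parts[4], parts[8]
        if "NOT" in qualifier:
            continue
        rows.append((_GAF_ASPECT.get(asp, asp), gene, term))
    out: dict[str, dict[str, set]] = {}
    for asp, gene, term in rows:
        out.setdefault(asp, {}).setdefault(gene, set()).add(term)
    return {
        asp: {g: frozenset(ts) for g, ts in genes.items()}
        for asp, genes in out.items()
    }


def load_ontology(obo_path, gaf_path) -> OntologyGraph:
    graph, aspect = read_obo(obo_path)
    annotations = read_gaf(gaf_path)
    return OntologyGraph(graph=graph, aspect=aspect, annotations=annotations)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialise the term DAG as a minimal OBO 1.2 document."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(graph.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {term}")
        lines.append(f"namespace: {_ASPECT_TO_NAMESPACE[graph.aspect[term]]}")
        for _, parent, data in sorted(graph.graph.out_edges(term, data=True)):
            rel = data.get("relation", "is_a")
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {parent}")
            else:
                lines.append(f"relationship: {rel} {parent} ! {parent}")
        lines.append("")
    lines += ["[Typedef]", "id: part_of", "name: part of", ""]
    Path(path).write_text("\n".join(lines))


def write_gaf(graph: OntologyGraph, path) -> None:
    """Serialise annotations as a minimal GAF 2.2 file."""
    rev = {v: k for k, v in _GAF_ASPECT.items()}
    lines = ["!gaf-version: 2.2"]
    for asp in sorted(graph.annotations):
        for gene in sorted(graph.annotations[asp]):
            for term in sorted(graph.annotations[asp][gene]):
                fields = [
                    "SILI", gene, gene, "", term, "SILI:0000", "IEA", "",
                    rev.get(asp, "F"), gene, "", "protein", "taxon:9606",
                    "20210101", "SILI", "", "",
                ]
                lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
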