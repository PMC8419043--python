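"""Wang term/gene similarity, the FS score, and format round-trips.

The independent oracle enumerates every directed path from a term to each
ancestor and takes the max product of edge weights — the definition of the
S-value — instead of the dynamic program the implementation uses.
"""
import math

import networkx as nx
import numpy as np
import pytest

from sili.ontology import (
    DEFAULT_EDGE_WEIGHTS,
    OntologyError,
    OntologyGraph,
    fs_score,
    gene_similarity,
    load_ontology,
    term_similarity,
    write_gaf,
    write_obo,
)


def brute_force_s_values(graph: OntologyGraph, term: str) -> dict[str, float]:
    """Max-over-paths product of edge weights: exhaustive path enumeration."""
    out = {term: 1.0}
    for anc in nx.descendants(graph.graph, term):
        best = 0.0
        for path in nx.all_simple_paths(graph.graph, term, anc):
            w = 1.0
            for u, v in zip(path, path[1:]):
                rel = graph.graph.edges[u, v].get("relation", "is_a")
                w *= graph.edge_weights[rel]
            best = max(best, w)
        out[anc] = best
    return out


def brute_force_term_similarity(t1, t2, graph):
    s1 = brute_force_s_values(graph, t1)
    s2 = brute_force_s_values(graph, t2)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    return sum(s1[t] + s2[t] for t in common) / (sum(s1.values()) + sum(s2.values()))


def random_dag(rng, n_terms: int) -> OntologyGraph:
    """Random single-aspect DAG: each non-root term gets 1-2 parents among
    earlier terms, with random is_a/part_of relations."""
    g = nx.DiGraph()
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    g.add_node(terms[0])
    for i, t in enumerate(terms[1:], 1):
        g.add_node(t)
        n_parents = 1 + int(rng.random() < 0.4 and i > 1)
        for p in rng.choice(i, size=min(n_parents, i), replace=False):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            g.add_edge(t, terms[p], relation=rel)
    return OntologyGraph(graph=g, aspect={t: "MF" for t in terms})


class TestTermSimilarity:
    def test_identity(self, toy_dag):
        assert term_similarity("GO:MA", "GO:MA", toy_dag) == 1.0

    def test_toy_dag_hand_value(self, toy_dag):
        # S_A = {A:1, R:0.8}, S_B = {B:1, R:0.8}; shared ancestor R only
        # sim = (0.8 + 0.8) / (1.8 + 1.8) = 0.4444...
        sim = term_similarity("GO:MA", "GO:MB", toy_dag)
        assert sim == pytest.approx(0.8 * 2 / 3.6, abs=1e-12)

    def test_disjoint_forest_is_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from(["GO:X", "GO:Y"])
        graph = OntologyGraph(graph=g, aspect={"GO:X": "MF", "GO:Y": "MF"})
        assert term_similarity("GO:X", "GO:Y", graph) == 0.0

    def test_cross_aspect_raises(self, toy_dag):
        with pytest.raises(OntologyError, match="cross-aspect"):
            term_similarity("GO:MA", "GO:CA", toy_dag)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            graph = random_dag(rng, int(rng.integers(3, 13)))
            terms = list(graph.graph.nodes)
            t1, t2 = rng.choice(terms, size=2, replace=False)
            expected = brute_force_term_similarity(t1, t2, graph)
            assert term_similarity(t1, t2, graph) == pytest.approx(expected, abs=1e-12)

    def test_shared_ancestor_never_decreases_similarity(self, toy_dag):
        # add a deeper shared parent C below R, re-annotate A and B under it
        g = nx.DiGraph(toy_dag.graph)
        g.add_node("GO:MC")
        g.add_edge("GO:MC", "GO:MR", relation="is_a")
        g.remove_edge("GO:MA", "GO:MR")
        g.remove_edge("GO:MB", "GO:MR")
        g.add_edge("GO:MA", "GO:MC", relation="is_a")
        g.add_edge("GO:MB", "GO:MC", relation="is_a")
        aspect = dict(toy_dag.aspect)
        aspect["GO:MC"] = "MF"
        deeper = OntologyGraph(graph=g, aspect=aspect)
        base = term_similarity("GO:MA", "GO:MB", toy_dag)
        assert term_similarity("GO:MA", "GO:MB", deeper) >= base


class TestGeneSimilarity:
    def test_identical_annotation_sets(self, toy_dag):
        assert gene_similarity("g1", "g3", "MF", toy_dag) == 1.0

    def test_singleton_reduces_to_term_similarity(self, toy_dag):
        assert gene_similarity("g1", "g2", "MF", toy_dag) == pytest.approx(
            term_similarity("GO:MA", "GO:MB", toy_dag)
        )

    def test_bma_hand_computed(self, toy_dag):
        graph = OntologyGraph(
            graph=nx.DiGraph(toy_dag.graph),
            aspect=dict(toy_dag.aspect),
            annotations={
                "MF": {"gx": frozenset({"GO:MA", "GO:MB"}), "gy": frozenset({"GO:MA"})},
                "CC": {},
            },
        )
        # sims: (A,A)=1, (B,A)=4/9; row maxima [1, 4/9], column max [1]
        expected = (1 + 4 / 9 + 1) / 3
        assert gene_similarity("gx", "gy", "MF", graph) == pytest.approx(expected)

    def test_unannotated_gene_is_nan(self, toy_dag):
        assert math.isnan(gene_similarity("g1", "nope", "MF", toy_dag))


class TestFSScore:
    def test_self_similarity_is_one(self, toy_dag):
        rec = fs_score("g1", "g1", toy_dag)
        assert rec.fs_score == 1.0 and rec.passes

    def test_symmetry_exact(self, toy_dag):
        a = fs_score("g1", "g2", toy_dag)
        b = fs_score("g2", "g1", toy_dag)
        assert a.fs_score == b.fs_score
        assert a.sim_mf == b.sim_mf and a.sim_cc == b.sim_cc

    def test_geometric_mean_and_threshold(self, toy_dag):
        rec = fs_score("g1", "g2", toy_dag)
        assert rec.fs_score == pytest.approx(
            math.sqrt(rec.sim_mf * rec.sim_cc), abs=1e-12
        )
        assert 0 <= rec.fs_score <= 1
        assert rec.passes == (rec.fs_score > 0.5)

    def test_missing_annotation_fails_screen(self, toy_dag):
        rec = fs_score("g1", "missing", toy_dag)
        assert math.isnan(rec.fs_score) and not rec.passes


class TestFormatRoundTrip:
    def test_obo_gaf_round_trip_preserves_similarity(self, tmp_path, toy_dag):
        write_obo(toy_dag, tmp_path / "t.obo")
        write_gaf(toy_dag, tmp_path / "t.gaf")
        back = load_ontology(tmp_path / "t.obo", tmp_path / "t.gaf")
        for a, b in [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]:
            assert fs_score(a, b, back).fs_score == pytest.approx(
                fs_score(a, b, toy_dag).fs_score, abs=1e-12
            )

    def test_gaf_not_qualifier_dropped(self, tmp_path, toy_dag):
        write_obo(toy_dag, tmp_path / "t.obo")
        gaf = tmp_path / "t.gaf"
        lines = [
            "!gaf-version: 2.2",
            "\t".join(["DB", "gN", "gN", "NOT", "GO:MA", "r", "IEA", "", "F",
                       "", "", "protein", "taxon:9606", "20200101", "DB", "", ""]),
            "\t".join(["DB", "gY", "gY", "", "GO:MA", "r", "IEA", "", "F",
                       "", "", "protein", "taxon:9606", "20200101", "DB", "", ""]),
        ]
        gaf.write_text("\n".join(lines) + "\n")
        graph = load_ontology(tmp_path / "t.obo", gaf)
        assert graph.annotations_for("gY", "MF")
        assert not graph.annotations_for("gN", "MF")
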