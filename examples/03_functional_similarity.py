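"""Wang semantic similarity and the FS score on a toy ontology.

Two genes annotated to sibling leaf terms share most of their ancestry and
score ~0.59 per aspect; genes under different branches share only the root
and score ~0.26. The FS score is the geometric mean of the MF and CC
gene-level similarities, with > 0.5 counted as functionally close.
"""
import networkx as nx

from sili.ontology import OntologyGraph, fs_score, term_similarity

g = nx.DiGraph()
aspect = {}
for tag, asp in (("M", "MF"), ("C", "CC")):
    root, b1, b2 = f"GO:{tag}R", f"GO:{tag}B1", f"GO:{tag}B2"
    l1, l2, l3 = f"GO:{tag}L1", f"GO:{tag}L2", f"GO:{tag}L3"
    g.add_edges_from(
        [(b1, root), (b2, root), (l1, b1), (l2, b1), (l3, b2)],
        relation="is_a",
    )
    aspect.update({t: asp for t in (root, b1, b2, l1, l2, l3)})

graph = OntologyGraph(
    graph=g,
    aspect=aspect,
    annotations={
        "MF": {"geneA": frozenset({"GO:ML1"}), "geneB": frozenset({"GO:ML2"}),
               "geneC": frozenset({"GO:ML3"})},
        "CC": {"geneA": frozenset({"GO:CL1"}), "geneB": frozenset({"GO:CL2"}),
               "geneC": frozenset({"GO:CL3"})},
    },
)

print("sibling terms  :", round(term_similarity("GO:ML1", "GO:ML2", graph), 4))
print("distant terms  :", round(term_similarity("GO:ML1", "GO:ML3", graph), 4))
for a, b in [("geneA", "geneB"), ("geneA", "geneC")]:
    rec = fs_score(a, b, graph)
    print(f"FS({a},{b}) = {rec.fs_score:.4f}  pass>0.5: {rec.passes}")
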