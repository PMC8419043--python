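"""Shared fixtures: toy ontologies, mini cohorts, and the session-scoped
synthetic benchmarks (generated once, reused across test modules)."""
from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sili.datatypes import Cohort, ExpressionMatrix, MutationTable, SurvivalTable, TPM_TOTAL
from sili.ontology import OntologyGraph
from sili.simulate import GeneratorConfig, SyntheticBundle, generate_all


@pytest.fixture(scope="session")
def toy_dag() -> OntologyGraph:
    """Root R with is_a children A and B, in both MF and CC aspects."""
    g = nx.DiGraph()
    aspect = {}
    for tag, asp in (("M", "MF"), ("C", "CC")):
        r, a, b = f"GO:{tag}R", f"GO:{tag}A", f"GO:{tag}B"
        g.add_nodes_from([r, a, b])
        g.add_edge(a, r, relation="is_a")
        g.add_edge(b, r, relation="is_a")
        aspect.update({r: asp, a: asp, b: asp})
    annotations = {
        "MF": {"g1": frozenset({"GO:MA"}), "g2": frozenset({"GO:MB"}),
               "g3": frozenset({"GO:MA"})},
        "CC": {"g1": frozenset({"GO:CA"}), "g2": frozenset({"GO:CB"}),
               "g3": frozenset({"GO:CA"})},
    }
    return OntologyGraph(graph=g, aspect=aspect, annotations=annotations)


def _tpm_df(values: np.ndarray, genes, samples) -> pd.DataFrame:
    v = np.asarray(values, dtype=float)
    v = v / v.sum(axis=0, keepdims=True) * TPM_TOTAL
    return pd.DataFrame(v, index=genes, columns=samples)


@pytest.fixture
def mini_cohort() -> Cohort:
    """8-sample, 3-gene cohort with TSG mutated in half the samples and the
    target clearly upregulated in mutants."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(8)]
    base = 2 ** rng.normal(6, 0.1, (3, 8))
    base[1, 4:] *= 8  # target up in mutant samples
    expr = ExpressionMatrix(
        values=_tpm_df(base, ["TSG", "TARGET", "OTHER"], samples),
        unit="tpm",
        cohort=pd.Series(["c1"] * 8, index=samples),
    )
    mut = pd.DataFrame(
        [[0, 0, 0, 0, 1, 1, 1, 1]], index=["TSG"], columns=samples
    )
    summary = pd.DataFrame(
        {
            "n_mutated_samples": [4],
            "n_functional_records": [4],
            "n_lof_records": [2],
            "mutation_frequency": [0.5],
            "lof_fraction": [0.5],
        },
        index=pd.Index(["TSG"], name="gene"),
    )
    surv = SurvivalTable(
        records=pd.DataFrame(
            {"sample": samples, "time": rng.uniform(100, 2000, 8), "event": 1}
        )
    )
    return Cohort(expression=expr, mutation_matrix=mut, gene_summary=summary, survival=surv)


SMALL_CONFIG = dict(
    n_samples=150,
    n_genes=400,
    n_dt=16,
    n_planted=4,
    n_tsgs=2,
    n_oncogenes=1,
    n_lines=120,
    n_decoy_drugs=4,
    panel_modules=20,
)


@pytest.fixture(scope="session")
def small_bundle() -> SyntheticBundle:
    """Cheap synthetic bundle for unit-level pipeline tests."""
    return generate_all(GeneratorConfig(seed=5, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def default_bundle() -> SyntheticBundle:
    """The default benchmark conditions (500 samples, 10 planted pairs)."""
    return generate_all(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def null_bundle() -> SyntheticBundle:
    """No planted effects: delta=0, rho=0, HR=1."""
    return generate_all(
        GeneratorConfig(seed=2, delta=0.0, rho_latent=0.0, hr_coinactive=1.0)
    )


@pytest.fixture(scope="session")
def drug_bundle() -> SyntheticBundle:
    """Drug-extension benchmark: 200 clinical samples."""
    return generate_all(GeneratorConfig(seed=3, n_samples=200))
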