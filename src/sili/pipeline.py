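"""End-to-end orchestration: prep -> screens -> rank -> drugs ->
characterization -> network, with deterministic table output and a JSON run
manifest. This is what the command line's ``run-all`` calls; the functions
are equally usable from Python.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterize import dependency_compare, enrich, per_gene_cox
from .config import SiliConfig
from .datatypes import Cohort
from .drugs import (
    DrugPanel,
    differential_response,
    extend_to_triples,
    map_drugs,
    predict_response,
    train_response_model,
)
from .io import log2_tpm
from .network import build_network, export_edge_tsv, export_graphml, export_sif
from .ontology import OntologyGraph
from .prep import apply_2020_rule
from .rank import aggregate
from .screen import ScreenOutput, run_sili

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def agonist_only_targets(drug_annotations: pd.DataFrame | None) -> set[str]:
    """Targets reachable only through agonist-mechanism drugs."""
    if drug_annotations is None or drug_annotations.empty:
        return set()
    ann = drug_annotations.copy()
    ann["is_agonist"] = ann["moa"].fillna("").str.lower().str.contains("agonist")
    by_target = ann.groupby("target")["is_agonist"].all()
    return set(by_target[by_target].index)


def universe_ras(audit: pd.DataFrame) -> pd.DataFrame:
    """Diagnostic rank aggregation over every evaluated pair.

    Pairs with an unfittable survival model get a neutral hazard ratio of 1
    so the aggregation stays defined; their gate flags are untouched.
    """
    filled = audit.copy()
    filled["hazard_ratio"] = filled["hazard_ratio"].fillna(1.0)
    for col in ("fs_score", "log2_fold_change", "spearman_rho"):
        filled[col] = filled[col].fillna(0.0)
    return aggregate(filled)


@dataclass
class PipelineResult:
    tsgs: list[str]
    screen: ScreenOutput
    ranked: pd.DataFrame
    audit_ras: pd.DataFrame
    triples: pd.DataFrame | None = None
    drug_models: dict = field(default_factory=dict)
    differential: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    dependency_p: float | None = None
    dependency_ranking: pd.DataFrame | None = None
    target_cox: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def run_all(
    cohort: Cohort,
    driver_genes,
    druggable_genes,
    ontology: OntologyGraph,
    config: SiliConfig | None = None,
    panel: DrugPanel | None = None,
    dependency: pd.DataFrame | None = None,
    gene_sets: dict | None = None,
    seed: int = 0,
    tsg_allow: list | None = None,
    tsg_deny: list | None = None,
) -> PipelineResult:
    """Run the full inference chain in memory."""
    config = config or SiliConfig()
    manifest: dict = {
        "version": __version__,
        "seed": int(seed),
        "config": config.to_dict(),
        "counts": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    counts = manifest["counts"]

    tsgs = apply_2020_rule(cohort.gene_summary, driver_genes, config.lof_threshold)
    if tsg_allow:
        tsgs = sorted(set(tsgs) | set(tsg_allow))
    if tsg_deny:
        tsgs = [t for t in tsgs if t not in set(tsg_deny)]
    counts["drivers"] = len(list(driver_genes))
    counts["tsgs"] = len(tsgs)

    drop = agonist_only_targets(panel.annotations if panel is not None else None)
    dts = [g for g in druggable_genes if g not in drop]
    counts["druggable_targets"] = len(dts)

    screen_out = run_sili(cohort, tsgs, dts, ontology, config)
    counts["pairs_evaluated"] = len(screen_out.audit)
    counts["candidates"] = len(screen_out.candidates)
    for gate in ("g1_fs", "g2_de", "g3_coexp", "g4_surv"):
        counts[f"pass_{gate}"] = int(screen_out.audit[gate].sum())

    ranked = aggregate(screen_out.candidates)
    audit_ras = universe_ras(screen_out.audit)

    result = PipelineResult(
        tsgs=tsgs, screen=screen_out, ranked=ranked, audit_ras=audit_ras, manifest=manifest
    )

    unique_targets = sorted(screen_out.candidates["target"].unique())
    counts["unique_targets"] = len(unique_targets)

    if panel is not None and unique_targets:
        drug_map = map_drugs(panel.annotations, unique_targets)
        counts["mapped_drugs"] = int(drug_map["drug"].str.lower().nunique())
        models, preds = {}, {}
        clinical = log2_tpm(cohort.expression)
        for drug in sorted(drug_map["drug"].unique()):
            try:
                model = train_response_model(panel, drug, seed=seed, config=config)
            except Exception as exc:
                log.warning("drug %s skipped: %s", drug, exc)
                continue
            models[drug] = model
            preds[drug] = predict_response(model, clinical)
        result.drug_models = models
        if preds:
            imputed = pd.DataFrame(preds)
            diffs = []
            for tsg in tsgs:
                diffs.append(differential_response(imputed, cohort.mutation_matrix, tsg, config))
            result.differential = pd.concat(diffs, ignore_index=True)
            result.triples = extend_to_triples(
                screen_out.candidates, drug_map, result.differential, config
            )
            counts["tsg_drug_pairs"] = int(result.differential["gate"].sum())
            counts["triples"] = len(result.triples)

    if gene_sets and unique_targets:
        result.enrichment = enrich(
            unique_targets, gene_sets, cohort.expression.genes, config
        )
        counts["enriched_sets"] = int(result.enrichment["significant"].sum())
    if dependency is not None and unique_targets:
        p, ranking = dependency_compare(unique_targets, dependency, seed=seed, config=config)
        result.dependency_p = p
        result.dependency_ranking = ranking
    if cohort.survival is not None and unique_targets:
        expr = log2_tpm(cohort.expression).loc[
            [g for g in unique_targets if g in cohort.expression.genes]
        ]
        result.target_cox = per_gene_cox(
            expr, cohort.survival.records, cohort.expression.cohort
        )
    return result


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_outputs(result: PipelineResult, outdir) -> dict:
    """Write all result tables + network exports + manifest; returns manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.screen.audit, out / "audit.tsv")
    _write_tsv(result.ranked, out / "candidates_ranked.tsv")
    _write_tsv(result.audit_ras, out / "audit_ras.tsv")
    (out / "tsgs.txt").write_text("\n".join(result.tsgs) + "\n")
    if result.triples is not None:
        _write_tsv(result.triples, out / "triples.tsv")
    if result.differential is not None:
        _write_tsv(result.differential, out / "differential_response.tsv")
    if result.enrichment is not None:
        _write_tsv(result.enrichment, out / "enrichment.tsv")
    if result.dependency_ranking is not None:
        _write_tsv(result.dependency_ranking, out / "dependency_ranking.tsv", index=True)
    if result.target_cox is not None:
        _write_tsv(result.target_cox, out / "target_cox.tsv", index=True)
    net = build_network(result.ranked, result.triples)
    export_graphml(net, out / "network.graphml")
    export_sif(net, out / "network.sif")
    export_edge_tsv(net, out / "network_edges.tsv")
    manifest = dict(result.manifest)
    if result.dependency_p is not None:
        manifest["dependency_p"] = result.dependency_p
    manifest["outputs"] = {
        p.name: _digest(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
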