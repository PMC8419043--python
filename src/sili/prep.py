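"""Mutation filtering, the binary mutation matrix, and the 20/20 TSG call.

The filters follow the standard meta-cohort recipe: drop non-functional
records (silent/intronic/intergenic), merge duplicate records per
(sample, gene), drop hypomutated samples, drop rarely mutated genes, and
call tumor suppressors among supplied drivers as genes whose functional
records are >20% truncating (frameshift or nonsense).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import (
    LOF_CLASSES,
    NONFUNCTIONAL_CLASSES,
    MutationTable,
    ValidationError,
)

log = logging.getLogger(__name__)


def filter_functional(t: MutationTable) -> MutationTable:
    """Remove non-functional records and merge per-(sample, gene) duplicates.

    When several functional records exist for one (sample, gene), the merged
    record keeps an LOF class if any record was truncating, so downstream
    LOF counting is not diluted by the merge.
    """
    r = t.records
    r = r[~r["variant_class"].isin(NONFUNCTIONAL_CLASSES)]
    if r.empty:
        return MutationTable(records=r.reset_index(drop=True))
    is_lof = r["variant_class"].isin(LOF_CLASSES)
    # keep one record per (sample, gene), preferring a truncating class
    order = r.assign(_lof=is_lof.astype(int)).sort_values(
        ["sample", "gene", "_lof"], ascending=[True, True, False], kind="mergesort"
    )
    merged = order.drop_duplicates(["sample", "gene"], keep="first").drop(columns="_lof")
    return MutationTable(records=merged.reset_index(drop=True))


def classify_lof(t: MutationTable) -> MutationTable:
    """Annotate each record with a boolean ``lof`` flag (truncating classes)."""
    r = t.records.copy()
    r["lof"] = r["variant_class"].isin(LOF_CLASSES)
    return MutationTable(records=r)


def filter_samples(
    t: MutationTable, min_mutations: int = 10
) -> tuple[MutationTable, list[str]]:
    """Drop samples with fewer than ``min_mutations`` functional records.

    The analyzed gene universe is the gene set of the (already functional-
    filtered) table itself. Returns (filtered table, dropped sample list).
    """
    counts = t.records.groupby("sample").size()
    keep = counts[counts >= min_mutations].index
    dropped = sorted(set(counts.index) - set(keep))
    if len(keep) == 0:
        raise ValidationError("no samples remain after the minimum-mutation filter")
    if dropped:
        log.info("dropped %d hypomutated samples (<%d records)", len(dropped), min_mutations)
    out = t.records[t.records["sample"].isin(keep)].reset_index(drop=True)
    return MutationTable(records=out), dropped


def mutation_matrix(t: MutationTable, samples=None) -> pd.DataFrame:
    """Binary gene x sample matrix from a functional mutation table."""
    r = t.records
    mat = (
        pd.crosstab(r["gene"], r["sample"]).clip(upper=1).astype(int)
    )
    if samples is not None:
        mat = mat.reindex(columns=pd.Index(samples), fill_value=0)
    return mat.sort_index()


def filter_gene_frequency(matrix: pd.DataFrame, min_freq: float = 0.025) -> pd.DataFrame:
    """Keep genes mutated in at least ``min_freq`` of the retained samples."""
    n = matrix.shape[1]
    if n == 0:
        raise ValidationError("no retained samples: cannot compute mutation frequency")
    freq = matrix.sum(axis=1) / n
    kept = matrix.loc[freq >= min_freq]
    log.info("gene frequency filter: %d -> %d genes", matrix.shape[0], kept.shape[0])
    return kept


def gene_summaries(t: MutationTable, n_retained_samples: int) -> pd.DataFrame:
    """Per-gene functional/LOF record counts and mutation frequency."""
    if "lof" not in t.records.columns:
        t = classify_lof(t)
    r = t.records
    g = r.groupby("gene")
    out = pd.DataFrame(
        {
            "n_mutated_samples": g["sample"].nunique(),
            "n_functional_records": g.size(),
            "n_lof_records": g["lof"].sum().astype(int),
        }
    )
    out["mutation_frequency"] = out["n_mutated_samples"] / n_retained_samples
    out["lof_fraction"] = out["n_lof_records"] / out["n_functional_records"]
    return out.sort_index()


def apply_2020_rule(
    summaries: pd.DataFrame, driver_genes, lof_threshold: float = 0.20
) -> list[str]:
    """Call tumor suppressors among ``driver_genes``: lof_fraction strictly >20%.

    Genes without functional records are excluded with a warning (the LOF
    fraction is undefined for them).
    """
    tsgs = []
    for gene in driver_genes:
        if gene not in summaries.index:
            log.warning("driver %s has no functional records; excluded from 20/20 call", gene)
            continue
        row = summaries.loc[gene]
        if row["n_functional_records"] == 0:
            log.warning("driver %s has zero functional records; excluded", gene)
            continue
        if row["lof_fraction"] > lof_threshold:
            tsgs.append(gene)
    return tsgs


def coverage_stats(matrix: pd.DataFrame, tsg_list, oncogene_list) -> dict[str, float]:
    """Fractions of samples carrying >=1 TSG / >=1 oncogene mutation."""
    def frac(genes) -> float:
        genes = [g for g in genes if g in matrix.index]
        if not genes or matrix.shape[1] == 0:
            return 0.0
        return float((matrix.loc[genes].sum(axis=0) > 0).mean())

    return {"tsg_coverage": frac(tsg_list), "oncogene_coverage": frac(oncogene_list)}


@dataclass
class PrepResult:
    """Bundle of mutation-prep outputs."""

    table: MutationTable
    matrix: pd.DataFrame
    summaries: pd.DataFrame
    dropped_samples: list[str] = field(default_factory=list)


def prepare_mutations(
    raw: MutationTable,
    min_mutations: int = 10,
    min_freq: float = 0.025,
) -> PrepResult:
    """Full mutation-prep chain: functional filter -> LOF flags -> sample and
    gene frequency filters -> binary matrix + per-gene summaries."""
    func = classify_lof(filter_functional(raw))
    func, dropped = filter_samples(func, min_mutations=min_mutations)
    mat = mutation_matrix(func)
    mat = filter_gene_frequency(mat, min_freq=min_freq)
    kept_records = func.records[func.records["gene"].isin(mat.index)].reset_index(drop=True)
    summaries = gene_summaries(MutationTable(records=kept_records), mat.shape[1])
    return PrepResult(
        table=MutationTable(records=kept_records),
        matrix=mat,
        summaries=summaries,
        dropped_samples=dropped,
    )
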