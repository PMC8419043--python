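"""Downstream characterization of the inferred target set.

Four independent views of the unique targets: hallmark-style gene-set
enrichment (hypergeometric), tumor-vs-normal differential expression,
per-gene survival association (Cox on continuous z-scored expression) and
comparison of gene-dependency scores against size-matched random gene sets.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SiliConfig
from .stats import bh_adjust, cox_hazard_ratio, hypergeom_enrichment_p, rank_sum

log = logging.getLogger(__name__)


def enrich(
    targets, gene_sets: dict[str, set], universe, config: SiliConfig | None = None
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``targets`` in each gene set.

    Gene sets are intersected with the universe before testing; the query is
    likewise restricted to the universe.
    """
    config = config or SiliConfig()
    universe = set(universe)
    query = set(targets) & universe
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        k = len(query & members)
        p = hypergeom_enrichment_p(k, len(members), len(query), len(universe))
        rows.append((name, k, len(members), len(query), len(universe), p))
    out = pd.DataFrame(
        rows, columns=["gene_set", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    out["p_adj"] = bh_adjust(out["p"])
    out["significant"] = out["p_adj"] < config.enrich_alpha
    out["neg_log10_p_adj"] = -np.log10(out["p_adj"])
    return out


def tumor_normal_de(
    tumor_expr: pd.DataFrame,
    normal_expr: pd.DataFrame,
    config: SiliConfig | None = None,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal comparison on log2-scale expression.

    Two-sided rank-sum, BH across genes; flagged when adjusted p < 0.01 and
    |log2 fold change| > 1 (both strict).
    """
    config = config or SiliConfig()
    genes = tumor_expr.index.intersection(normal_expr.index)
    rows = []
    for g in genes:
        a = tumor_expr.loc[g].to_numpy()
        b = normal_expr.loc[g].to_numpy()
        lfc = float(a.mean() - b.mean())
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append((g, 0.0, np.nan))
            continue
        p = rank_sum(a, b, alternative="two-sided")
        rows.append((g, lfc, p))
    out = pd.DataFrame(rows, columns=["gene", "log2_fold_change", "p"]).set_index("gene")
    out["p_adj"] = bh_adjust(out["p"])
    out["flag"] = (out["p_adj"] < config.tn_de_alpha) & (
        out["log2_fold_change"].abs() > config.tn_de_lfc
    )
    out["flag"] = out["flag"].fillna(False).astype(bool)
    return out


def per_gene_cox(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    cohort_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Univariable cohort-stratified Cox per gene on z-scored log2 expression.

    ``expression``: genes x samples, log2 scale; ``survival``: DataFrame with
    columns sample/time/event. HR is per 1 SD of expression. Constant genes
    are skipped with a reason.
    """
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    samples = expression.columns.intersection(surv.index)
    time = surv.loc[samples, "time"].to_numpy()
    event = surv.loc[samples, "event"].to_numpy()
    strata = None if cohort_labels is None else cohort_labels.reindex(samples).to_numpy()
    rows = []
    for g in expression.index:
        x = expression.loc[g, samples].to_numpy()
        if np.ptp(x) == 0:
            rows.append((g, np.nan, np.nan, "constant gene"))
            continue
        hr, p = cox_hazard_ratio(time, event, x, strata, z_score=True)
        reason = "" if np.isfinite(hr) else "fit failed"
        rows.append((g, hr, p, reason))
    return pd.DataFrame(rows, columns=["gene", "hazard_ratio", "p", "reason"]).set_index("gene")


def dependency_compare(
    targets,
    dependency_matrix: pd.DataFrame,
    seed: int = 0,
    n_resamples: int | None = None,
    config: SiliConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Compare per-gene median dependency of the target set vs random sets.

    Each of ``n_resamples`` seeded draws picks a uniformly random gene set of
    the same size from the matrix and performs a one-sided rank-sum test
    (targets lower = more essential); the median p over draws is reported
    (n_resamples=1 reproduces the single-draw comparison). Also returns the
    per-gene ranking by median score ascending with lexicographic
    tie-breaks.
    """
    config = config or SiliConfig()
    n_resamples = n_resamples or config.dependency_resamples
    medians = dependency_matrix.median(axis=1)
    targets = [g for g in targets if g in medians.index]
    if not targets:
        raise ValueError("no targets present in the dependency matrix")
    target_scores = medians.loc[targets].to_numpy()
    pool = medians.index.to_numpy()
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_resamples):
        random_set = rng.choice(pool, size=len(targets), replace=False)
        p = rank_sum(target_scores, medians.loc[random_set].to_numpy(), alternative="less")
        pvals.append(p)
    p_summary = float(np.median(pvals))
    ranking = (
        medians.rename("median_score")
        .to_frame()
        .assign(gene=medians.index)
        .sort_values(["median_score", "gene"], kind="mergesort")
        .drop(columns="gene")
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    ranking["is_target"] = ranking.index.isin(targets)
    return p_summary, ranking
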