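"""The four statistical screens and the combined candidate selection.

A tumor-suppressor / druggable-target (TSG-DT) pair is a synthetic-lethality
candidate when it passes all four gates:

g1  functional similarity: FS score > 0.5 (see :mod:`sili.ontology`);
g2  compensatory upregulation: the target is significantly higher expressed
    in TSG-mutant than wild-type tumors (one-sided rank-sum on centred
    log2(TPM+1), BH-adjusted p < 0.05, positive log2 fold change);
g3  co-expression: Spearman rho > 0.15 with BH-adjusted p < 0.05;
g4  co-inactivation survival benefit: patients with both genes expressed
    below their medians have better outcomes (stratified log-rank p < 0.05
    and Cox hazard ratio < 1).

Gate logic is a pure conjunction, so loosening any threshold can only grow
the candidate set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SiliConfig
from .datatypes import Cohort, ValidationError
from .io import centered_log_expression
from .ontology import OntologyGraph, fs_table
from .stats import (
    bh_adjust,
    cox_hazard_ratio,
    rank_sum,
    spearman_test,
    stratified_logrank,
)

log = logging.getLogger(__name__)


def mutant_wildtype_split(cohort: Cohort, tsg: str) -> tuple[pd.Index, pd.Index]:
    """Expression samples with / without a functional mutation in ``tsg``."""
    if tsg not in cohort.mutation_matrix.index:
        raise ValidationError(f"TSG {tsg} absent from the mutation matrix")
    shared = cohort.shared_samples
    status = cohort.mutation_matrix.loc[tsg, shared]
    mutant = shared[status.to_numpy() == 1]
    wildtype = shared[status.to_numpy() == 0]
    return mutant, wildtype


def differential_expression(
    cohort: Cohort,
    tsg: str,
    candidate_genes,
    config: SiliConfig | None = None,
    centered: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-sided rank-sum (higher in mutant) per candidate gene, BH per TSG."""
    config = config or SiliConfig()
    if centered is None:
        centered = centered_log_expression(cohort.expression)
    mutant, wildtype = mutant_wildtype_split(cohort, tsg)
    rows = []
    underpowered = len(mutant) < config.min_group or len(wildtype) < config.min_group
    for gene in candidate_genes:
        if gene not in centered.index:
            rows.append((gene, np.nan, np.nan, "gene absent from expression"))
            continue
        x = centered.loc[gene, mutant].to_numpy()
        y = centered.loc[gene, wildtype].to_numpy()
        if underpowered:
            rows.append((gene, np.nan, np.nan, "underpowered"))
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append((gene, 0.0, np.nan, "zero-variance gene"))
            continue
        log2fc = float(x.mean() - y.mean())
        p = rank_sum(x, y, alternative="greater")
        rows.append((gene, log2fc, p, ""))
    out = pd.DataFrame(rows, columns=["gene", "log2_fold_change", "de_p", "de_reason"])
    out["de_p_adj"] = bh_adjust(out["de_p"])
    out["de_gate"] = (out["de_p_adj"] < config.de_alpha) & (out["log2_fold_change"] > 0)
    out["de_gate"] = out["de_gate"].fillna(False).astype(bool)
    out.loc[out["de_reason"] == "", "de_reason"] = np.where(
        out.loc[out["de_reason"] == "", "de_gate"], "", "not significant"
    )
    return out.set_index("gene")


def coexpression(
    cohort: Cohort,
    pair: tuple[str, str],
    config: SiliConfig | None = None,
    centered: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Spearman rho and (two-sided) p for one gene pair across all samples."""
    config = config or SiliConfig()
    if centered is None:
        centered = centered_log_expression(cohort.expression)
    a, b = pair
    for g in pair:
        if g not in centered.index:
            raise ValidationError(f"gene {g} absent from expression")
    return spearman_test(centered.loc[a].to_numpy(), centered.loc[b].to_numpy())


def inactivation_status(expression: pd.DataFrame) -> pd.DataFrame:
    """Binary inactivation calls: strictly below the per-gene median.

    Values tied with the median count as active, so a constant gene is never
    inactive anywhere.
    """
    med = expression.median(axis=1)
    return expression.lt(med, axis=0).astype(int)


def pairwise_survival(
    cohort: Cohort,
    pair: tuple[str, str],
    inactive: pd.DataFrame,
    config: SiliConfig | None = None,
) -> dict:
    """Co-inactivation survival comparison for one pair.

    Group 1 = samples with both genes inactive; group 0 = everyone else.
    Returns log-rank p (cohort-stratified), Cox HR, the gate flag and a
    failure reason when the comparison is not possible.
    """
    config = config or SiliConfig()
    res = {"survival_p": np.nan, "hazard_ratio": np.nan, "surv_gate": False, "surv_reason": ""}
    if cohort.survival is None:
        res["surv_reason"] = "no survival data"
        return res
    surv = cohort.survival.records.set_index("sample")
    samples = inactive.columns.intersection(surv.index)
    if len(samples) < config.min_survival_samples:
        res["surv_reason"] = f"fewer than {config.min_survival_samples} samples with follow-up"
        return res
    a, b = pair
    co = (inactive.loc[a, samples] == 1) & (inactive.loc[b, samples] == 1)
    group = co.astype(int).to_numpy()
    if group.sum() == 0:
        res["surv_reason"] = "empty co-inactive group"
        return res
    if group.sum() == len(group):
        res["surv_reason"] = "all samples co-inactive"
        return res
    time = surv.loc[samples, "time"].to_numpy()
    event = surv.loc[samples, "event"].to_numpy()
    strata = cohort.cohort_of(samples).to_numpy()
    _, p = stratified_logrank(time, event, group, strata)
    hr, _ = cox_hazard_ratio(time, event, group, strata)
    res["survival_p"] = p
    res["hazard_ratio"] = hr
    res["surv_gate"] = bool(p < config.surv_alpha and np.isfinite(hr) and hr < 1)
    if not res["surv_gate"] and not res["surv_reason"]:
        res["surv_reason"] = "no significant co-inactivation benefit"
    return res


@dataclass
class ScreenOutput:
    """Full audit of every evaluated pair plus the passed-all candidates."""

    audit: pd.DataFrame     # one row per (tsg, target): statistics + gates
    candidates: pd.DataFrame  # rows of audit with passed_all

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def run_sili(
    cohort: Cohort,
    tsg_list,
    druggable_list,
    ontology: OntologyGraph,
    config: SiliConfig | None = None,
) -> ScreenOutput:
    """Evaluate all four gates for every TSG x druggable-target pair."""
    config = config or SiliConfig()
    tsg_list = list(dict.fromkeys(tsg_list))
    dt_list = [g for g in dict.fromkeys(druggable_list) if g not in set(tsg_list)]
    if not tsg_list or not dt_list:
        raise ValidationError("empty TSG or druggable-target list")
    centered = centered_log_expression(cohort.expression)
    inactive = inactivation_status(centered)

    pairs = [(t, d) for t in tsg_list for d in dt_list]
    log.info("screening %d pairs (%d TSGs x %d targets)", len(pairs), len(tsg_list), len(dt_list))

    # gate 1: functional similarity
    fs = fs_table(pairs, ontology, threshold=config.fs_threshold)
    fs.index = pd.MultiIndex.from_arrays([fs["gene_a"], fs["gene_b"]])

    # gate 2: differential expression, BH within each TSG
    de_frames = {}
    for tsg in tsg_list:
        de_frames[tsg] = differential_expression(
            cohort, tsg, dt_list, config=config, centered=centered
        )

    # gate 3: co-expression, BH across all evaluated pairs
    rows = []
    for tsg, dt in pairs:
        ok = tsg in centered.index and dt in centered.index
        if not ok:
            rows.append((np.nan, np.nan, "gene absent from expression"))
            continue
        rho, p = coexpression(cohort, (tsg, dt), config=config, centered=centered)
        reason = "" if np.isfinite(rho) else "zero-variance gene"
        rows.append((rho, p, reason))
    coexp = pd.DataFrame(rows, columns=["spearman_rho", "coexp_p", "coexp_reason"])
    coexp["coexp_p_adj"] = bh_adjust(coexp["coexp_p"])
    coexp["coexp_gate"] = (
        (coexp["spearman_rho"] > config.coexp_rho)
        & (coexp["coexp_p_adj"] < config.coexp_alpha)
    ).fillna(False)

    # gate 4: pairwise survival
    surv_rows = []
    for tsg, dt in pairs:
        if tsg in inactive.index and dt in inactive.index:
            surv_rows.append(pairwise_survival(cohort, (tsg, dt), inactive, config=config))
        else:
            surv_rows.append(
                {
                    "survival_p": np.nan,
                    "hazard_ratio": np.nan,
                    "surv_gate": False,
                    "surv_reason": "gene absent from expression",
                }
            )
    surv = pd.DataFrame(surv_rows)

    audit = pd.DataFrame({"tsg": [p[0] for p in pairs], "target": [p[1] for p in pairs]})
    audit["sim_mf"] = fs["sim_mf"].to_numpy()
    audit["sim_cc"] = fs["sim_cc"].to_numpy()
    audit["fs_score"] = fs["fs_score"].to_numpy()
    audit["g1_fs"] = fs["fs_pass"].to_numpy()
    de_cols = ["log2_fold_change", "de_p", "de_p_adj", "de_gate", "de_reason"]
    for col in de_cols:
        audit[col] = [de_frames[t].loc[d, col] for t, d in pairs]
    audit = audit.rename(columns={"de_gate": "g2_de"})
    for col in ["spearman_rho", "coexp_p", "coexp_p_adj", "coexp_gate", "coexp_reason"]:
        audit[col] = coexp[col].to_numpy()
    audit = audit.rename(columns={"coexp_gate": "g3_coexp"})
    for col in ["survival_p", "hazard_ratio", "surv_gate", "surv_reason"]:
        audit[col] = surv[col].to_numpy()
    audit = audit.rename(columns={"surv_gate": "g4_surv"})
    for g in ["g1_fs", "g2_de", "g3_coexp", "g4_surv"]:
        audit[g] = audit[g].astype(bool)
    audit["passed_all"] = audit[["g1_fs", "g2_de", "g3_coexp", "g4_surv"]].all(axis=1)
    audit = audit.sort_values(["tsg", "target"], kind="mergesort").reset_index(drop=True)
    candidates = audit[audit["passed_all"]].reset_index(drop=True)
    log.info("%d of %d pairs passed all four gates", len(candidates), len(audit))
    return ScreenOutput(audit=audit, candidates=candidates)
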