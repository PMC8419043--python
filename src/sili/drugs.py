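"""Drug-response imputation and the TSG-target-drug extension.

Clinical drug response is imputed from cell-line panels: a ridge regression
of drug AUC (lower = more sensitive) on standardized log2 expression is
trained per drug on solid-tumor lines (hematopoietic/lymphoid lines
excluded), with the penalty chosen by 10-fold cross-validation, then
applied to clinical expression. A drug is linked to a TSG when its imputed
AUC is significantly lower in TSG-mutant samples (one-sided rank-sum,
BH across drugs per TSG). The drug layer annotates the candidate pair list;
it never filters it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .config import SiliConfig
from .datatypes import ValidationError
from .stats import bh_adjust, rank_sum

log = logging.getLogger(__name__)

EXCLUDED_TISSUES = {"haematopoietic_and_lymphoid_tissue", "hematopoietic_and_lymphoid_tissue"}


@dataclass
class DrugPanel:
    """Cell-line expression (log2 scale, genes x lines), per-drug AUC, annotations.

    auc: DataFrame lines x drugs, NaN where unmeasured, values >= 0.
    annotations: DataFrame with columns drug, target, moa (one row per edge).
    tissue: optional Series line -> tissue label.
    """

    expression: pd.DataFrame
    auc: pd.DataFrame
    annotations: pd.DataFrame
    tissue: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.auc.to_numpy() < 0).any():
            raise ValidationError("AUC values must be non-negative")
        missing = self.auc.index.difference(self.expression.columns)
        if len(missing):
            raise ValidationError(f"AUC lines absent from expression: {missing[:5].tolist()}")

    def solid_lines(self) -> pd.Index:
        lines = self.auc.index
        if self.tissue is None:
            return lines
        t = self.tissue.reindex(lines).str.lower()
        return lines[~t.isin(EXCLUDED_TISSUES)]


@dataclass
class ResponseModel:
    drug: str
    genes: pd.Index
    means: np.ndarray
    scales: np.ndarray
    coef: np.ndarray
    intercept: float
    alpha: float
    cv_r2: float
    n_lines: int
    fitted: pd.Series = field(repr=False, default=None)


def train_response_model(
    panel: DrugPanel,
    drug: str,
    lambda_grid=None,
    folds: int = 10,
    seed: int = 0,
    config: SiliConfig | None = None,
) -> ResponseModel:
    """Fit the per-drug ridge model with CV-selected penalty.

    Features are the top most-variable panel genes (config.n_feature_genes),
    z-scored with the training means/scales. Raises when fewer than
    config.min_lines_per_drug solid lines have a measured AUC.
    """
    config = config or SiliConfig()
    lambda_grid = tuple(lambda_grid or config.ridge_lambda_grid)
    if drug not in panel.auc.columns:
        raise ValidationError(f"drug {drug} not in panel")
    lines = panel.solid_lines()
    y = panel.auc.loc[lines, drug].dropna()
    lines = y.index
    if len(lines) < config.min_lines_per_drug:
        raise ValidationError(
            f"drug {drug}: only {len(lines)} usable lines (< {config.min_lines_per_drug})"
        )
    expr = panel.expression.loc[:, lines]
    variances = expr.var(axis=1)
    genes = variances[variances > 0].nlargest(config.n_feature_genes).index.sort_values()
    x = expr.loc[genes].to_numpy().T  # lines x genes
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=0)
    xz = (x - means) / scales
    yv = y.to_numpy()

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(xz))
    cv_pred = {a: np.empty_like(yv) for a in lambda_grid}
    for train_idx, test_idx in splits:
        for a in lambda_grid:
            model = Ridge(alpha=a)
            model.fit(xz[train_idx], yv[train_idx])
            cv_pred[a][test_idx] = model.predict(xz[test_idx])
    sst = ((yv - yv.mean()) ** 2).sum()
    mse = {a: float(((yv - cv_pred[a]) ** 2).mean()) for a in lambda_grid}
    best = min(lambda_grid, key=lambda a: (mse[a], a))
    cv_r2 = float(1 - ((yv - cv_pred[best]) ** 2).sum() / sst) if sst > 0 else float("nan")
    final = Ridge(alpha=best)
    final.fit(xz, yv)
    fitted = pd.Series(final.predict(xz), index=lines)
    if not np.isfinite(cv_r2) or cv_r2 <= 0:
        log.warning("drug %s: cross-validated R^2 = %.3f (no predictive signal)", drug, cv_r2)
    return ResponseModel(
        drug=drug,
        genes=genes,
        means=means,
        scales=scales,
        coef=final.coef_,
        intercept=float(final.intercept_),
        alpha=float(best),
        cv_r2=cv_r2,
        n_lines=len(lines),
        fitted=fitted,
    )


def predict_response(model: ResponseModel, clinical_expression: pd.DataFrame) -> pd.Series:
    """Imputed AUC per clinical sample (log2-scale expression, genes x samples).

    Clinical genes are standardized with the training means/scales; training
    genes missing from the clinical matrix are imputed at the training mean
    (z = 0), with a warning above 30% missing. Gene order is irrelevant.
    """
    present = model.genes.intersection(clinical_expression.index)
    n_missing = len(model.genes) - len(present)
    if n_missing:
        frac = n_missing / len(model.genes)
        msg = "drug %s: %d/%d training genes missing from clinical data"
        if frac > 0.30:
            log.warning(msg + " (over 30%%)", model.drug, n_missing, len(model.genes))
        else:
            log.info(msg, model.drug, n_missing, len(model.genes))
    z = np.zeros((clinical_expression.shape[1], len(model.genes)))
    pos = {g: i for i, g in enumerate(model.genes)}
    for g in present:
        i = pos[g]
        z[:, i] = (clinical_expression.loc[g].to_numpy() - model.means[i]) / model.scales[i]
    pred = z @ model.coef + model.intercept
    return pd.Series(pred, index=clinical_expression.columns, name=model.drug)


def differential_response(
    imputed: pd.DataFrame,
    mutation_matrix: pd.DataFrame,
    tsg: str,
    config: SiliConfig | None = None,
) -> pd.DataFrame:
    """One-sided rank-sum (mutant AUC lower) per drug; BH across drugs.

    ``imputed``: samples x drugs. The gate is adjusted p < alpha AND a
    negative mutant-minus-wild-type median difference.
    """
    config = config or SiliConfig()
    if tsg not in mutation_matrix.index:
        raise ValidationError(f"TSG {tsg} absent from the mutation matrix")
    samples = imputed.index.intersection(mutation_matrix.columns)
    status = mutation_matrix.loc[tsg, samples]
    mut = samples[status.to_numpy() == 1]
    wt = samples[status.to_numpy() == 0]
    if len(mut) == 0:
        raise ValidationError(f"empty mutant group for {tsg}")
    if len(wt) == 0:
        raise ValidationError(f"empty wild-type group for {tsg}")
    rows = []
    for drug in imputed.columns:
        a = imputed.loc[mut, drug].to_numpy()
        b = imputed.loc[wt, drug].to_numpy()
        effect = float(np.median(a) - np.median(b))
        p = rank_sum(a, b, alternative="less")
        rows.append((drug, effect, p))
    out = pd.DataFrame(rows, columns=["drug", "median_auc_diff", "p"])
    out["p_adj"] = bh_adjust(out["p"])
    out["gate"] = (out["p_adj"] < config.drug_alpha) & (out["median_auc_diff"] < 0)
    out["tsg"] = tsg
    return out


def map_drugs(drug_table: pd.DataFrame, dt_set) -> pd.DataFrame:
    """Drug -> target edges restricted to the inferred target set.

    Agonist mechanism-of-action edges are dropped (an agonist cannot
    phenocopy target loss), drugs without any retained target are dropped,
    and drug names are de-duplicated case-insensitively.
    """
    dt_set = set(dt_set)
    t = drug_table.copy()
    t["drug_key"] = t["drug"].str.lower()
    t = t[~t["moa"].fillna("").str.lower().str.contains("agonist")]
    t = t[t["target"].isin(dt_set)]
    t = t.drop_duplicates(["drug_key", "target"])
    return t[["drug", "target", "moa"]].reset_index(drop=True)


def extend_to_triples(
    candidates: pd.DataFrame,
    drug_map: pd.DataFrame,
    differential: pd.DataFrame,
    config: SiliConfig | None = None,
) -> pd.DataFrame:
    """TSG-target-drug triples: candidate pairs joined with drugs that target
    the pair's target and pass the differential-response gate for its TSG."""
    sig = differential[differential["gate"]]
    merged = candidates.merge(
        drug_map.rename(columns={"target": "target"}), on="target", how="inner"
    )
    merged = merged.merge(sig, on=["tsg", "drug"], how="inner")
    cols = ["tsg", "target", "drug", "moa", "median_auc_diff", "p", "p_adj"]
    keep = [c for c in cols if c in merged.columns]
    return (
        merged[keep]
        .sort_values(["tsg", "target", "drug"], kind="mergesort")
        .reset_index(drop=True)
    )
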