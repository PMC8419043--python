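"""Shared statistical kernels.

Thin wrappers around scipy/statsmodels/lifelines with the tie, sidedness
and small-sample conventions the screens need in one place:

- rank-sum tests are exact (no-tie, both groups <= 25) or normal-
  approximated with midranks and continuity correction otherwise;
- Spearman p-values are exact pairing-permutation probabilities for n <= 9
  and t-approximated above;
- the two-sample log-rank test supports stratification by cohort via the
  standard summed observed-minus-expected / variance decomposition.
"""
from __future__ import annotations

import logging
import math
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

EXACT_N_MAX = 25
SPEARMAN_EXACT_N_MAX = 9


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def rank_sum(x, y, alternative: str = "greater") -> float:
    """Wilcoxon rank-sum p-value for location shift of x relative to y.

    Exact null enumeration when both groups are small and tie-free,
    otherwise the midrank normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    if max(len(x), len(y)) <= EXACT_N_MAX and not _has_ties(x, y):
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


def spearman_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Spearman rank correlation and its p-value.

    For n <= 9 the p-value is the exact probability over all pairings of
    observing a correlation at least as extreme; above that, the usual
    t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        return float("nan"), float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho = float(sps.spearmanr(x, y).statistic)
    if n <= SPEARMAN_EXACT_N_MAX:
        def stat(xx):
            return sps.spearmanr(xx, y).statistic

        res = sps.permutation_test(
            (x,),
            stat,
            permutation_type="pairings",
            alternative=alternative,
            n_resamples=math.inf,
        )
        return rho, float(res.pvalue)
    p = float(sps.spearmanr(x, y, alternative=alternative).pvalue)
    return rho, p


def stratified_logrank(
    time, event, group, strata=None
) -> tuple[float, float]:
    """Two-sample log-rank test, optionally stratified.

    Sums the per-stratum observed-minus-expected deaths in the indicated
    group and the hypergeometric variance over event times; the squared
    standardised sum is chi-squared with 1 df. With a single stratum this
    is the ordinary (Mantel-Cox) log-rank test.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "group": np.asarray(group, dtype=int),
        }
    )
    df["stratum"] = "all" if strata is None else np.asarray(strata)
    oe = 0.0
    var = 0.0
    for _, block in df.groupby("stratum"):
        times = np.sort(block.loc[block["event"] == 1, "time"].unique())
        for t in times:
            at_risk = block["time"] >= t
            n = int(at_risk.sum())
            n1 = int((at_risk & (block["group"] == 1)).sum())
            deaths = block.loc[(block["time"] == t) & (block["event"] == 1)]
            d = len(deaths)
            d1 = int((deaths["group"] == 1).sum())
            if n == 0:
                continue
            oe += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = oe * oe / var
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def cox_hazard_ratio(
    time, event, covariate, strata=None, z_score: bool = False
) -> tuple[float, float]:
    """Hazard ratio and Wald p for one covariate in a (stratified) Cox model.

    Returns (nan, nan) when the fit cannot be performed (degenerate group
    composition or non-convergence); callers treat that as a failed gate.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "x": np.asarray(covariate, dtype=float),
        }
    )
    strata_cols = None
    if strata is not None:
        df["stratum"] = np.asarray(strata)
        strata_cols = ["stratum"]
    if df["x"].nunique() < 2:
        return float("nan"), float("nan")
    if z_score:
        df["x"] = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)
    cph = CoxPHFitter(penalizer=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event", strata=strata_cols)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        log.debug("Cox fit failed: %s", exc)
        return float("nan"), float("nan")
    row = cph.summary.loc["x"]
    return float(np.exp(row["coef"])), float(row["p"])


def hypergeom_enrichment_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) with set size K, draw n, universe N."""
    if k < 0 or K < 0 or n < 0 or k > min(K, n) or K > N or n > N:
        raise ValueError("inconsistent hypergeometric counts")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def fisher_depletion_p(n_both: int, n_a_only: int, n_b_only: int, n_neither: int) -> float:
    """One-sided Fisher exact p for co-occurrence depletion (fewer co-mutated
    samples than expected at fixed margins)."""
    table = [[n_both, n_a_only], [n_b_only, n_neither]]
    return float(sps.fisher_exact(table, alternative="less")[1])
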