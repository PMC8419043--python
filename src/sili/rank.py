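"""Order-statistics rank aggregation (Stuart's method) and the RAS.

Each candidate pair is ranked under every criterion (functional similarity,
fold change and correlation descending; hazard ratio ascending, since a
stronger protective effect is better), ranks are converted to rank ratios
r = midrank / n, and Stuart's order-statistics probability

    q(r) = P( U_(k) <= r_(k) for all k ),   U_1..U_N iid Uniform(0,1)

is computed by the exact recursion. A small q means the pair sits
improbably high under all criteria simultaneously; the rank aggregation
score RAS = -log10(q) orders candidates best-first.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: criterion name -> True if larger scores are better
DEFAULT_DIRECTIONS: dict[str, bool] = {
    "fs_score": True,
    "log2_fold_change": True,
    "spearman_rho": True,
    "hazard_ratio": False,
}


def rank_ratios(
    scores: pd.DataFrame, directions: Mapping[str, bool] | None = None
) -> pd.DataFrame:
    """Per-criterion rank ratios in (0, 1], midranks for ties.

    ``scores``: one row per candidate, one column per criterion; every entry
    must be finite. ``directions[c]`` is True when larger is better.
    """
    directions = dict(directions or DEFAULT_DIRECTIONS)
    missing = set(directions) - set(scores.columns)
    if missing:
        raise ValueError(f"criteria absent from score table: {sorted(missing)}")
    if not np.isfinite(scores[list(directions)].to_numpy()).all():
        raise ValueError("non-finite criterion scores; impute or drop candidates first")
    n = len(scores)
    out = {}
    for crit, larger_better in directions.items():
        vals = scores[crit].to_numpy(dtype=float)
        ranks = rankdata(-vals if larger_better else vals, method="average")
        out[crit] = ranks / n
    return pd.DataFrame(out, index=scores.index)


def stuart_q(r: Sequence[float]) -> float:
    """Exact Stuart order-statistics probability for one rank-ratio vector.

    Uses the alternating factorial recursion over the ascending-sorted
    ratios (the same recursion rank-aggregation packages implement); for
    N=1 it reduces to q = r.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or len(r) == 0:
        raise ValueError("rank-ratio vector must be non-empty and 1-D")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("rank ratios must lie in (0, 1]")
    rs = np.sort(r)
    n = len(rs)
    v = [1.0]
    for k in range(1, n + 1):
        # v_k built from v_0..v_{k-1} and the (N-k+1)-th largest ratio
        x = rs[n - k]
        total = 0.0
        for i in range(1, k + 1):
            total += (-1) ** (i - 1) * v[k - i] * x**i / math.factorial(i)
        v.append(total)
    return float(math.factorial(n) * v[n])


def stuart_q_monte_carlo(
    r: Sequence[float], n_draws: int = 1_000_000, seed: int | None = None
) -> float:
    """Monte-Carlo estimate of the Stuart probability (the definition itself).

    Kept as an independent check of :func:`stuart_q`; never used in the
    pipeline path.
    """
    r = np.sort(np.asarray(r, dtype=float))
    rng = np.random.default_rng(seed)
    u = np.sort(rng.random((n_draws, len(r))), axis=1)
    return float((u <= r).all(axis=1).mean())


def ras(q: float) -> float:
    """Rank aggregation score: -log10(q); q=1 maps to 0."""
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    return -math.log10(q)


def aggregate(
    candidates: pd.DataFrame,
    directions: Mapping[str, bool] | None = None,
    pair_columns: tuple[str, str] = ("tsg", "target"),
) -> pd.DataFrame:
    """Attach rank ratios, q, RAS and the final rank to a candidate table.

    Ordering is deterministic: RAS descending, then q ascending, then pair
    identifier lexicographic. Input row order never matters.
    """
    directions = dict(directions or DEFAULT_DIRECTIONS)
    out = candidates.copy()
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        out["ras"] = pd.Series(dtype=float)
        out["final_rank"] = pd.Series(dtype=int)
        return out
    ratios = rank_ratios(out, directions)
    for crit in directions:
        out[f"rr_{crit}"] = ratios[crit]
    out["q"] = [stuart_q(row) for row in ratios.to_numpy()]
    out["ras"] = [ras(q) for q in out["q"]]
    a, b = pair_columns
    out = out.sort_values(
        ["ras", "q", a, b], ascending=[False, True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out
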