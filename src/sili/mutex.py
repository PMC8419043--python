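"""Mutual-exclusivity diagnostic on binary mutation matrices.

Mutual exclusivity (fewer co-mutated samples than expected) is a classic
synthetic-lethality signal, but it is underpowered on sparse mutation
profiles, which is why it is a stand-alone diagnostic here rather than a
screening gate. Two tests are provided:

- a one-sided Fisher exact test for co-occurrence depletion (fast; assumes
  homogeneous per-sample mutation rates), and
- a margin-preserving permutation test that randomises the matrix by
  checkerboard swaps, which keeps every per-gene and per-sample mutation
  count fixed and is therefore robust to heterogeneous mutation rates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SiliConfig
from .stats import bh_adjust, fisher_depletion_p


@dataclass(frozen=True)
class MutexResult:
    gene_a: str
    gene_b: str
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    p: float


def _counts(matrix: pd.DataFrame, a: str, b: str) -> tuple[int, int, int, int]:
    va = matrix.loc[a].to_numpy().astype(bool)
    vb = matrix.loc[b].to_numpy().astype(bool)
    n_both = int((va & vb).sum())
    n_a = int((va & ~vb).sum())
    n_b = int((~va & vb).sum())
    n_neither = int((~va & ~vb).sum())
    return n_both, n_a, n_b, n_neither


def fisher_mutex(pairs, matrix: pd.DataFrame, config: SiliConfig | None = None) -> pd.DataFrame:
    """Fisher exact depletion test for each pair; BH across tested pairs."""
    config = config or SiliConfig()
    rows = []
    for a, b in pairs:
        nb, na_, nb_, nn = _counts(matrix, a, b)
        p = fisher_depletion_p(nb, na_, nb_, nn)
        rows.append(MutexResult(a, b, nb, na_, nb_, nn, p))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["p_adj"] = bh_adjust(out["p"])
    out["significant_adjusted"] = out["p_adj"] < config.mutex_adjusted_alpha
    out["significant_nominal"] = out["p"] < config.mutex_nominal_alpha
    return out


def checkerboard_randomize(
    matrix: np.ndarray, n_swaps: int, rng: np.random.Generator
) -> np.ndarray:
    """Degree-preserving randomisation by repeated 2x2 checkerboard swaps.

    Each attempted swap picks two rows and two columns; when the 2x2
    submatrix is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]) it is
    flipped, which preserves every row and column sum exactly.
    """
    m = matrix.copy()
    n_rows, n_cols = m.shape
    rows1 = rng.integers(0, n_rows, size=n_swaps)
    rows2 = rng.integers(0, n_rows, size=n_swaps)
    cols1 = rng.integers(0, n_cols, size=n_swaps)
    cols2 = rng.integers(0, n_cols, size=n_swaps)
    for r1, r2, c1, c2 in zip(rows1, rows2, cols1, cols2):
        if r1 == r2 or c1 == c2:
            continue
        a, b, c, d = m[r1, c1], m[r1, c2], m[r2, c1], m[r2, c2]
        if a == d and b == c and a != b:
            m[r1, c1], m[r1, c2] = b, a
            m[r2, c1], m[r2, c2] = c ^ 1, d ^ 1
    return m


def permutation_mutex(
    pairs,
    matrix: pd.DataFrame,
    n_swaps: int | None = None,
    n_perms: int = 200,
    seed: int = 0,
    config: SiliConfig | None = None,
) -> pd.DataFrame:
    """Empirical depletion p-values from margin-preserving permutations.

    p = (1 + #{null co-occurrence <= observed}) / (n_perms + 1). Deterministic
    given ``seed``.
    """
    config = config or SiliConfig()
    arr = matrix.to_numpy().astype(np.int8)
    if n_swaps is None:
        n_swaps = 5 * int(arr.sum())
    rng = np.random.default_rng(seed)
    gene_idx = {g: i for i, g in enumerate(matrix.index)}
    observed = {}
    for a, b in pairs:
        observed[(a, b)] = int((arr[gene_idx[a]] & arr[gene_idx[b]]).sum())
    at_most = {pair: 0 for pair in observed}
    for _ in range(n_perms):
        null = checkerboard_randomize(arr, n_swaps, rng)
        for (a, b), obs in observed.items():
            co = int((null[gene_idx[a]] & null[gene_idx[b]]).sum())
            if co <= obs:
                at_most[(a, b)] += 1
    rows = []
    for a, b in pairs:
        nb, na_, nb_, nn = _counts(matrix, a, b)
        p = (1 + at_most[(a, b)]) / (n_perms + 1)
        rows.append(MutexResult(a, b, nb, na_, nb_, nn, p))
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["p_adj"] = bh_adjust(out["p"])
    out["significant_adjusted"] = out["p_adj"] < config.mutex_adjusted_alpha
    out["significant_nominal"] = out["p"] < config.mutex_nominal_alpha
    return out
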