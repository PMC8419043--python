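"""Stuart order-statistics aggregation: anchors, Monte-Carlo agreement,
dominance and invariance properties."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sili.rank import (
    DEFAULT_DIRECTIONS,
    aggregate,
    rank_ratios,
    ras,
    stuart_q,
    stuart_q_monte_carlo,
)


class TestStuartQ:
    def test_analytic_anchors(self):
        assert stuart_q([0.3]) == pytest.approx(0.3, abs=1e-12)
        assert stuart_q([1.0, 1.0]) == pytest.approx(1.0, abs=1e-12)
        assert stuart_q([0.5, 0.5]) == pytest.approx(0.25, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stuart_q([0.0, 0.5])
        with pytest.raises(ValueError):
            stuart_q([0.5, 1.2])

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(8)
        for _ in range(8):
            n = int(rng.integers(1, 7))
            r = rng.uniform(0.05, 1.0, n)
            n_draws = 200_000
            q_mc = stuart_q_monte_carlo(r, n_draws, seed=int(rng.integers(2**31)))
            se = math_se(q_mc, n_draws)
            assert abs(stuart_q(r) - q_mc) <= 3 * se + 1e-9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_dominance_increasing_a_ratio_never_decreases_q(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        r = rng.uniform(0.05, 0.95, n)
        q0 = stuart_q(r)
        i = int(rng.integers(n))
        r2 = r.copy()
        r2[i] = min(1.0, r2[i] + rng.uniform(0, 1 - r2[i]))
        assert stuart_q(r2) >= q0 - 1e-12

    def test_sorted_input_invariance(self):
        r = [0.9, 0.1, 0.5, 0.3]
        assert stuart_q(r) == stuart_q(sorted(r))


def math_se(q, n):
    return np.sqrt(max(q * (1 - q), 1e-12) / n)


class TestRankRatios:
    def test_dominant_candidate(self):
        scores = pd.DataFrame(
            {
                "fs_score": [0.9, 0.2],
                "log2_fold_change": [2.0, 0.1],
                "spearman_rho": [0.5, 0.2],
                "hazard_ratio": [0.4, 0.9],
            },
            index=["winner", "loser"],
        )
        rr = rank_ratios(scores)
        assert (rr.loc["winner"] == 0.5).all()
        assert (rr.loc["loser"] == 1.0).all()

    def test_midrank_ties(self):
        scores = pd.DataFrame(
            {
                "fs_score": [0.9, 0.9],
                "log2_fold_change": [1.0, 1.0],
                "spearman_rho": [0.3, 0.3],
                "hazard_ratio": [0.5, 0.5],
            }
        )
        rr = rank_ratios(scores)
        assert (rr.to_numpy() == 0.75).all()

    def test_hazard_ratio_ranked_ascending(self):
        scores = pd.DataFrame(
            {
                "fs_score": [0.5, 0.5],
                "log2_fold_change": [1.0, 1.0],
                "spearman_rho": [0.3, 0.3],
                "hazard_ratio": [0.3, 0.8],
            },
            index=["protective", "weak"],
        )
        rr = rank_ratios(scores)
        assert rr.loc["protective", "hazard_ratio"] == 0.5
        assert rr.loc["weak", "hazard_ratio"] == 1.0

    def test_five_candidate_hand_fixture(self):
        scores = pd.DataFrame(
            {
                "fs_score": [0.9, 0.8, 0.7, 0.6, 0.5],
                "log2_fold_change": [0.1, 0.2, 0.3, 0.4, 0.5],
                "spearman_rho": [0.5, 0.4, 0.3, 0.2, 0.1],
                "hazard_ratio": [0.9, 0.8, 0.7, 0.6, 0.5],
            }
        )
        rr = rank_ratios(scores)
        np.testing.assert_allclose(rr["fs_score"], [0.2, 0.4, 0.6, 0.8, 1.0])
        np.testing.assert_allclose(rr["log2_fold_change"], [1.0, 0.8, 0.6, 0.4, 0.2])
        np.testing.assert_allclose(rr["spearman_rho"], [0.2, 0.4, 0.6, 0.8, 1.0])
        np.testing.assert_allclose(rr["hazard_ratio"], [1.0, 0.8, 0.6, 0.4, 0.2])

    def test_non_finite_scores_rejected(self):
        scores = pd.DataFrame(
            {
                "fs_score": [0.9, np.nan],
                "log2_fold_change": [1.0, 1.0],
                "spearman_rho": [0.3, 0.3],
                "hazard_ratio": [0.5, 0.5],
            }
        )
        with pytest.raises(ValueError, match="non-finite"):
            rank_ratios(scores)


class TestRAS:
    def test_values(self):
        assert ras(1.0) == 0.0
        assert ras(0.01) == pytest.approx(2.0)
        assert ras(0.25) == pytest.approx(0.602, abs=1e-3)


def _random_candidates(rng, n):
    return pd.DataFrame(
        {
            "tsg": [f"T{i % 3}" for i in range(n)],
            "target": [f"D{i}" for i in range(n)],
            "fs_score": rng.uniform(0.5, 1.0, n),
            "log2_fold_change": rng.uniform(0, 2, n),
            "spearman_rho": rng.uniform(0.15, 0.9, n),
            "hazard_ratio": rng.uniform(0.2, 0.99, n),
        }
    )


class TestAggregate:
    def test_dominant_pair_ranks_first(self):
        rng = np.random.default_rng(0)
        cand = _random_candidates(rng, 10)
        cand.loc[0, ["fs_score", "log2_fold_change", "spearman_rho"]] = [1.0, 3.0, 0.99]
        cand.loc[0, "hazard_ratio"] = 0.1
        out = aggregate(cand)
        assert out.iloc[0]["target"] == "D0"
        assert out.iloc[0]["final_rank"] == 1

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        cand = _random_candidates(rng, 20)
        out1 = aggregate(cand)
        out2 = aggregate(cand.sample(frac=1, random_state=3).reset_index(drop=True))
        pd.testing.assert_frame_equal(out1, out2)

    def test_matches_brute_force_q(self):
        rng = np.random.default_rng(2)
        cand = _random_candidates(rng, 20)
        out = aggregate(cand)
        # independent recomputation: ranks via argsort, q via Monte Carlo
        for _, row in out.head(5).iterrows():
            r = sorted(
                row[["rr_fs_score", "rr_log2_fold_change", "rr_spearman_rho",
                     "rr_hazard_ratio"]]
            )
            q_mc = stuart_q_monte_carlo(r, 200_000, seed=9)
            assert abs(row["q"] - q_mc) <= 3 * math_se(q_mc, 200_000) + 1e-9
        np.testing.assert_allclose(out["ras"], -np.log10(out["q"]), rtol=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        cand = _random_candidates(rng, 15)
        out1 = aggregate(cand)
        cand2 = cand.copy()
        cand2["log2_fold_change"] = np.exp(cand2["log2_fold_change"] * 3)
        out2 = aggregate(cand2)
        assert list(out1["target"]) == list(out2["target"])
        np.testing.assert_allclose(out1["q"], out2["q"])

    def test_empty_table(self):
        out = aggregate(_random_candidates(np.random.default_rng(0), 0))
        assert len(out) == 0
        assert {"q", "ras", "final_rank"} <= set(out.columns)
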