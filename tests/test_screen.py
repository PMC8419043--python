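"""The four screening gates and the combined candidate selection."""
import numpy as np
import pandas as pd
import pytest

from sili.config import SiliConfig
from sili.datatypes import ValidationError
from sili.io import centered_log_expression
from sili.screen import (
    coexpression,
    differential_expression,
    inactivation_status,
    mutant_wildtype_split,
    pairwise_survival,
    run_sili,
)


class TestDifferentialExpression:
    def test_upregulated_target_passes(self, mini_cohort):
        out = differential_expression(mini_cohort, "TSG", ["TARGET", "OTHER"])
        assert bool(out.loc["TARGET", "de_gate"])
        assert out.loc["TARGET", "log2_fold_change"] > 0

    def test_identical_groups_fail(self, mini_cohort):
        out = differential_expression(mini_cohort, "TSG", ["OTHER"])
        assert not bool(out.loc["OTHER", "de_gate"])

    def test_missing_tsg_raises(self, mini_cohort):
        with pytest.raises(ValidationError, match="absent"):
            differential_expression(mini_cohort, "NOPE", ["TARGET"])

    def test_underpowered_group(self, mini_cohort):
        mini_cohort.mutation_matrix.loc["TSG"] = [0] * 7 + [1]
        out = differential_expression(mini_cohort, "TSG", ["TARGET"])
        assert out.loc["TARGET", "de_reason"] == "underpowered"
        assert not bool(out.loc["TARGET", "de_gate"])

    def test_power_at_large_n(self, default_bundle):
        # planted upshift of one log2 unit at ~100 vs ~400 samples
        gt = default_bundle.ground_truth
        tsg, target = gt.planted_pairs[0]
        out = differential_expression(default_bundle.cohort, tsg, [target])
        assert out.loc[target, "de_p"] < 1e-6


class TestCoexpression:
    def test_monotone_pair(self, mini_cohort):
        centered = centered_log_expression(mini_cohort.expression)
        centered.loc["TSG"] = np.arange(8.0)
        centered.loc["TARGET"] = np.arange(8.0) ** 2
        rho, p = coexpression(mini_cohort, ("TSG", "TARGET"), centered=centered)
        assert rho == 1.0

    def test_antimonotone_pair(self, mini_cohort):
        centered = centered_log_expression(mini_cohort.expression)
        centered.loc["TSG"] = np.arange(8.0)
        centered.loc["TARGET"] = -np.arange(8.0)
        rho, _ = coexpression(mini_cohort, ("TSG", "TARGET"), centered=centered)
        assert rho == -1.0


class TestInactivation:
    def test_below_median_strict(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=list("abcd"))
        out = inactivation_status(m)
        assert list(out.loc["g"]) == [1, 1, 0, 0]

    def test_constant_gene_never_inactive(self):
        m = pd.DataFrame([[5.0] * 4], index=["g"], columns=list("abcd"))
        assert inactivation_status(m).loc["g"].sum() == 0

    def test_value_at_median_is_active(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = inactivation_status(m)
        assert list(out.loc["g"]) == [1, 0, 0]


class TestPairwiseSurvival:
    def test_planted_hazard_ratios_protective(self, default_bundle):
        # marginal per-pair HRs compound below the configured 0.5 because
        # samples co-inactive for one planted pair are often co-inactive for
        # others (shared TSG latent factors)
        cohort = default_bundle.cohort
        gt = default_bundle.ground_truth
        inactive = inactivation_status(centered_log_expression(cohort.expression))
        hits = 0
        for pair in gt.planted_pairs:
            res = pairwise_survival(cohort, pair, inactive)
            if res["surv_gate"]:
                hits += 1
                assert 0.1 < res["hazard_ratio"] < 0.8
        assert hits >= 8

    def test_single_planted_pair_hazard_ratio_recovered(self):
        # isolated pair: the estimated HR should sit near the planted 0.5
        from sili.simulate import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(seed=6, n_planted=1, n_dt=10)
        cohort, gt, _ = generate_cohort(cfg)
        inactive = inactivation_status(centered_log_expression(cohort.expression))
        res = pairwise_survival(cohort, gt.planted_pairs[0], inactive)
        assert res["surv_gate"]
        assert 0.35 < res["hazard_ratio"] < 0.7

    def test_no_survival_data_fails_with_reason(self, mini_cohort):
        mini_cohort.survival = None
        inactive = inactivation_status(
            centered_log_expression(mini_cohort.expression)
        )
        res = pairwise_survival(mini_cohort, ("TSG", "TARGET"), inactive)
        assert not res["surv_gate"]
        assert res["surv_reason"] == "no survival data"

    def test_small_cohort_underpowered_reason(self, mini_cohort):
        inactive = inactivation_status(
            centered_log_expression(mini_cohort.expression)
        )
        res = pairwise_survival(mini_cohort, ("TSG", "TARGET"), inactive)
        assert "fewer than" in res["surv_reason"]


class TestRunSili:
    def test_planted_pairs_recovered_small(self, small_bundle):
        gt = small_bundle.ground_truth
        out = run_sili(
            small_bundle.cohort, gt.tsgs, gt.dt_genes, small_bundle.ontology
        )
        got = set(zip(out.candidates["tsg"], out.candidates["target"]))
        planted = set(gt.planted_pairs)
        assert len(got & planted) >= len(planted) - 1
        decoys = got - planted
        assert len(decoys) <= 0.05 * (len(out.audit) - len(planted))

    def test_gate_conjunction(self, small_bundle):
        gt = small_bundle.ground_truth
        out = run_sili(
            small_bundle.cohort, gt.tsgs, gt.dt_genes, small_bundle.ontology
        )
        gates = out.audit[["g1_fs", "g2_de", "g3_coexp", "g4_surv"]].all(axis=1)
        assert (out.audit["passed_all"] == gates).all()

    def test_impossible_threshold_empties_candidates(self, small_bundle):
        gt = small_bundle.ground_truth
        cfg = SiliConfig(fs_threshold=1.1)
        out = run_sili(
            small_bundle.cohort, gt.tsgs, gt.dt_genes, small_bundle.ontology, cfg
        )
        assert out.n_candidates == 0

    def test_loosening_thresholds_is_monotone(self, small_bundle):
        gt = small_bundle.ground_truth
        strict = run_sili(
            small_bundle.cohort, gt.tsgs, gt.dt_genes, small_bundle.ontology,
            SiliConfig(),
        )
        loose = run_sili(
            small_bundle.cohort, gt.tsgs, gt.dt_genes, small_bundle.ontology,
            SiliConfig(fs_threshold=0.2, de_alpha=0.2, coexp_rho=0.05,
                       coexp_alpha=0.2, surv_alpha=0.2),
        )
        strict_set = set(zip(strict.candidates["tsg"], strict.candidates["target"]))
        loose_set = set(zip(loose.candidates["tsg"], loose.candidates["target"]))
        assert strict_set <= loose_set

    def test_split_helper(self, mini_cohort):
        mut, wt = mutant_wildtype_split(mini_cohort, "TSG")
        assert len(mut) == 4 and len(wt) == 4
        assert set(mut).isdisjoint(wt)
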