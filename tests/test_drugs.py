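"""Ridge drug-response imputation and the TSG-target-drug extension."""
import numpy as np
import pandas as pd
import pytest

from sili.datatypes import ValidationError
from sili.drugs import (
    differential_response,
    extend_to_triples,
    map_drugs,
    predict_response,
    train_response_model,
)
from sili.io import log2_tpm


@pytest.fixture(scope="module")
def trained(small_bundle):
    gt = small_bundle.ground_truth
    drug = gt.planted_drugs[gt.planted_pairs[0][1]]
    model = train_response_model(small_bundle.panel, drug, seed=1)
    return drug, model


class TestTraining:
    def test_planted_drug_has_signal(self, trained, small_bundle):
        drug, model = trained
        assert model.cv_r2 >= 0.3
        target = drug.removesuffix("-inh")
        # the target's coefficient must point the right way (lower AUC at
        # higher expression)
        idx = list(model.genes).index(target)
        assert model.coef[idx] < 0

    def test_noise_drug_flagged(self, small_bundle):
        model = train_response_model(small_bundle.panel, "decoy01-inh", seed=1)
        assert model.cv_r2 < 0.2

    def test_determinism(self, small_bundle):
        gt = small_bundle.ground_truth
        drug = gt.planted_drugs[gt.planted_pairs[0][1]]
        m1 = train_response_model(small_bundle.panel, drug, seed=7)
        m2 = train_response_model(small_bundle.panel, drug, seed=7)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.alpha == m2.alpha

    def test_too_few_lines_rejected(self, small_bundle):
        panel = small_bundle.panel
        crippled = panel.auc.copy()
        crippled.iloc[20:, :] = np.nan
        from sili.drugs import DrugPanel

        p2 = DrugPanel(
            expression=panel.expression,
            auc=crippled,
            annotations=panel.annotations,
            tissue=panel.tissue,
        )
        with pytest.raises(ValidationError, match="usable lines"):
            train_response_model(p2, p2.auc.columns[0], seed=0)

    def test_lymphoid_lines_excluded(self, small_bundle):
        drug = small_bundle.panel.auc.columns[0]
        model = train_response_model(small_bundle.panel, drug, seed=0)
        n_lymph = (small_bundle.panel.tissue == "haematopoietic_and_lymphoid_tissue").sum()
        assert model.n_lines == small_bundle.panel.auc.shape[0] - n_lymph


class TestPrediction:
    def test_training_line_reproduces_fitted_value(self, trained, small_bundle):
        drug, model = trained
        line = model.fitted.index[0]
        clinical = small_bundle.panel.expression[[line]]
        pred = predict_response(model, clinical)
        assert pred.loc[line] == pytest.approx(model.fitted.loc[line], abs=1e-9)

    def test_gene_order_invariance(self, trained, small_bundle):
        drug, model = trained
        clinical = log2_tpm(small_bundle.cohort.expression)
        p1 = predict_response(model, clinical)
        p2 = predict_response(model, clinical.iloc[::-1])
        pd.testing.assert_series_equal(p1, p2)

    def test_missing_genes_warn_and_still_predict(self, trained, small_bundle, caplog):
        drug, model = trained
        clinical = log2_tpm(small_bundle.cohort.expression)
        kept = clinical.loc[model.genes[: int(len(model.genes) * 0.5)]]
        with caplog.at_level("WARNING"):
            pred = predict_response(model, kept)
        assert np.isfinite(pred).all()
        assert any("missing" in r.message for r in caplog.records)

    def test_upshifted_target_lowers_predicted_auc(self, trained, small_bundle):
        drug, model = trained
        target = drug.removesuffix("-inh")
        clinical = log2_tpm(small_bundle.cohort.expression)
        boosted = clinical.copy()
        boosted.loc[target] += 2.0
        assert (
            predict_response(model, boosted).mean()
            < predict_response(model, clinical).mean()
        )


class TestScaleInvariance:
    def test_auc_rescaling_scales_predictions(self, small_bundle):
        from sili.drugs import DrugPanel

        gt = small_bundle.ground_truth
        drug = gt.planted_drugs[gt.planted_pairs[0][1]]
        panel = small_bundle.panel
        scaled = DrugPanel(
            expression=panel.expression,
            auc=panel.auc * 3.0,
            annotations=panel.annotations,
            tissue=panel.tissue,
        )
        m1 = train_response_model(panel, drug, seed=2)
        m2 = train_response_model(scaled, drug, seed=2)
        assert m2.alpha == m1.alpha
        assert m2.cv_r2 == pytest.approx(m1.cv_r2, abs=1e-9)
        clinical = log2_tpm(small_bundle.cohort.expression)
        np.testing.assert_allclose(
            predict_response(m2, clinical), 3.0 * predict_response(m1, clinical),
            rtol=1e-8,
        )


class TestDifferentialResponse:
    def test_planted_tsg_drug_link(self, small_bundle):
        gt = small_bundle.ground_truth
        tsg, target = gt.planted_pairs[0]
        drug = gt.planted_drugs[target]
        model = train_response_model(small_bundle.panel, drug, seed=1)
        imputed = pd.DataFrame(
            {drug: predict_response(model, log2_tpm(small_bundle.cohort.expression))}
        )
        out = differential_response(imputed, small_bundle.cohort.mutation_matrix, tsg)
        assert out.loc[0, "median_auc_diff"] < 0
        assert out.loc[0, "p"] < 0.05

    def test_all_wildtype_raises(self, small_bundle):
        gt = small_bundle.ground_truth
        mat = small_bundle.cohort.mutation_matrix.copy()
        mat.loc[gt.tsgs[0]] = 0
        imputed = pd.DataFrame(
            {"d": np.zeros(mat.shape[1])}, index=mat.columns
        )
        with pytest.raises(ValidationError, match="empty mutant"):
            differential_response(imputed, mat, gt.tsgs[0])


class TestMapDrugs:
    def test_rules(self):
        table = pd.DataFrame(
            {
                "drug": ["plkx", "PLKX", "ago-drug", "stray"],
                "target": ["PLK1", "PLK1", "PLK1", "NOPE"],
                "moa": ["inhibitor", "inhibitor", "agonist", "inhibitor"],
            }
        )
        out = map_drugs(table, {"PLK1"})
        # case-insensitive dedup keeps a single PLK1 inhibitor edge
        assert len(out) == 1
        assert out.loc[0, "target"] == "PLK1"
        assert "ago-drug" not in set(out["drug"])

    def test_extension_join(self):
        candidates = pd.DataFrame({"tsg": ["T1"], "target": ["D1"]})
        drug_map = pd.DataFrame(
            {"drug": ["d1", "d2"], "target": ["D1", "D1"], "moa": ["inhibitor"] * 2}
        )
        differential = pd.DataFrame(
            {
                "tsg": ["T1", "T1"],
                "drug": ["d1", "d2"],
                "median_auc_diff": [-0.5, -0.1],
                "p": [0.001, 0.5],
                "p_adj": [0.002, 0.5],
                "gate": [True, False],
            }
        )
        out = extend_to_triples(candidates, drug_map, differential)
        assert len(out) == 1
        assert out.loc[0, "drug"] == "d1"
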