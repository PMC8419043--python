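"""Pipeline configuration: every screening threshold in one schema.

Defaults are the published operating point of the pipeline: FS > 0.5,
BH-adjusted p < 0.05 for differential expression and co-expression,
Spearman rho > 0.15, survival p < 0.05 with hazard ratio < 1, 10 functional
mutations per sample, 2.5% gene mutation frequency, 20% LOF fraction for
the tumor-suppressor call.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class SiliConfig:
    # mutation prep
    min_mutations_per_sample: int = 10
    min_gene_frequency: float = 0.025
    lof_threshold: float = 0.20
    # gate 1: functional similarity
    fs_threshold: float = 0.5
    # gate 2: differential expression
    de_alpha: float = 0.05
    min_group: int = 2
    # gate 3: co-expression
    coexp_rho: float = 0.15
    coexp_alpha: float = 0.05
    # gate 4: pairwise survival
    surv_alpha: float = 0.05
    min_survival_samples: int = 30
    # mutual exclusivity diagnostic
    mutex_adjusted_alpha: float = 0.15
    mutex_nominal_alpha: float = 0.05
    # drug extension
    drug_alpha: float = 0.05
    min_lines_per_drug: int = 30
    n_feature_genes: int = 5000
    ridge_folds: int = 10
    ridge_lambda_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    domain_zscore: bool = False
    # characterization
    enrich_alpha: float = 0.05
    tn_de_alpha: float = 0.01
    tn_de_lfc: float = 1.0
    dependency_resamples: int = 1000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ridge_lambda_grid"] = list(d["ridge_lambda_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SiliConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "ridge_lambda_grid" in kwargs:
            kwargs["ridge_lambda_grid"] = tuple(kwargs["ridge_lambda_grid"])
        return cls(**kwargs)
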