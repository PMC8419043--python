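"""Core in-memory containers for the pipeline.

Everything is a thin, validated wrapper around pandas objects so that the
statistical modules can work with plain DataFrames/Series while ingestion
enforces the invariants once, up front.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Closed vocabulary of variant classes after MAF-dialect normalisation.
VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "inframe_indel",
    "silent",
    "intronic",
    "intergenic",
    "other",
)

#: Classes carrying no (presumed) functional consequence; removed before analysis.
NONFUNCTIONAL_CLASSES = frozenset({"silent", "intronic", "intergenic"})

#: Truncating classes presumed to abolish protein function.
LOF_CLASSES = frozenset({"nonsense", "frameshift"})

TPM_TOTAL = 1e6


class SiliError(Exception):
    """Base class for pipeline errors."""


class ParseError(SiliError):
    """Raised when an input file violates its format contract."""


class ValidationError(SiliError):
    """Raised when parsed data violate a model invariant."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with a declared unit.

    values: DataFrame, rows=genes, columns=samples, non-negative.
    unit: one of {"counts", "fpkm", "tpm"}.
    cohort: optional Series mapping sample -> cohort label.
    """

    values: pd.DataFrame
    unit: str
    cohort: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.unit = self.unit.lower()
        if self.unit not in {"counts", "fpkm", "tpm"}:
            raise ValidationError(f"unknown expression unit: {self.unit!r}")
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("expression contains non-finite values")
        if (arr < 0).any():
            raise ValidationError("expression contains negative values")
        if self.unit == "tpm":
            colsums = arr.sum(axis=0)
            if (colsums == 0).any():
                bad = v.columns[colsums == 0].tolist()
                raise ValidationError(f"all-zero TPM columns: {bad[:5]}")
            if not np.allclose(colsums, TPM_TOTAL, rtol=1e-6):
                raise ValidationError("TPM columns do not sum to 1e6")
        if self.cohort is not None:
            self.cohort = self.cohort.reindex(v.columns)
            if self.cohort.isna().any():
                raise ValidationError("cohort label missing for some samples")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MutationTable:
    """Long-format mutation records: one row per (sample, gene, variant_class)."""

    records: pd.DataFrame  # columns: sample, gene, variant_class [, lof]

    def __post_init__(self) -> None:
        req = {"sample", "gene", "variant_class"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValidationError(f"mutation table missing columns: {sorted(missing)}")
        r = self.records
        if r["sample"].isna().any() or (r["sample"].astype(str) == "").any():
            raise ValidationError("empty sample identifiers in mutation table")
        if r["gene"].isna().any() or (r["gene"].astype(str) == "").any():
            raise ValidationError("empty gene identifiers in mutation table")
        bad = set(r["variant_class"]) - set(VARIANT_CLASSES)
        if bad:
            raise ValidationError(f"variant classes outside vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.records["sample"].unique())

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.records["gene"].unique())


@dataclass
class SurvivalTable:
    """Right-censored follow-up: one row per sample, time in days, event 1=death."""

    records: pd.DataFrame  # columns: sample, time, event

    def __post_init__(self) -> None:
        req = {"sample", "time", "event"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValidationError(f"survival table missing columns: {sorted(missing)}")
        r = self.records
        if r["sample"].duplicated().any():
            raise ValidationError("duplicate samples in survival table")
        if (r["time"] <= 0).any():
            raise ValidationError("non-positive survival times")
        if not r["event"].isin([0, 1]).all():
            raise ValidationError("event must be 0 or 1")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class Cohort:
    """Assembled analysis unit: TPM expression, binary mutations, survival.

    mutation_matrix: binary gene x sample DataFrame (functional mutations).
    gene_summary: per-gene counts (n_mutated_samples, mutation_frequency,
        n_functional_records, n_lof_records, lof_fraction).
    """

    expression: ExpressionMatrix
    mutation_matrix: pd.DataFrame
    gene_summary: pd.DataFrame
    survival: Optional[SurvivalTable] = None
    mutation_only_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.expression.unit != "tpm":
            raise ValidationError("cohort expression must be TPM")
        mm = self.mutation_matrix
        if not mm.isin([0, 1]).all().all():
            raise ValidationError("mutation matrix must be binary")
        expr_samples = set(self.expression.samples)
        extra = set(mm.columns) - expr_samples - set(self.mutation_only_samples)
        if extra:
            raise ValidationError(
                f"mutation samples absent from expression and not tracked: {sorted(extra)[:5]}"
            )

    @property
    def shared_samples(self) -> pd.Index:
        """Samples with both expression and mutation calls, expression order."""
        return self.expression.samples.intersection(self.mutation_matrix.columns)

    def cohort_of(self, samples) -> pd.Series:
        if self.expression.cohort is None:
            return pd.Series("cohort0", index=pd.Index(samples))
        return self.expression.cohort.reindex(samples)
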