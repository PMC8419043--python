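"""Readers/writers for the pipeline's plain-text input formats.

Supported formats: TSV/CSV expression matrices (genes x samples), MAF-like
mutation tables, survival tables, GMT gene sets, drug/target annotation CSVs
and gene-dependency CSV matrices. Unit conversion to TPM lives here too.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    TPM_TOTAL,
    VARIANT_CLASSES,
    ExpressionMatrix,
    MutationTable,
    ParseError,
    SurvivalTable,
    ValidationError,
)

log = logging.getLogger(__name__)

# MAF Variant_Classification strings -> closed vocabulary. Unknown strings map
# to "other" with a warning. Keys are matched lower-case.
MAF_CLASS_MAP: dict[str, str] = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "nonstop_mutation": "nonsense",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift": "frameshift",
    "frameshift_deletion": "frameshift",
    "frameshift_insertion": "frameshift",
    "splice_site": "splice",
    "splice_region": "splice",
    "splice": "splice",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "inframe_indel": "inframe_indel",
    "silent": "silent",
    "synonymous": "silent",
    "intron": "intronic",
    "intronic": "intronic",
    "igr": "intergenic",
    "intergenic": "intergenic",
    "translation_start_site": "other",
    "other": "other",
}


def _sep_for(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, unit_hint: str = "tpm") -> ExpressionMatrix:
    """Read a gene x sample expression matrix (TSV or CSV, header row).

    Duplicate gene rows are collapsed by summation; duplicate sample columns
    are an error. The declared unit is taken from ``unit_hint``.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_names = [c for c in header[1:] if c]
    if len(set(sample_names)) < len(sample_names):
        # pandas would silently rename duplicates, so check the raw header
        raise ParseError(f"{path}: duplicate sample names in header")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # malformed file
        raise ParseError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ParseError(f"{path}: non-numeric entries in matrix body")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative expression values")
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        log.warning("%s: collapsing %d duplicate gene rows by sum", path, n)
        df = df.groupby(level=0, sort=False).sum()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    log.info("read %s: %d genes x %d samples", path, *df.shape)
    return ExpressionMatrix(values=df, unit=unit_hint)


def write_expression(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def to_tpm(
    m: ExpressionMatrix,
    gene_lengths_kb: Optional[Mapping[str, float]] = None,
    allow_cpm_fallback: bool = False,
) -> ExpressionMatrix:
    """Convert an expression matrix to TPM.

    counts: per-gene rate = count / length_kb, then each sample column is
    scaled to sum to 1e6. FPKM: column renormalisation only (the length
    division is already folded in). TPM passes through unchanged.

    Counts without a length table raise, unless ``allow_cpm_fallback``
    explicitly requests length-free scaling (CPM treated as TPM; logged).
    """
    if m.unit == "tpm":
        return m
    values = m.values
    if m.unit == "counts":
        if gene_lengths_kb is None:
            if not allow_cpm_fallback:
                raise ValidationError(
                    "counts -> TPM requires gene lengths (or allow_cpm_fallback=True)"
                )
            log.warning("no gene lengths: falling back to CPM scaling of counts")
            rates = values
        else:
            lengths = pd.Series(gene_lengths_kb, dtype=float)
            missing = values.index.difference(lengths.index)
            if len(missing):
                raise ValidationError(
                    f"gene lengths missing for {len(missing)} genes, e.g. {missing[:5].tolist()}"
                )
            if (lengths.reindex(values.index) <= 0).any():
                raise ValidationError("gene lengths must be positive")
            rates = values.div(lengths.reindex(values.index), axis=0)
    else:  # fpkm
        rates = values
    colsums = rates.sum(axis=0)
    if (colsums == 0).any():
        bad = values.columns[colsums == 0].tolist()
        raise ValidationError(f"all-zero expression columns: {bad[:5]}")
    tpm = rates.div(colsums, axis=1) * TPM_TOTAL
    return ExpressionMatrix(values=tpm, unit="tpm", cohort=m.cohort)


def normalize_variant_class(raw: str) -> str:
    key = str(raw).strip().lower()
    if key in MAF_CLASS_MAP:
        return MAF_CLASS_MAP[key]
    if key in VARIANT_CLASSES:
        return key
    log.warning("unknown variant classification %r mapped to 'other'", raw)
    return "other"


def read_mutations(path) -> MutationTable:
    """Read a MAF-like mutation table.

    Only three columns are required — sample, gene (Hugo symbol) and the
    variant classification; several common MAF header spellings are accepted
    and extra columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    colmap = {}
    lower = {c.lower(): c for c in df.columns}
    for want, aliases in {
        "sample": ("sample", "tumor_sample_barcode", "sample_id"),
        "gene": ("gene", "hugo_symbol", "gene_symbol"),
        "variant_class": ("variant_class", "variant_classification", "effect"),
    }.items():
        for a in aliases:
            if a in lower:
                colmap[want] = lower[a]
                break
        else:
            raise ParseError(f"{path}: no column for {want} (tried {aliases})")
    out = df[[colmap["sample"], colmap["gene"], colmap["variant_class"]]].copy()
    out.columns = ["sample", "gene", "variant_class"]
    out["variant_class"] = out["variant_class"].map(normalize_variant_class)
    return MutationTable(records=out.reset_index(drop=True))


def read_survival(path) -> SurvivalTable:
    """Read a survival table with columns sample, time (days), event (0/1)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    lower = {c.lower(): c for c in df.columns}
    try:
        out = df[[lower["sample"], lower["time"], lower["event"]]].copy()
    except KeyError as exc:
        raise ParseError(f"{path}: need columns sample/time/event") from exc
    out.columns = ["sample", "time", "event"]
    out["sample"] = out["sample"].astype(str)
    return SurvivalTable(records=out.reset_index(drop=True))


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{ln}: GMT line has fewer than 3 fields")
        name, _desc, *genes = parts
        sets[name] = {g for g in genes if g}
    return sets


def write_gene_sets(sets: Mapping[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")


def read_drug_targets(path) -> pd.DataFrame:
    """Read a drug annotation CSV with columns drug, target(s), moa.

    Multiple targets may be pipe-separated; the result is exploded to one
    row per drug-target edge.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    lower = {c.lower(): c for c in df.columns}
    try:
        out = df[[lower["drug"], lower["target"], lower["moa"]]].copy()
    except KeyError as exc:
        raise ParseError(f"{path}: need columns drug/target/moa") from exc
    out.columns = ["drug", "target", "moa"]
    out["target"] = out["target"].str.split("|")
    out = out.explode("target", ignore_index=True)
    out["target"] = out["target"].str.strip()
    out = out[out["target"] != ""]
    return out.reset_index(drop=True)


def read_dependency(path) -> pd.DataFrame:
    """Read a gene x cell-line dependency score matrix (CSV/TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ParseError(f"{path}: non-numeric dependency scores")
    return df


def log2_tpm(m: ExpressionMatrix) -> pd.DataFrame:
    """log2(TPM + 1) matrix."""
    if m.unit != "tpm":
        raise ValidationError("log2_tpm expects a TPM matrix")
    return np.log2(m.values + 1.0)


def centered_log_expression(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-cohort, per-gene median-centred log2(TPM+1).

    Rank-based tests downstream are insensitive to monotone per-cohort
    shifts; this mild harmonisation makes pooled comparisons sensible when
    several cohorts are stacked.
    """
    logx = log2_tpm(m)
    if m.cohort is None:
        return logx.sub(logx.median(axis=1), axis=0)
    out = logx.copy()
    for _, cols in m.cohort.groupby(m.cohort).groups.items():
        block = logx.loc[:, cols]
        out.loc[:, cols] = block.sub(block.median(axis=1), axis=0)
    return out
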