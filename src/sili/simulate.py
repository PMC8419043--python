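"""Seeded generator of every pipeline input with planted ground truth.

The generator encodes the statistical assumptions the screens test for:

- tumor-suppressor mutations are Bernoulli per sample with a configurable
  loss-of-function fraction (planted TSGs exceed the 20% truncating
  threshold, planted oncogene decoys do not);
- planted SL partner genes are upshifted by ``delta`` log2 units in
  TSG-mutant samples (compensatory upregulation) and share a latent factor
  giving correlation ``rho_latent`` with their TSG;
- survival is Weibull with the hazard multiplied by ``hr_coinactive`` for
  each planted pair a patient is co-inactive for, plus independent
  censoring;
- the toy ontology places planted pairs on sibling leaves (FS > 0.5 by
  construction) and every other gene on its own branch (FS well below 0.5);
- the drug panel ties each planted target to an inhibitor whose AUC
  decreases with target expression (slope ``beta``), with pure-noise and
  agonist decoys.

A single master seed fans out to per-component streams (mutations,
expression, survival, ontology, drugs, dependency — in that fixed order)
via numpy SeedSequence.spawn, so stages can be regenerated independently.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import Cohort, ExpressionMatrix, MutationTable, SurvivalTable, TPM_TOTAL
from .drugs import DrugPanel
from .io import centered_log_expression, write_expression, write_gene_sets
from .ontology import OntologyGraph, write_gaf, write_obo
from .prep import prepare_mutations
from .screen import inactivation_status

FUNCTIONAL_NON_LOF = ("missense", "splice", "inframe_indel")
LOF = ("nonsense", "frameshift")
NONFUNCTIONAL = ("silent", "intronic", "intergenic")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark (defaults: a desk-scale
    multi-cohort study that runs end to end in minutes on one CPU)."""

    n_samples: int = 500
    n_genes: int = 2000
    n_cohorts: int = 3
    n_tsgs: int = 5
    n_oncogenes: int = 3
    n_dt: int = 50
    n_planted: int = 10
    tsg_mut_freq: float = 0.20
    tsg_lof_fraction: float = 0.50
    oncogene_mut_freq: float = 0.15
    oncogene_lof_fraction: float = 0.05
    background_freq_range: tuple[float, float] = (0.005, 0.08)
    background_lof_fraction: float = 0.30
    nonfunctional_rate: float = 0.30  # extra silent/intronic records per functional one
    # expression
    delta: float = 1.0            # log2 upshift of the partner in TSG-mutant samples
    rho_latent: float = 0.4       # latent-factor correlation of planted pairs
    baseline_mean_range: tuple[float, float] = (2.0, 8.0)
    baseline_sd: float = 1.0
    cohort_shift_sd: float = 0.3  # per-cohort per-gene batch shift (log2 units)
    # survival
    hr_coinactive: float = 0.5
    weibull_shape: float = 1.2
    weibull_scale_days: float = 1500.0
    censor_scale_days: float = 3000.0
    admin_censor_days: float = 3650.0
    # drug panel
    n_lines: int = 200
    n_lymphoid_lines: int = 10
    beta: float = 0.8
    sigma: float = 0.2
    auc_intercept: float = 5.0
    n_decoy_drugs: int = 10
    panel_modules: int = 50       # co-expression modules among panel genes
    panel_module_corr: float = 0.8
    # dependency screen
    n_dependency_lines: int = 20
    dependency_shift: float = -0.5
    dependency_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_latent < 1:
            raise ValueError("rho_latent must lie in [0, 1)")
        if not 0 < self.hr_coinactive <= 1:
            raise ValueError("hr_coinactive must lie in (0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not 0 < self.tsg_mut_freq < 1:
            raise ValueError("mutation frequencies must lie in (0, 1)")
        if self.n_planted > self.n_tsgs * self.n_dt:
            raise ValueError("more planted pairs than the TSG x DT universe")


@dataclass
class GroundTruth:
    planted_pairs: list[tuple[str, str]]
    tsgs: list[str]
    oncogenes: list[str]
    dt_genes: list[str]
    planted_drugs: dict[str, str]              # target gene -> drug name
    planted_triples: list[tuple[str, str, str]]
    baseline_mean: pd.Series = field(repr=False, default=None)
    config: GeneratorConfig = None


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = [
        "mutations", "expression", "survival", "ontology", "drugs",
        "dependency", "modules",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _module_assignment(cfg: GeneratorConfig, genes: list[str]) -> np.ndarray:
    """Co-expression module per gene, shared by cohort and panel generators.

    Drawn from a dedicated seed stream so both generators agree without one
    having to run before the other.
    """
    rng = _streams(cfg.seed)["modules"]
    module = rng.integers(0, cfg.panel_modules, len(genes))
    # planted targets own distinct modules so their drug-response programs
    # do not overlap across TSGs
    tsgs, _, dts, _ = _gene_names(cfg)
    pos = {g: i for i, g in enumerate(genes)}
    for k in range(cfg.n_planted):
        module[pos[dts[k]]] = k % cfg.panel_modules
    return module


def _gene_names(cfg: GeneratorConfig) -> tuple[list, list, list, list]:
    tsgs = [f"TSG{i+1:02d}" for i in range(cfg.n_tsgs)]
    oncs = [f"ONC{i+1:02d}" for i in range(cfg.n_oncogenes)]
    dts = [f"DT{i+1:03d}" for i in range(cfg.n_dt)]
    n_bg = cfg.n_genes - cfg.n_tsgs - cfg.n_oncogenes - cfg.n_dt
    bgs = [f"BG{i+1:04d}" for i in range(n_bg)]
    return tsgs, oncs, dts, bgs


def _planted_pairs(cfg: GeneratorConfig, tsgs, dts) -> list[tuple[str, str]]:
    # deterministic round-robin: TSG i gets partners i, i+n_tsgs, ...
    pairs = []
    for k in range(cfg.n_planted):
        pairs.append((tsgs[k % cfg.n_tsgs], dts[k]))
    return pairs


def generate_cohort(cfg: GeneratorConfig) -> tuple[Cohort, GroundTruth, MutationTable]:
    """Generate (assembled cohort, ground truth, raw mutation table)."""
    rngs = _streams(cfg.seed)
    tsgs, oncs, dts, bgs = _gene_names(cfg)
    genes = tsgs + oncs + dts + bgs
    samples = [f"S{i+1:04d}" for i in range(cfg.n_samples)]
    cohorts = pd.Series(
        [f"C{1 + i % cfg.n_cohorts}" for i in range(cfg.n_samples)], index=samples
    )
    pairs = _planted_pairs(cfg, tsgs, dts)

    # --- mutations --------------------------------------------------------
    rng = rngs["mutations"]
    freq = pd.Series(index=genes, dtype=float)
    freq[tsgs] = cfg.tsg_mut_freq
    freq[oncs] = cfg.oncogene_mut_freq
    lo, hi = cfg.background_freq_range
    freq[dts] = rng.uniform(lo, hi, size=len(dts))
    freq[bgs] = rng.uniform(lo, hi, size=len(bgs))
    mut = rng.random((len(genes), cfg.n_samples)) < freq.to_numpy()[:, None]
    mut_df = pd.DataFrame(mut, index=genes, columns=samples)

    lof_frac = pd.Series(cfg.background_lof_fraction, index=genes)
    lof_frac[tsgs] = cfg.tsg_lof_fraction
    lof_frac[oncs] = cfg.oncogene_lof_fraction
    records = []
    gene_arr = np.array(genes)
    for j, s in enumerate(samples):
        mutated = gene_arr[mut[:, j]]
        is_lof = rng.random(len(mutated)) < lof_frac[mutated].to_numpy()
        for g, lofg in zip(mutated, is_lof):
            vc = rng.choice(LOF) if lofg else rng.choice(FUNCTIONAL_NON_LOF)
            records.append((s, g, vc))
        n_extra = rng.poisson(cfg.nonfunctional_rate * max(len(mutated), 1))
        for g in rng.choice(gene_arr, size=n_extra):
            records.append((s, g, rng.choice(NONFUNCTIONAL)))
    raw = MutationTable(
        records=pd.DataFrame(records, columns=["sample", "gene", "variant_class"])
    )

    # --- expression -------------------------------------------------------
    rng = rngs["expression"]
    mu = pd.Series(
        rng.uniform(*cfg.baseline_mean_range, size=len(genes)), index=genes
    )
    z = rng.standard_normal((len(genes), cfg.n_samples))
    gi = {g: i for i, g in enumerate(genes)}
    r = cfg.rho_latent
    latents = {t: rng.standard_normal(cfg.n_samples) for t in tsgs}
    for t in tsgs:
        z[gi[t]] = np.sqrt(r) * latents[t] + np.sqrt(1 - r) * z[gi[t]]
    module = _module_assignment(cfg, genes)
    bg_set = set(bgs)
    for t, d in pairs:
        z[gi[d]] = np.sqrt(r) * latents[t] + np.sqrt(1 - r) * z[gi[d]]
        mut_t = mut_df.loc[t].to_numpy()
        z[gi[d]] += cfg.delta / cfg.baseline_sd * mut_t
        # compensatory upregulation is a program-level shift: the target's
        # co-expression module (background members only) moves with it
        for g_ in np.array(genes)[module == module[gi[d]]]:
            if g_ in bg_set:
                z[gi[g_]] += cfg.delta / cfg.baseline_sd * mut_t
    logx = mu.to_numpy()[:, None] + cfg.baseline_sd * z
    # per-cohort batch shifts (removed downstream by median-centering)
    for c in cohorts.unique():
        cols = np.flatnonzero((cohorts == c).to_numpy())
        logx[:, cols] += rng.normal(0, cfg.cohort_shift_sd, size=len(genes))[:, None]
    logx = np.clip(logx, 0, None)
    tpm = np.exp2(logx) - 1.0
    tpm = tpm / tpm.sum(axis=0, keepdims=True) * TPM_TOTAL
    expr = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=genes, columns=samples),
        unit="tpm",
        cohort=cohorts,
    )

    # --- survival ---------------------------------------------------------
    rng = rngs["survival"]
    inactive = inactivation_status(centered_log_expression(expr))
    log_m = np.zeros(cfg.n_samples)
    for t, d in pairs:
        co = (inactive.loc[t].to_numpy() == 1) & (inactive.loc[d].to_numpy() == 1)
        log_m += np.log(cfg.hr_coinactive) * co
    m = np.exp(log_m)
    e = rng.exponential(1.0, cfg.n_samples)
    t_event = cfg.weibull_scale_days * (e / m) ** (1.0 / cfg.weibull_shape)
    censor = np.minimum(
        rng.exponential(cfg.censor_scale_days, cfg.n_samples), cfg.admin_censor_days
    )
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    surv = SurvivalTable(
        records=pd.DataFrame(
            {"sample": samples, "time": np.maximum(time, 1.0), "event": event}
        )
    )

    prep = prepare_mutations(raw)
    cohort = Cohort(
        expression=expr,
        mutation_matrix=prep.matrix.reindex(columns=pd.Index(samples), fill_value=0),
        gene_summary=prep.summaries,
        survival=surv,
    )
    gt = GroundTruth(
        planted_pairs=pairs,
        tsgs=tsgs,
        oncogenes=oncs,
        dt_genes=dts,
        planted_drugs={},
        planted_triples=[],
        baseline_mean=mu,
        config=cfg,
    )
    return cohort, gt, raw


def generate_ontology(cfg: GeneratorConfig, gt: GroundTruth) -> OntologyGraph:
    """Toy two-aspect ontology.

    Per aspect: one root; one branch per TSG holding the TSG's leaf and one
    sibling leaf per planted partner (Wang similarity of siblings ~0.59 with
    is_a edges, so FS > 0.5); every other annotated gene sits alone on its
    own branch (only the root is shared; FS ~0.24). The CC aspect uses
    part_of for branch->root edges for weight variety.
    """
    g = nx.DiGraph()
    aspect: dict[str, str] = {}
    annotations: dict[str, dict[str, frozenset]] = {"MF": {}, "CC": {}}
    partners: dict[str, list[str]] = {t: [] for t in gt.tsgs}
    for t, d in gt.planted_pairs:
        partners[t].append(d)
    singles = [g_ for g_ in gt.dt_genes if all(g_ != d for _, d in gt.planted_pairs)]
    for asp, tag, branch_rel in (("MF", "MF", "is_a"), ("CC", "CC", "part_of")):
        root = f"GO:{tag}0000000"
        g.add_node(root)
        aspect[root] = asp
        counter = 1

        def new_term(parent, rel):
            nonlocal counter
            term = f"GO:{tag}{counter:07d}"
            counter += 1
            g.add_node(term)
            aspect[term] = asp
            g.add_edge(term, parent, relation=rel)
            return term

        for t in gt.tsgs:
            branch = new_term(root, branch_rel)
            leaf_t = new_term(branch, "is_a")
            annotations[asp][t] = frozenset({leaf_t})
            for d in partners[t]:
                leaf_d = new_term(branch, "is_a")
                annotations[asp][d] = frozenset({leaf_d})
        for g_ in singles:
            branch = new_term(root, branch_rel)
            leaf = new_term(branch, "is_a")
            annotations[asp][g_] = frozenset({leaf})
    return OntologyGraph(graph=g, aspect=aspect, annotations=annotations)


def generate_drug_panel(cfg: GeneratorConfig, gt: GroundTruth) -> DrugPanel:
    """Cell-line panel with planted target-mediated drug sensitivity.

    Panel expression carries co-expression modules (each gene loads on one
    of ``panel_modules`` latent factors with correlation
    ``panel_module_corr``), emulating the pathway-level structure of real
    cell-line transcriptomes that expression-based response models rely on.
    """
    rngs = _streams(cfg.seed)
    rng = rngs["drugs"]
    genes = list(gt.baseline_mean.index)
    lines = [f"L{i+1:03d}" for i in range(cfg.n_lines)]
    c = cfg.panel_module_corr
    module = _module_assignment(cfg, genes)
    factors = rng.standard_normal((cfg.panel_modules, cfg.n_lines))
    z = np.sqrt(c) * factors[module] + np.sqrt(1 - c) * rng.standard_normal(
        (len(genes), cfg.n_lines)
    )
    expr = pd.DataFrame(
        gt.baseline_mean.to_numpy()[:, None] + cfg.baseline_sd * z,
        index=genes,
        columns=lines,
    ).clip(lower=0)
    tissue = pd.Series("liver", index=lines)
    tissue.iloc[: cfg.n_lymphoid_lines] = "haematopoietic_and_lymphoid_tissue"

    drugs: dict[str, np.ndarray] = {}
    ann_rows = []
    planted_drugs: dict[str, str] = {}
    planted_targets = [d for _, d in gt.planted_pairs]
    for dt in planted_targets:
        name = f"{dt}-inh"
        x = expr.loc[dt].to_numpy()
        xz = (x - x.mean()) / x.std(ddof=0)
        drugs[name] = cfg.auc_intercept - cfg.beta * xz + rng.normal(0, cfg.sigma, cfg.n_lines)
        ann_rows.append((name, dt, "inhibitor"))
        planted_drugs[dt] = name
        # agonist decoy against the same target: must be excluded by MOA
        ag = f"{dt}-ago"
        drugs[ag] = cfg.auc_intercept + rng.normal(0, cfg.sigma, cfg.n_lines)
        ann_rows.append((ag, dt, "agonist"))
    decoy_targets = [d for d in gt.dt_genes if d not in planted_targets]
    for i in range(cfg.n_decoy_drugs):
        dt = decoy_targets[i % len(decoy_targets)]
        name = f"decoy{i+1:02d}-inh"
        drugs[name] = cfg.auc_intercept + rng.normal(0, cfg.sigma, cfg.n_lines)
        ann_rows.append((name, dt, "inhibitor"))
    auc = pd.DataFrame(drugs, index=lines).clip(lower=0)
    annotations = pd.DataFrame(ann_rows, columns=["drug", "target", "moa"])
    panel = DrugPanel(expression=expr, auc=auc, annotations=annotations, tissue=tissue)
    gt.planted_drugs = planted_drugs
    gt.planted_triples = [(t, d, planted_drugs[d]) for t, d in gt.planted_pairs]
    return panel


def generate_dependency(cfg: GeneratorConfig, gt: GroundTruth) -> pd.DataFrame:
    """Gene x cell-line dependency scores; planted targets shifted down."""
    rng = _streams(cfg.seed)["dependency"]
    genes = list(gt.baseline_mean.index)
    lines = [f"D{i+1:03d}" for i in range(cfg.n_dependency_lines)]
    scores = rng.normal(0.0, cfg.dependency_sd, (len(genes), len(lines)))
    dep = pd.DataFrame(scores, index=genes, columns=lines)
    dep.loc[gt.dt_genes] += cfg.dependency_shift
    return dep


def hallmark_like_sets(gt: GroundTruth, rng_seed: int = 0) -> dict[str, set[str]]:
    """Small named gene sets: one enriched in the planted targets, decoy sets."""
    rng = np.random.default_rng(rng_seed)
    universe = list(gt.baseline_mean.index)
    sets = {"SET_PLANTED_TARGETS": set(d for _, d in gt.planted_pairs)}
    for i in range(5):
        sets[f"SET_RANDOM_{i+1}"] = set(rng.choice(universe, size=40, replace=False))
    return sets


@dataclass
class SyntheticBundle:
    cohort: Cohort
    raw_mutations: MutationTable
    ground_truth: GroundTruth
    ontology: OntologyGraph
    panel: DrugPanel
    dependency: pd.DataFrame
    gene_sets: dict[str, set[str]]


def generate_all(cfg: GeneratorConfig) -> SyntheticBundle:
    cohort, gt, raw = generate_cohort(cfg)
    onto = generate_ontology(cfg, gt)
    panel = generate_drug_panel(cfg, gt)
    dep = generate_dependency(cfg, gt)
    sets = hallmark_like_sets(gt, rng_seed=cfg.seed)
    return SyntheticBundle(cohort, raw, gt, onto, panel, dep, sets)


def write_all(bundle: SyntheticBundle, outdir) -> None:
    """Serialise every input in the plain-text formats the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.cohort.expression, out / "expression.tsv")
    bundle.raw_mutations.records.to_csv(out / "mutations.tsv", sep="\t", index=False)
    bundle.cohort.survival.records.to_csv(
        out / "survival.tsv", sep="\t", index=False, float_format="%.6f"
    )
    cohorts = bundle.cohort.expression.cohort
    cohorts.rename("cohort").to_frame().rename_axis("sample").to_csv(
        out / "cohorts.tsv", sep="\t"
    )
    write_obo(bundle.ontology, out / "ontology.obo")
    write_gaf(bundle.ontology, out / "annotations.gaf")
    bundle.panel.expression.to_csv(out / "panel_expression.csv", float_format="%.6f")
    bundle.panel.auc.to_csv(out / "panel_auc.csv", float_format="%.6f")
    bundle.panel.annotations.to_csv(out / "drug_targets.csv", index=False)
    bundle.panel.tissue.rename("tissue").to_frame().rename_axis("line").to_csv(
        out / "panel_tissue.csv"
    )
    bundle.dependency.to_csv(out / "dependency.csv", float_format="%.6f")
    write_gene_sets(bundle.gene_sets, out / "gene_sets.gmt")
    gt = bundle.ground_truth
    truth = {
        "planted_pairs": [list(p) for p in gt.planted_pairs],
        "tsgs": gt.tsgs,
        "oncogenes": gt.oncogenes,
        "dt_genes": gt.dt_genes,
        "planted_drugs": gt.planted_drugs,
        "planted_triples": [list(t) for t in gt.planted_triples],
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(gt.config).items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
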