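# Methods

## Data model and preprocessing

Expression is carried as TPM (per-sample columns summing to 10⁶). Raw
counts are converted via per-gene rates (count / length in kb) and column
renormalisation; FPKM needs only the renormalisation; an explicit
`allow_cpm_fallback` flag permits length-free scaling of counts, logged as
a deviation. All statistics operate on log2(TPM+1) after per-cohort,
per-gene median-centering. The centering is deliberately mild: every test
downstream of it is rank-based or stratified by cohort, so only monotone
within-cohort structure matters; the centering merely makes pooled
quantities (medians for inactivation calls, fold changes) comparable across
cohorts with different library chemistry.

Mutation records use a closed vocabulary (missense, nonsense, frameshift,
splice, inframe_indel, silent, intronic, intergenic, other); a shipped
mapping table normalises common MAF `Variant_Classification` spellings, and
unknown strings map to `other` with a warning. Filtering follows the
standard meta-cohort recipe: silent/intronic/intergenic records removed;
duplicate records per (sample, gene) merged — keeping a truncating class if
any record was truncating, so loss-of-function (LOF) counting is not
diluted by the merge; samples with fewer than 10 functional records
dropped; genes mutated in under 2.5% of retained samples dropped (the
frequency denominator is re-based after the sample drop). LOF means
frameshift or nonsense; splice and missense count as functional but
non-LOF. A driver gene is called a tumor suppressor when strictly more than
20% of its functional records are LOF; manual curation of the resulting
list is supported through allow/deny options because it cannot be
reproduced computationally.

## Screens

**Functional similarity (gate 1).** Wang's graph-based measure: for a term
t, every ancestor a receives S_t(a), the maximum over directed paths t→a of
the product of edge weights (`is_a` 0.8, `part_of` 0.6, configurable),
computed by dynamic programming in topological order and verified in the
tests against exhaustive path enumeration. Term similarity is the summed
S-mass on shared ancestors over the total S-mass; gene similarity combines
terms by best-match averaging; FS = √(Sim_MF · Sim_CC) with a 0.5 pass
threshold. The MF and CC aspects are used (function and location); BP is
parsed but not scored. A gene lacking MF or CC annotation yields FS = NaN
and the pair fails the gate, counted in the audit. The graph measure was
chosen over information-content measures (Resnik/Lin) because it needs no
annotation corpus; the IC route would require a reference GOA corpus that a
desk-scale analysis does not have.

**Differential expression (gate 2).** One-sided Wilcoxon rank-sum (greater
in mutants) per candidate target, BH-adjusted within each TSG; gate =
adjusted p < 0.05 and positive log2 fold change (difference of group means
of centred log2 expression). Groups with fewer than 2 samples fail with
reason "underpowered". The adjusted (not raw) threshold is used because
every p-value family in the pipeline is BH-corrected.

**Co-expression (gate 3).** Spearman ρ with two-sided p, BH across all
evaluated pairs; gate = ρ > 0.15 and adjusted p < 0.05. For n ≤ 9 the
p-value is the exact pairing-permutation probability; above that, the
t-approximation. Zero-variance genes are excluded with a logged reason.

**Co-inactivation survival (gate 4).** A gene is inactive in a sample when
its centred log2 expression is strictly below the gene's median across all
samples; ties at the median are active, so a constant gene is never
inactive. Group 1 = both genes inactive, group 0 = everyone else. The
two-sample log-rank test is summed over cohort strata (per-stratum
observed−expected and hypergeometric variance; identical to the Mantel-Cox
test within one stratum, verified against lifelines), because pooling
cohorts with different baseline survival would confound the comparison. The
hazard ratio comes from a cohort-stratified Cox model on the co-inactivation
indicator. Gate = p < 0.05 and HR < 1; the explicit HR < 1 conjunction
makes the direction of benefit part of the contract rather than an
inspection step. A configurable floor (30 samples with follow-up) guards
degenerate fits, and unfittable models fail the gate with a reason instead
of erroring.

Gate logic is pure conjunction, so loosening any threshold can only grow
the candidate set (property-tested). The audit table records every pair,
every statistic, every gate flag and a failure reason.

## Rank aggregation

Within the candidate set, each criterion (FS, log2 fold change, ρ
descending; HR ascending — the strongest protective effect ranks first)
yields midrank-based rank ratios r = rank/n ∈ (0,1]. Stuart's
order-statistics probability q(r) = P(U₍ₖ₎ ≤ r₍ₖ₎ ∀k) is computed by the
exact alternating factorial recursion v_k = Σᵢ (−1)^(i−1) v_{k−i} x^i / i!
over the ascending-sorted ratios, validated against the Monte-Carlo
definition (10⁶ draws, agreement within 3 SE on random vectors). RAS =
−log₁₀(q); since any strictly decreasing transform of q preserves the
ordering, the ordering — not the RAS value — is the contract. Final
ordering is deterministic: RAS descending, then q ascending, then pair
identifier. A diagnostic aggregation over the full evaluated universe
(audit_ras) fills unfittable hazard ratios with the neutral value 1 so that
planted-versus-decoy separation can be inspected on all pairs, not only
survivors.

## Mutual exclusivity (diagnostic)

Mutually exclusive mutation is a classic SL signal but is underpowered on
sparse mutation profiles, so it is shipped as a stand-alone diagnostic, not
a gate. Two tests: a one-sided Fisher exact test for co-occurrence
depletion (fast; assumes homogeneous per-sample rates) and a
degree-preserving permutation test (repeated 2×2 checkerboard swaps keep
every row and column sum exactly; empirical p with add-one correction;
seeded). Neither reproduces the Poisson-binomial background model of the
DISCOVER method; the permutation test is the rate-robust analogue.

## Drug extension

Per drug, ridge regression of AUC (lower = more sensitive) on standardized
log2 expression of the top 5,000 most-variable panel genes; hematopoietic/
lymphoid lines excluded; at least 30 lines with a measured AUC required;
penalty chosen by 10-fold cross-validated MSE over a fixed grid
(10⁻²…10³). The model is scale-equivariant in AUC: rescaling all AUC by a
positive constant rescales coefficients and predictions identically and
leaves CV penalty choice, R² and all gate decisions unchanged
(property-tested). Clinical genes are standardized with the training
means/scales, so a clinical sample identical to a training line reproduces
that line's fitted value exactly; per-domain z-scoring is available behind
`domain_zscore` for settings with platform shifts. Training genes missing
from the clinical matrix are imputed at the training mean, with a warning
above 30% missing. Drugs whose CV R² is near zero are flagged: their
imputed values are noise functionals of expression and must not be
interpreted even when a downstream test is formally significant.

A drug links to a TSG when its imputed AUC is significantly lower in
TSG-mutant samples (one-sided Wilcoxon, BH across drugs per TSG) with a
negative median difference. Agonist mechanism-of-action edges are excluded
(an agonist cannot phenocopy target loss), drug names de-duplicate
case-insensitively, and datasets are analysed separately without
cross-dataset de-duplication. The drug layer annotates the candidate pair
list; it never filters it.

## Characterization

Hypergeometric upper-tail enrichment against named gene sets, universe =
all genes in the expression matrix (the conventional default when no
custom background is supplied), BH-adjusted. Tumor-vs-normal comparison:
two-sided rank-sum per gene, flag = adjusted p < 0.01 and |log2FC| > 1,
both strict. Per-gene survival: univariable cohort-stratified Cox on
z-scored log2 expression (HR per 1 SD; continuous, not dichotomised).
Dependency comparison: per-gene median scores of the target set versus a
size-matched uniformly drawn random set, one-sided rank-sum (lower = more
essential), averaged over 1,000 seeded resamples with the median p reported
— a single draw is available for strict fidelity, but resampling removes
the draw-to-draw volatility of the diagnostic.

## Synthetic benchmark

The generator emulates the study conditions end to end with planted ground
truth; one master seed fans out to per-component streams (mutations,
expression, survival, ontology, drugs, dependency, modules) via
`SeedSequence.spawn`, so components can be regenerated independently and
identical seeds give bit-identical data.

Defaults (a desk-scale study, chosen so the full pipeline runs in minutes
on one CPU): 500 samples in 3 cohorts, 2,000 genes, 5 TSGs (mutation
frequency 0.20, LOF fraction 0.5 — comfortably past the 20% rule),
3 oncogene decoys (LOF fraction 0.05), 50 druggable targets, 10 planted
pairs. Planted effects: δ = 1 log2 unit of target upregulation in
TSG-mutant samples; a shared latent factor per TSG giving planted-pair
Spearman ≈ 0.4; survival from a Weibull(shape 1.2, scale 1500 days)
baseline with the hazard multiplied by 0.5 per co-inactive planted pair,
exponential censoring (scale 3000 days) truncated at 10 years. All three
cohorts carry follow-up. Per-cohort batch shifts (SD 0.3 log2 units) are
added and must be absorbed by the median-centering. Because a TSG's two
planted partners share its latent factor, samples co-inactive for one pair
are often co-inactive for another; marginal per-pair hazard ratios
therefore compound below 0.5, and the single-pair configuration is used
when the per-pair effect size itself is under test.

The toy ontology gives each TSG one branch holding its leaf and one sibling
leaf per planted partner (Wang sibling similarity ≈ 0.59 under is_a
edges, so FS > 0.5 by construction) and every other gene its own branch
(only the root shared, FS ≈ 0.24). The CC aspect uses part_of edges
branch-to-root for weight variety.

The drug panel has 200 lines (10 hematopoietic/lymphoid decoys) and
module-structured expression: each gene loads on one of 50 latent modules
with within-module correlation 0.8, matching the pathway-level structure of
real cell-line transcriptomes. This structure is what makes expression-
based response imputation work at all: with mutually independent genes and
a single informative one, ridge — which does not select features — cannot
exceed CV R² ≈ 0.04 at 200 lines regardless of penalty, whereas with
module structure the planted drugs reach CV R² ≈ 0.55–0.75. Planted drug
AUC = 5 − 0.8·z(target expression) + N(0, 0.2), decoy drugs are pure
noise, and each planted target also gets an agonist decoy that the
mechanism-of-action filter must remove. Consistently, the compensatory
upregulation in mutant tumors is modelled as a program-level shift: the
planted target's module (background members) moves by δ with it. Planted
targets occupy distinct modules so drug-response programs do not overlap
across TSGs. Dependency scores are N(0, 0.3) with the druggable-target set
shifted by −0.5.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: mutational signatures and panel-specific
coverage; copy-number-driven inactivation; non-proportional hazards and
informative censoring; global co-expression structure in the tumor cohort
(only planted pairs and planted programs correlate, so the decoy pass rate
of the co-expression gate is optimistic relative to real transcriptomes);
ontology annotation depth and multi-parent density of the real GO; and
cross-dataset heterogeneity of drug panels.

## Numerical choices

Rank-sum tests are exact (no ties, both groups ≤ 25) or midrank-normal
with continuity correction; Spearman p exact by pairing enumeration for
n ≤ 9; BH via statsmodels with NaN propagation; ties in ranking use
midranks everywhere; ordering tie-breaks are lexicographic and documented
per table. The log-rank variance term uses the hypergeometric formula with
the (n−d)/(n−1) multiplicity correction. Tables are written with
`%.10g` floats and sorted keys, so identical runs are byte-identical; the
run manifest records seed, config snapshot, stage counts and output
digests.

## Known limitations

The Stuart recursion is evaluated in double precision and is accurate for
the N ≤ 10 criteria regime it is used in; it is not implemented in log
space for large N. The permutation mutual-exclusivity test mixes by random
checkerboard swaps (5 × fill attempts per permutation by default) without a
formal mixing diagnostic. Ridge imputation transfers panel scale to
clinical samples by design; strong platform shifts require the
`domain_zscore` option. The survival gate assumes proportional hazards
within cohort strata.
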