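# Methods

## Design and scope

`txrescue` analyzes a three-group bulk RNA-seq design — control, disease,
disease+drug — and classifies each gene's disease response and drug
sensitivity. The pipeline order is fixed: read counts → restrict to
protein-coding genes → FPM normalization → PCA sample QC → consensus
differential expression → two-strategy rescue classification → optional GO
over-representation analysis. Everything upstream of the count matrix
(alignment, counting) and everything downstream of the reported tables
(visualization) is out of scope.

## Abundance and filtering

FPM is fragments per million counted fragments: a per-sample
counts-per-million with **no** gene-length correction. Library size is the
column sum of the matrix at the point of normalization, i.e. after the
protein-coding filter, so the abundance gate (rule 1 below) operates on the
analyzed gene universe. Genes without a biotype annotation are dropped by
default (`keep` and `error` policies available); whether low-abundance
filtering happens before or after the biotype restriction is configurable
because sources rarely state this order.

Sample QC works on log2(FPM+1): samples are projected onto the first two
principal components and flagged when their distance to their own group
centroid exceeds 3× (configurable) the median within-group centroid distance.
Groups with fewer than three members are never flagged — with n=2 both
samples sit symmetrically around their centroid and the rule is
uninformative. Flagged samples are dropped by default (mirroring the common
practice of excluding one PCA-outlying control), and FPM is recomputed on the
retained samples.

## Differential expression: consensus of two stand-in callers

The selection criterion is the **consensus**: a gene counts as differentially
expressed only when both callers give FDR < 0.05 (strict, Benjamini–Hochberg).
The callers are intentionally simple and fully documented rather than
re-implementations of DESeq2/edgeR internals (no trended dispersion, no
TMM/median-of-ratios size factors); the object of study is the selection
procedure, not the third-party packages.

**NB Wald caller.** Counts follow NB(μ = s_j·q_group, var = μ + α·μ²) with
per-sample total-count size factors s_j. Per-gene dispersion α is estimated
by method of moments on normalized counts within each group, clipped at zero,
pooled by degrees of freedom, and shrunk 50/50 toward the genome-wide median.
The Wald statistic log(q̂_b) − log(q̂_a) over its delta-method standard error
is referred to a t distribution with 2(n_a + n_b − 2) degrees of freedom.
The doubling reflects the information added by shrinkage: with the plain
residual df the test is visibly conservative at n = 4–5 per group (empirical
type-I ≈ 0.031–0.040 at nominal 0.05 in null NB simulations), while a normal
reference is anticonservative (≈ 0.061–0.071); the doubled-df reference sits
at ≈ 0.046–0.056. A continuity term (0.5 on a group's total) keeps the
statistic finite when one group is all zero; genes with zero counts in both
groups get p = 1 and a degenerate flag.

**Moderated-t caller.** Welch t on log2(CPM+1) with each group's gene-wise
variance shrunk equal-weight (50/50) toward that group's across-gene mean
variance. The Satterthwaite degrees of freedom are doubled for the same
prior-information reason (equal-weight shrinkage toward a prior estimated
from thousands of genes contributes about one residual's worth of df, as in
empirical-Bayes moderated t statistics). Zero shrunk variance with zero
difference gives p = 1 by convention.

Fold changes are raw group-mean FPM ratios with pseudocount 1:
log2FC = log2((mean_b + 1)/(mean_a + 1)), disease relative to control
(positive = up in disease). No shrunken fold-change estimator is used; this
is deliberately the simplest estimator consistent with the thresholding
rules and is noted here because shrunk and raw estimates can differ near the
|log2FC| = 1 gates.

## Rescue classification

**Strategy A** (DE-based "normalized" criterion): consensus DEG with
|log2FC| ≥ 1 in control vs disease, and NOT a consensus DEG with |log2FC| ≤ 1
in control vs disease+drug.

**Strategy B** (five sequential gates): (1) mean abundance > 3 FPM in at
least one group (strict); (2) |log2FC(control→disease)| > 1 (strict);
(3) control/disease 95% CIs disjoint; (4) disease/drug CIs disjoint;
(5) control/drug CIs overlapping.

The fold-change gates are deliberately asymmetric — Strategy B uses strict
`> 1`, Strategy A uses `≥ 1` — because each strategy's defining rule set
states it that way; the package preserves the discrepancy rather than
harmonizing it.

Confidence intervals are t-intervals on log2(FPM+1), back-transformed by
2^y − 1. The log scale stabilizes the variance of count-derived abundances;
a linear-scale mode is retained for sensitivity analysis. Touching interval
endpoints count as overlap — the conservative convention: it is harder to
establish the separation rules (3, 4) and easier to establish the restoration
rule (5). Widening the intervals (raising the level) can therefore only flip
rules 3/4 from pass to fail and rule 5 from fail to pass, which is tested as
a property.

The per-gene direction label (up/down/none) partitions the gene universe; the
study-level table uses the Strategy A regulated set for direction bookkeeping
(the summary's "regulated genes"), since that is the universe in which the
direction × sensitivity percentages are conventionally reported.

## Enrichment

The ontology is a child→parent DAG of `is_a` edges (`part_of` opt-in),
parsed from OBO; obsolete terms are dropped and cycles rejected. Annotations
are propagated up the DAG (true-path rule) before testing, so a term's gene
count k is always ≥ any descendant's. Over-representation per term is the
one-sided hypergeometric tail P(X ≥ k) with parameters (N, K, n). Adjustment
defaults to Bonferroni — closer in stringency to g:Profiler's proprietary
g:SCS than BH, which is also available — and significance is adjusted
p ≤ 1e-6 (a 1e-7 preset ships as well). "Enrichment score" means fold
enrichment (k/n)/(K/N). The background is configurable between the full
annotation universe ("whole genome") and the expressed genes. A "common
child term" is a significant term that is a proper descendant of at least
two significant terms; leaves of the significant subgraph are flagged as the
most specific shared themes.

## Assay models

**Mito-stress OCR.** "Initial OCR" is the mean over pre-injection cycles;
post-injection phases are summarized by their minimum (means selectable in
principle; the minimum matches the standard parameter definitions). NMOC =
min after rotenone/antimycin A; basal = initial − NMOC; proton leak =
min after oligomycin − NMOC; ATP-linked = initial − min after oligomycin;
coupling efficiency = ((basal+NMOC) − (leak+NMOC))/(basal+NMOC), which
algebraically equals (initial − min_oligomycin)/initial. One published
formula set prints the ATP-linked definition identically to basal — an
evident transcription slip; the standard definition is the default and an
`as_printed=True` audit mode reproduces the printed version. The
leak fraction is reported as proton_leak / basal with basal NMOC-subtracted
(the alternative, leak/(basal+NMOC), equals 1 − coupling efficiency and is
recoverable from the other outputs).

**Lactate/glucose stoichiometry.** Glycolysis yields at most 2 lactate per
glucose, so for ratio r = L/G the fraction of lactate that cannot derive from
consumed glucose is max(0, 1 − 2/r): zero on r ≤ 2, ≈ 0.10 at r ≈ 2.22,
≈ 0.43 at r = 3.5.

**ddCq.** ΔCq = Cq_target − mean(Cq_ref1, Cq_ref2) (arithmetic mean of Cq,
equivalent to the geometric mean of linear quantities); ΔΔCq subtracts the
control-group mean ΔCq; percent of control = 100·2^(−ΔΔCq). Shift-invariant
in the target Cq by construction.

**Outliers.** Modified Z-score (Iglewicz–Hoaglin) M = 0.6745(x − median)/MAD
with default cutoff |M| ≥ 3.5; MAD = 0 yields no flags with a warning.
Grubbs: iterative two-sided test at P < 0.05 using the t-based critical
value, removing one extreme per iteration.

## Synthetic data

The generator draws the design it is meant to exercise: groups of 4/5/5
(five per arm with one control excluded is the emulated scenario), log-normal
baseline abundances (median ≈ 100 on the relative-abundance scale,
σ_log = 1.5, giving a realistically long-tailed expression distribution with
only a few percent of genes under the 3 FPM gate), NB counts with
variance = μ + α·μ² (α = 0.05 constant by default, optional log-normal
per-gene spread), and library sizes log-normal around 2×10⁷ fragments
(σ_log = 0.15) so FPM scaling is genuinely exercised. Gene classes —
null (70%), up/down persistent (10% each), up/down rescued (5% each) — plant
multiplicative group effects of ±`effect_log2fc` (default 1.5; the headline
recovery check uses 2.0) on the disease mean; `rescue_completeness`
interpolates the drug-group mean between disease (0) and control (1) on the
log2 scale.

One property of the generator worth knowing: because planted up- and
down-regulated genes change the disease columns' library totals, FPM fold
changes are compositionally compressed by ≈ 0.4 log2 units at the default
class mix. This mimics real compositional bias in CPM-type normalization.
Tests that verify the *planted* effect therefore normalize by null-gene
totals; the classifier operates on ordinary FPM, and its |log2FC| > 1 gates
tolerate the compression at the simulated effect sizes.

What the generator does **not** emulate: gene–gene correlation, GC/length
biases, trended mean–dispersion relationships, outlier counts of the kind
DESeq2's Cook's-distance filtering targets, and batch structure. Passing
recovery tests therefore demonstrate correctness of the selection logic
under the stated model, not performance on arbitrary real data.

## Numerical and degenerate-input conventions

- Zero-variance groups give point CIs; identical groups always overlap.
- All-zero genes: p = 1 with a degenerate flag in both callers.
- All-zero sample columns are rejected by FPM normalization (named error).
- BH adjustment is the plain step-up, capped at 1 (via statsmodels,
  cross-checked in tests against an independent implementation).
- PCA uses the full SVD solver for determinism; a tiny absolute floor on the
  flagging threshold prevents numerically identical samples from being
  flagged when the median distance is zero.
- Apportionment of genes to classes uses largest remainders, so class counts
  match proportions up to ±1 gene.

## Problem sizes used by the test suite and acceptance script

Simulation-based checks run at 2,000 null genes (caller calibration,
permutation consensus rate), 5,000 genes for planted-rescue recovery, 10,000
replicates for CI coverage, and 100 plates for noisy OCR recovery. These
sizes give stable empirical rates (binomial standard error ≤ ~0.005 on the
calibration quantities) while the whole suite runs in a few seconds.

## Known limitations

- The callers are calibrated stand-ins; agreement with DESeq2/edgeR gene
  lists on real data is approximate by design.
- Strategy B's CIs assume approximate normality of log2(FPM+1) within group;
  at very low counts (FPM ≪ 1) coverage degrades.
- The enrichment module tests each term marginally; no conditional or
  topology-weighted testing (parent–child, elim/weight algorithms).
- The pipeline handles exactly one three-group factor; no covariates, paired
  designs or batch terms.
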