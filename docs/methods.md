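# Methods

This note documents the statistical models, the defaults and the design
choices behind the package, and what the synthetic-data experiments do and
do not establish.

## Bulk arm

### Model and normalization

Bulk counts are treated as negative binomial over a paired design: four
donor pairs, each contributing one scrambled-control (Scr) and one
triple-knockdown (TKD) library at each timepoint. TMM normalization
computes, for every sample against a reference, gene-wise log ratios
M = log2 of depth-normalized count ratios and abundances
A = ½·log2 of their product, over genes positive in both samples. The
extreme `trim_m = 0.30` fraction of genes by M-rank and `trim_a = 0.05` by
A-rank are discarded (average ranks on ties) and the factor is the
precision-weighted mean of the surviving M values, with weights equal to
the inverse asymptotic variance of M under binomial sampling,
w_g = [(N_j−y_gj)/(N_j y_gj) + (N_r−y_gr)/(N_r y_gr)]⁻¹. Factors are
rescaled to geometric mean 1. The reference sample defaults to the one
whose 75th-percentile depth-normalized count is closest to the mean of
those percentiles. Genes with zero counts in every sample are dropped
before normalization and the count is logged in the run summary.

CPM uses TMM-effective library sizes N_j·f_j; paired log2 differences use a
pseudocount of 0.5 (configurable) to avoid −∞ without materially biasing
well-covered genes.

### Paired reproducibility-optimized test

Per gene, the paired differences Δ_gi = log2 CPM(TKD, pair i) −
log2 CPM(Scr, pair i) are summarized by the mean m̄_g and standard error
s_g. The test statistic family is d_g = |m̄_g| / (α₁ + α₂·s_g), spanning
pure fold change (α₂ = 0) through a regularized t-like statistic. The
member and the top-list size k are chosen to maximize

Z_k = (R_k − R⁰_k) / sd(R_k),

where R_k is the mean over B = 500 bootstrap iterations of the top-k
overlap proportion between two independent pair-level bootstrap resamples,
and R⁰_k is the same quantity on sign-flip-randomized differences. Grid
defaults: α₁ ∈ {0, 0.01, …, 0.5}, α₂ ∈ {0, 1} (all α₂ = 0 members rank
genes identically and are collapsed to one representative), k on a
geometric ladder from 10 to half the gene count. Ties in top-k lists break
by statistic and then stable gene order.

FDR is estimated by sign-flip permutations of the paired differences:
q_g = mean over permutations of #{permuted d ≥ d_g} / #{observed d ≥ d_g},
monotonized to be non-increasing in d and clipped to [0, 1]. Two sign
patterns — the identity and the global negation — reproduce the observed
|m̄| and s exactly and therefore carry no null information; they are
excluded. Because the statistic is invariant under global negation, the
2^(n−1) − 1 distinct informative patterns are enumerated exhaustively
whenever they fit within `n_perm` (always true at n = 4 pairs, where there
are 7); otherwise `n_perm` patterns are sampled. With few pairs the
permutation granularity is coarse, which makes small FDRs conservative
rather than anti-conservative.

Selection applies strict inequalities — FDR below the threshold and linear
fold change 2^|m̄_g| above it ("below 0.1", "above 1.4"); the relaxed
exploratory tier uses FDR < 0.25. The fold-change filter is evaluated on
2^|mean paired log2 difference|; a ratio-of-normalized-means variant was
considered and rejected as the default because the paired statistic is
defined on the same differences (the mean-ratio option remains available
by computing FC from CPM directly).

## Single-cell arm

QC removes cells with mitochondrial fraction strictly above 0.10 or with
fewer than 200 detected (nonzero) genes; zero-total cells are removed and
counted separately since their mitochondrial fraction is undefined. The
gene universe is never filtered here. Mitochondrial genes are identified
by the `MT-` name prefix unless an explicit list is supplied.

Normalization is ln(1 + count/total · 10⁴) per cell. PIM⁻ classification
operates on raw post-QC counts: a cell is PIM⁻ iff all three knockdown
targets have count exactly 0. Joint marker states treat the PIM group as
positive when any target is detected, and each additional marker (defaults
TBX21, RORA) as positive when its own count is nonzero.

### Downsampling-balanced DE

The comparison of interest is a small case group (PIM⁻ cells of the TKD
sample) against a larger control group (all Scr cells). To remove the
group-size imbalance, the larger group is downsampled without replacement
to the smaller group's size, `n_subsets = 100` times; if the case group is
the larger one the same logic applies symmetrically. Each subset uses an
independent RNG substream spawned from the master seed, so results are
identical regardless of evaluation order and a shorter run is a prefix of
a longer one.

Within a subset, genes detected in at least 10 % of cells of either group
are tested (the filter is configurable, including off); the test is the
two-sided Wilcoxon rank-sum, exact when both groups have ≤ 25 tie-free
observations and otherwise the normal approximation with tie and
continuity corrections; BH adjustment is applied across the subset's
tested genes. The subset log2FC back-transforms the log-normalized values:
log2[(mean expm1(x_case) + 1) / (mean expm1(x_ctrl) + 1)], the common
single-cell convention with pseudocount 1. A gene "qualifies" in a subset
when FDR < 0.05 and |log2FC| > 0.24; `signif_prop` is the number of
qualifying subsets divided by `n_subsets`. The log2FC criterion is
two-sided by default because both up- and down-regulated genes are
reported from this analysis; a signed mode is available. Genes never
tested in any subset are flagged and given signif_prop 0. Calling DE genes
from the aggregated table requires signif_prop ≥ a user threshold (no
canonical value exists; the analysis drivers use 0.9), with direction from
the sign of the mean log2FC.

## Integration and assay quantification

Overlaps of signed gene sets report the intersection plus its concordant
(matching direction) and discordant partitions, since a direction
requirement may or may not be intended by a given comparison. ddCt assumes
amplification efficiency 2; technical replicates are averaged on the Ct
scale before ΔCt. Readout normalization divides by live-cell count and
anchors the control at exactly 1.

## Synthetic-data generator

The generator reproduces the statistical structure the pipeline assumes,
not the biology of any particular deposit.

**Bulk**: gene baselines are log-normal (σ = 1.2 in natural log) relative
abundances; donor-pair effects are multiplicative log-normal (σ = 0.15)
per gene × pair, shared between the two conditions of a pair so they
cancel in paired differences — the paired design's raison d'être; the
condition effect is 2^lfc in TKD for planted DE genes (default 10 % of
genes at |log2FC| = 1.5, random sign); counts are gamma-Poisson
(negative binomial, default dispersion φ = 0.1) at library sizes uniform
in 0.8–1.2 M. An optional composition-bias map multiplies chosen genes'
means in one sample to exercise TMM. Named marker-gene effects can be
planted so the bulk and single-cell arms share DE genes.

**Single cell**: two samples (Scr, TKD) with silenced-cell fractions 0.26
and 0.53 — the knockdown-efficiency values observed in the study system,
used as simulation truth. Silenced cells carry hard zeros on the three
PIM targets (matching the PIM⁻ operational definition; a reduced-mean mode
exists) and have the planted effect genes shifted by their log2FC; effects
are confined to silenced cells in either sample. Per-cell depth is
log-normal (σ = 0.3) around 5,000; counts are NB with φ = 0.3; an optional
logistic detection model (probability σ(slope·(log mean − midpoint)),
default midpoint −2.5, slope 1.5) thins low-expression genes to mimic
dropout. PIM targets (and planted effect genes) are pinned at a
moderate, reliably detectable baseline — 8× and 4× the median gene,
respectively — because the classifier's zero-count rule and any real DE
call both presuppose expressed genes; without this the triple-zero rate in
non-silenced cells would reflect baseline sparsity rather than knockdown.
Mitochondrial genes are a configurable fraction (default 5 %) of the
universe named with the `MT-` prefix.

A single master seed drives `numpy.random.SeedSequence` substreams per
component (baselines, truth assignment, each sample, each subset), so all
outputs are byte-reproducible and component order is immaterial.

**What the generator does not emulate**: ambient RNA, doublets, UMI
collisions, batch effects, gene-gene correlation, and cell-state
heterogeneity beyond the silenced/non-silenced dichotomy. Passing
recovery tests on this generator therefore shows the procedures are
correctly implemented and calibrated under their own assumptions; it does
not certify performance on real droplet data, where empirical dropout and
correlation structure are heavier.

## Problem sizes and numerical choices

The validation experiments use 1,000–2,000 genes, 4 donor pairs, and
300–3,000 cells per group — large enough for stable rate estimates while
keeping a full run in minutes on one CPU. Degenerate inputs are defined
explicitly: a gene with zero paired differences gets d = 0 and FDR 1; a
bootstrap resample with zero SE falls back to the fold-change ordering
(ties broken by stable gene order); fully tied Wilcoxon rows get p = 1;
zero-variance genes make z-scoring fail loudly with the offending gene
names. Strict-versus-inclusive threshold conventions follow the stated
selection rules everywhere ("below", "above", "less than 200").

## Known limitations

- With 4 pairs the sign-flip FDR has resolution 1/7 per gene rank stratum;
  FDR estimates below ~0.01 are indistinguishable from 0.
- The reproducibility optimization is itself stochastic; with the default
  B = 500 the selected (α₁, α₂, k) can vary between seeds, though the
  resulting gene ranking is stable in practice.
- `signif_prop` aggregates dependent subsets (all share the fixed case
  group), so it is a stability measure, not a probability with frequentist
  guarantees.
- The ddCt implementation fixes amplification efficiency at 2; no
  efficiency-corrected mode is provided.
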