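# Methods

This note documents the statistical models, the synthetic data generator,
the numerical choices and the known limitations of `dielgate`.

## Data model and preprocessing

The unit of analysis is a gene × sample matrix of raw read counts over a
4-group design: time ∈ {AM, PM} × condition ∈ {control, heat}, with a
replicate id per sample. Counts must be non-negative integers; genes and
samples must be uniquely named; every sample carries exactly one time and
one condition label.

**Count filter.** A gene is kept if its *maximum* count across samples is
at least `min_count` (default 10). The rule is deliberately per-sample
rather than row-sum: a transcript expressed only after heat shock at one
time of day ([0,0,…,10]) is exactly the kind of gene this analysis is
about. The filter is applied before testing and before multiple-testing
correction, so the BH denominator counts only testable genes. It is
idempotent.

**Normalization.** Median-of-ratios size factors: for each gene with
nonzero counts in every sample, the ratio of each sample's count to the
gene's geometric mean is formed; the sample's factor is the median of
these ratios. The median is taken in ratio space (not log space), matching
the definition literally; the two differ only when the number of
reference genes is even, at the ~1e-5 level. Factors enter the GLM as
offsets. Two consequences worth knowing:

* factors are invariant to a global rescaling of the whole matrix — only
  *relative* depth differences between samples matter;
* the normalization assumes most genes are unchanged between samples. If
  a large, directionally unbalanced fraction of genes responds in one
  group, part of that shift is absorbed into the size factors and
  effect estimates for all genes are biased toward the complement. The
  test suite's power and interaction fixtures therefore use up/down-
  balanced or null-padded gene mixtures; real transcriptome-scale data
  (~26% responsive, both directions) is comfortably inside the method's
  operating range.

## Negative-binomial GLM

Counts are modeled as NB with variance μ + αμ², log link, and log size
factors as offsets.

**Dispersion.** Per experimental group, a method-of-moments estimate
α̂ = (s² − m)/m² is computed on normalized counts and pooled across groups
weighted by residual degrees of freedom (with 4 groups × 4 replicates this
gives 12 df, the main advantage of the four-group model over the per-time
fits). The pooled raw values are then shrunk toward a parametric trend
α(μ) = a/μ + b fitted across genes by non-negative least squares:
α = w·trend + (1−w)·raw with w = 0.5 by default, floored at 1e-8. The
weight and trend form are configurable; the defaults were chosen for
stability at n = 4 replicates, not to replicate any specific engine
bit-for-bit. Single-replicate designs carry no within-group information
and are accepted only with a user-supplied fixed α.

**Fitting.** Each gene is fit by iteratively reweighted least squares,
vectorized across genes (the per-gene normal equations are solved in
batch). The linear predictor is clamped to ±30 on the natural-log scale so
that separated fits (a group with all-zero counts) stay finite, and a
1e-10 ridge keeps the weighted normal equations solvable in that limit.
Convergence is a max |Δβ| < 1e-10 within 100 iterations; non-converged
genes are flagged, their p set missing and excluded from BH.

**Testing.** Contrast effects c᙮β are reported as log2 fold changes with
delta-method standard errors; the Wald statistic is referenced to the
standard normal, two-sided; BH is applied within each contrast.
Reported LFCs are plain maximum-likelihood estimates — no shrinkage —
because the downstream dual threshold (padj < 0.05 and |log2FC| > 0.5) is
defined on the raw fold change. Empirically (seeded all-null simulations,
5,000 genes, 4 replicates/group) the raw p < 0.05 fraction is ≈ 0.055,
slightly anti-conservative as expected for a plug-in-dispersion Wald test
at n = 4, and stable across seeds.

The three analyses: per-time (`~ condition` on one time's samples),
four-group (cell means with the two heat contrasts and the
control–control basal contrast), and interaction
(`~ condition + time + condition:time`). The per-time and four-group heat
contrasts estimate the same effects and differ only in dispersion pooling;
they agree on ≥ 90% of strong-effect calls.

## Refined categorization

A gene is *heat-responsive* iff significant (dual threshold) in at least
one heat contrast of the four-group model. Branches:

* **basal** — from the AM-control vs PM-control contrast: AM_higher if
  log2FC > 0.5, PM_higher if < −0.5, else equal. By default this is an
  LFC-only criterion (the literal reading of the classification rule);
  an option additionally requires padj < 0.05.
* **timing** — which heat contrasts are significant (AM_only, PM_only,
  both).
* **direction** — the sign of the significant heat effect(s); for
  both-times genes the signs agree by construction because genes
  significant in both contrasts with opposite signs are flagged
  **discordant** and receive no category number. Such genes exist in real
  data (e.g. AM-repressed/PM-induced chaperone co-factors) but fit none
  of the 18 patterns; they are surfaced, never silently dropped.

The (basal, timing, direction) triple maps bijectively onto categories
1–18 (AM-higher block 1–6, PM-higher 7–12, equal 13–18; AM-only /
PM-only / both pairs within each block; odd up, even down). Summaries
report per-category counts, nearest-integer percentages of the
categorized total (round half away from zero, matching the convention of
printed percentage tables), and the named unions (gated, time-independent,
basal-driven gated, …). Categories below `category_min_size` (default 10)
are marked unreported — a reporting flag only; assignment is unaffected.

## Temporal selection and clustering

Temporally gated genes are those with interaction-term padj < 0.05. No
fold-change cut is applied by default because the interaction effect is a
difference of two contrasts and its magnitude is not comparable to a
single-contrast LFC; a toggle exists. Selected genes are clustered on
their four condition-mean profiles (normalized counts by default; raw
counts and all-samples modes are available), z-scored per gene so that
only profile *shape* matters, with Euclidean distance and complete
linkage, the tree cut into `n_clusters` = 5 groups. Zero-variance rows
z-score to all-zeros and are logged. Groups are relabeled by decreasing
size with ties broken by the smallest member gene id, which together with
a sorted input order makes the assignment invariant to how the caller
orders genes. Linkage and metric are configurable; complete/Euclidean are
the conventional heatmap-clustering defaults.

## Enrichment

Overlap tests are exact: enrichment p = P(X ≥ k) and depletion
p = P(X ≤ k) for X hypergeometric over the declared universe (the two
tails share the point mass at k, so they sum to ≥ 1). The one-sided
Fisher exact test of the equivalent 2×2 table is provided as the
collection-level interface with BH across sets. Genes outside the
universe are dropped with a warning and counts recomputed — for
cross-study comparisons the universe should be the genes detectable in
*both* experiments. Tail computation delegates to scipy's hypergeometric
distribution, which accumulates in log space and is stable at large N.

## Conservation and ΔΔCq

For each gene, the 4-condition mean profile of the replicated diel
experiment is correlated (Pearson) with the single-replicate
constant-light profile, both on size-factor-normalized counts (linear
scale by default; a log2(x+1) toggle exists — the scale of the published
procedure is not fully specified, and Pearson r on 4 points can differ
between the two). Classes: r > 0.7 conserved, 0.5 < r ≤ 0.7 review,
else not conserved. The review band mirrors a manual-evaluation step and
is never auto-promoted. Zero-variance profiles give undefined r and are
flagged, classed not-conserved. Mean-level (not replicate-level) diel
profiles are used; with one circadian replicate there is no pairing that
would justify replicate-level correlation.

ΔΔCq: ΔCq = target Cq − arithmetic mean of reference Cqs (equivalent to
the geometric mean of linear quantities); ΔΔCq subtracts the calibrator
group's mean ΔCq (default PM control); relative expression =
efficiency^(−ΔΔCq) with efficiency 2.0 by default. The calibrator group's
mean ΔΔCq is 0 by construction.

## Synthetic data generator

The generator emulates the structure of the two-timepoint study: 4
replicates per group by default, NB counts, per-sample library-size
factors drawn log-uniformly from (0.7, 1.4) to exercise normalization,
per-gene baselines log-normal (μ = 5, σ = 2 in natural log, i.e. median
~150 counts) and dispersions log-normal around 0.05 (σ = 0.5), typical of
replicated plant RNA-seq. Each gene draws an archetype: one of the 18
categories (sign pattern of basal, AM-heat, PM-heat effects), `null`, or
`discordant` (AM-repressed / PM-induced). Effect magnitudes default to
2 log2 units for both basal and heat effects — a strong-effect regime
chosen so recovery tests measure classifier correctness rather than raw
power. Default mixture: 1.5% per category (27% responsive overall,
matching the ~26% responsive fraction of a genome-scale screen), 1%
discordant, 72% null. The truth table records every per-gene parameter.

The circadian counterpart re-simulates one replicate per group from the
same truth; genes flagged conserved keep their diel effects, the rest
have their time-specific heat effects replaced by a both-times response
of averaged magnitude (gating removed, responsiveness kept).

What the generator does **not** emulate: batch effects, mean–variance
trends beyond the NB, correlated genes, kinetic differences in response
timing, and rhythms beyond the two-label AM/PM abstraction. Passing
recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not performance on any particular real
dataset; genome-scale gene counts from real experiments are not
reproducible from synthetic data and are not targets of the test suite.

## Problem sizes

Defaults used in the tests and the acceptance script: 2,000-gene
simulations for recovery, 5,000 genes for type-I error, 500 genes for
planted clustering, 400 for conservation. The vectorized IRLS fits ~2,000
genes × 4 designs in well under a second, so these sizes give stable
statistics with a test suite that runs in seconds.

## Known limitations

* Wald tests with plug-in dispersions are mildly anti-conservative at
  small n; no outlier handling (Cook's-style) or independent filtering is
  performed.
* Median-of-ratios normalization biases effect estimates when the
  responsive fraction is large and directionally unbalanced (see above).
* The basal branch defaults to an LFC-only criterion; with noisy basal
  contrasts some equal-basal genes are assigned to basal-different
  categories (and vice versa) near the 0.5 cutoff.
* The discordant flag depends on both heat contrasts reaching
  significance; a gene discordant in truth but significant at only one
  time is categorized by that time's response.
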