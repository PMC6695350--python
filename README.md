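# dielgate

Time-of-day-resolved differential expression and gating analysis for
two-timepoint stress transcriptomes.

## The problem

The circadian clock and the day/night cycle reshape the baseline
transcriptome, so the set of genes called "stress-responsive" depends on
*when* the stress was applied. In a two-timepoint heat-shock design —
seedlings treated at dawn (AM) and dusk (PM), each with paired controls and
replicated RNA-seq — a transcript's response can be **gated** (present at
only one time of day, or of different magnitude) or **time-independent**,
and the apparent gating can originate in basal (unstressed) differences,
in the response itself, or both. `dielgate` is a library for dissecting
exactly this: it implements the differential-expression models, the
classification scheme and the downstream comparisons for a 4-group design
(AM/PM × control/heat, *n* replicates per group), plus a synthetic data
generator with per-gene ground truth so every stage can be validated
end-to-end without access to real sequencing data.

## The models

**Differential expression.** Counts \(K_{gj}\) are modeled as negative
binomial, \(K_{gj} \sim \mathrm{NB}(\mu_{gj}, \alpha_g)\) with
\(\mathrm{Var} = \mu + \alpha\mu^2\) and
\(\log \mu_{gj} = \log s_j + x_j^\top \beta_g\), where \(s_j\) are
median-of-ratios size factors. Three designs are provided:

1. **per-time** — `~ condition`, fit separately on AM and PM samples;
2. **four-group** — cell means for {AM, PM} × {control, heat}, with
   contrasts AM heat − AM control, PM heat − PM control and
   AM control − PM control;
3. **interaction** — `~ condition + time + condition:time`; the
   interaction coefficient tests whether the heat effect differs by time
   of day.

Gene-wise dispersions are method-of-moments estimates pooled across groups
and shrunk toward an \(a/\mu + b\) trend; each gene is fit by IRLS and
contrasts are Wald-tested with Benjamini–Hochberg adjustment per contrast.
Significance uses the dual threshold padj < 0.05 and |log2FC| > 0.5.

**Refined categorization.** Every heat-responsive gene (significant in at
least one heat contrast of the four-group model) is placed in one of 18
categories by three branches: basal level (AM-higher / PM-higher / equal,
from the control–control contrast), response timing (AM-only / PM-only /
both) and direction (up / down). Categories 1–6 have AM-higher basal,
7–12 PM-higher, 13–18 equal; within each block the pairs are AM-only,
PM-only, both; odd = up, even = down. Genes responding in opposite
directions at the two times are flagged *discordant*. Union bookkeeping
(gated = {1–4, 7–10, 13–16}, time-independent = {5–6, 11–12, 17–18},
basal-driven gated = {2, 3, 7, 10}, …) reports nearest-integer
percentages of the categorized total.

**Downstream.** Interaction-significant genes are clustered
(z-scored 4-condition profiles, Euclidean distance, complete linkage, tree
cut at *k* = 5); overlaps with external gene lists use exact
hypergeometric/Fisher tails with BH correction; conservation of a response
in a constant-light single-replicate experiment is called from the Pearson
correlation of 4-condition profiles (r > 0.7 conserved, 0.5–0.7 review);
and a ΔΔCq reduction supports qPCR validation
(\(\mathrm{rel.expr} = E^{-\Delta\Delta C_q}\), calibrated to PM control).

## Worked example

```python
import dielgate as dg

cfg = dg.SimulationConfig(seed=1)           # 2,000 genes, 4 reps/group
cm, truth = dg.simulate_experiment(cfg)
cm = dg.filter_low_counts(cm, min_count=10)

rc = dg.refined_categorize(dg.run_analysis2(cm))
summary = dg.summarize_categories(rc)
print(summary.total_categorized, summary.n_discordant)
print(summary.unions.loc[["gated", "time_independent"], ["count", "pct"]])
```

prints

```
548 24
                  count  pct
union
gated               374   68
time_independent    174   32
```

i.e. of the 548 genes the pipeline calls heat-responsive in this
simulation, 68% respond differently at dawn versus dusk (gated) and 32%
respond identically at both times; 24 further genes switch direction
between the timepoints. The `examples/` directory has one narrative
script per capability (simulation + DE, categorization, temporal
clustering, enrichment, conservation + ΔΔCq).

A thin CLI mirrors the library:
`dielgate simulate|de|categorize|temporal|enrich|conserve|ddcq|run`.

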