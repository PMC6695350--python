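"""Select temporally gated genes and cluster their response profiles.

Uses the interaction model to pick genes whose heat response depends on
the time of day, clusters their z-scored 4-condition profiles into five
groups, and prints each group's mean profile.
"""

import dielgate as dg

cfg = dg.SimulationConfig(seed=1)
cm, truth = dg.simulate_experiment(cfg)
cm = dg.filter_low_counts(cm, 10)

de3 = dg.run_analysis3(cm)
tg = dg.select_temporal_genes(de3)
print(f"{len(tg)} temporally heat-responsive genes (interaction padj < 0.05)")

ca = dg.cluster_temporal(tg, cm)
print(f"\ncluster sizes: {ca.sizes.to_dict()}")
print("\nmean z-scored profile per cluster (AMc, AMh, PMc, PMh):")
print(ca.profiles.round(2))
# Each row is one response shape, e.g. a positive AM_heat entry with a
# flat PM pair is a morning-only induction.
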