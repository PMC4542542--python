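"""Spatial analysis: does lineage relatedness track vegetation or geography?

Runs the full over-lakes analysis on a synthetic environment-driven study:
NMDS of samples on Bray-Curtis presence/absence, RDA of occurrence on
transect and vegetation dummies, and dbRDA of patristic distances on
transect- and vegetation-affinity columns, each with forward selection
(p < 0.1).  R2/adjR2 are percentages; P is the permutation p-value of the
selected model (999 permutations).
"""

import sedlineage as sl

data = sl.simulate_dataset(sl.strong_preset("environment", seed=7))
report = sl.run_spatial(data.occurrence, data.lake_table, data.tree,
                        n_perm=999, alpha=0.1, seed=7)

print(f"NMDS stress (k=2): {report.nmds.stress:.4f}")
print()
print(report.results.to_string(index=False))
print()
print("Reading: under an environment-driven truth the vegetation rows are")
print("significant while the transect (geography) rows are not — closely")
print("related lineages occupy similar vegetation, not similar transects.")
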