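"""Tissue-specific expansion: pairwise tests and heatmap clustering.

Simulates a 23-individual brain cohort across seven regions, measures
expansion indices end to end (somatic distribution -> electropherogram ->
sizing -> index), ranks tissues by median index, tests blood-like contrasts
pairwise, and clusters the z-scored individual x tissue matrix with
Manhattan distance.
"""
from repeatmosaic import simcore, cohortstats, pipeline

profiles = simcore.default_tissue_profiles()
cfg = simcore.CohortConfig(n_individuals=23, seed=30)
cohort = pipeline.measure_cohort(simcore.simulate_cohort(cfg, profiles), seed=31)

medians = cohort.groupby("tissue")["expansion_index"].median().sort_values()
print("median expansion index by tissue:")
for tissue, m in medians.items():
    print(f"  {tissue:18s} {m:.3f}")

pmat = cohortstats.pairwise_tissue_tests(cohort)
print(f"\nblood vs occipital cortex adjusted p = "
      f"{pmat.loc['blood', 'occipital_cortex']:.2e}")

brain = cohort[cohort["tissue"] != "blood"]
res = cohortstats.heatmap_cluster(brain)
print("\ncolumn clusters (Manhattan distance, average linkage):")
for tissue, cl in sorted(res.column_clusters.items(), key=lambda kv: kv[1]):
    print(f"  cluster {cl}: {tissue}")

# Cortical regions (cingulate gyrus, frontal BA9, occipital cortex) carry
# higher expansion propensities than subcortical ones and separate into
# their own column cluster, as in postmortem repeat-instability surveys.
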