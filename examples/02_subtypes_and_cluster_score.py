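"""Sub-biletypes, genus co-clusters and the cluster-1 signature score.

Splits biletype B into B1/B2 (B1 = the advanced-stage-enriched subtype),
co-clusters the signature genera into two blocks, and evaluates the
B1-enriched block ("bacterial cluster 1") as a single diagnostic score.
"""

from biletyper import (
    SyntheticCohortConfig,
    biletype_sweep,
    cluster_score_roc,
    generate_cohort,
    genus_coclusters,
    rank_genera_by_auc,
    sub_biletype,
    survival_by_group,
)

table, records, truth = generate_cohort(SyntheticCohortConfig(seed=1))
rel = table.relative()
ranking = rank_genera_by_auc(rel, records, "CCA", "BBD")
result = biletype_sweep(rel, records, ranking, seed=5)
result = sub_biletype(rel, records, result)

b1 = [s for s, v in result.sub_partition.items() if v == "B1"]
b2 = [s for s, v in result.sub_partition.items() if v == "B2"]
print(f"biletype B split into B1 (n={len(b1)}) and B2 (n={len(b2)}), "
      f"labelled by {result.sub_rule}")

clusters = genus_coclusters(rel, result.feature_taxa, b1_samples=b1)
cluster1 = [t for t, c in clusters.items() if c == 1]
overlap = len(set(cluster1) & set(truth.subsignature_taxa))
print(f"cluster 1 holds {len(cluster1)} genera; "
      f"{overlap} of the {len(truth.subsignature_taxa)} planted "
      f"aggressive-subgroup genera co-cluster there")

score = cluster_score_roc(rel, records, cluster1, "CCA")
print(f"cluster-1 signature score predicts CCA with AUC {score.auc:.3f}")

surv = survival_by_group(records, dict(result.sub_partition))
print(f"log-rank B1 vs B2: chi2 = {surv['chi_square']:.2f}, "
      f"p = {surv['p_value']:.3f}")
# The score AUC near 1 shows the co-clustered block carries the diagnostic
# signal; the log-rank p probes whether B1 also marks worse survival (the
# generator plants a hazard ratio of 3 on the aggressive subgroup, but at
# n=24 in B the test is underpowered, so large p-values here are common).
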