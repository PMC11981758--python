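"""Generate a synthetic bile cohort and discover biletypes.

Builds the default study cohort (20 cholangiocarcinoma-like cases, 20 benign
controls, 150 genera with a planted 17-genus case signature), ranks genera
by oriented diagnostic AUC, sweeps top-k genus combinations through Ward.D2
clustering and reports the chosen signature size, the two biletypes and how
well they recover the true case/control split.
"""

from sklearn.metrics import adjusted_rand_score

from biletyper import (
    SyntheticCohortConfig,
    biletype_sweep,
    generate_cohort,
    rank_genera_by_auc,
)

table, records, truth = generate_cohort(SyntheticCohortConfig(seed=1))
rel = table.relative()
print(f"cohort: {table.n_taxa} genera x {table.n_samples} bile samples")

ranking = rank_genera_by_auc(rel, records, "CCA", "BBD")
top = ranking.entries.iloc[0]
print(f"best single genus: {top['taxon_id']} "
      f"(oriented AUC {top['oriented_auc']:.3f}, {top['direction']})")

result = biletype_sweep(rel, records, ranking, seed=5)
part = [result.partition[s] for s in table.sample_ids]
ari = adjusted_rand_score(truth.group, part)
print(f"chosen signature size k = {result.chosen_k}")
print(f"biletype B holds {len(result.samples_in('B'))} samples "
      f"(the case-enriched community type)")
print(f"association: phi = {result.association['effect_size']:.2f}, "
      f"selection-adjusted p = {result.association['p_value']:.3g}")
print(f"adjusted Rand index vs true case/control labels: {ari:.2f}")
# ARI near 1 means the unsupervised biletypes rediscover the planted
# case/control structure; the permutation p guards against the sweep
# manufacturing an association on unstructured data.
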