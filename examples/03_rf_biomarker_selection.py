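"""Random-forest biomarker selection with repeated cross-validation.

Splits the cohort 7:3 (stratified), selects the number of biomarker genera
by five repeats of 10-fold cross-validation on the training set, and
evaluates the final forest on the held-out samples.
"""

from biletyper import SyntheticCohortConfig, generate_cohort
from biletyper.data import AbundanceTable, metadata_frame
from biletyper.rf import evaluate, rfcv_select, split_train_test, train_classifier

table, records, truth = generate_cohort(SyntheticCohortConfig(seed=1))
rel = table.relative()
labels = metadata_frame(records).set_index("sample_id").loc[rel.sample_ids, "group"]

train_ids, test_ids = split_train_test(rel.sample_ids, labels, ratio=0.7, seed=7)
train = AbundanceTable(rel.data[train_ids], kind=rel.kind)
test = AbundanceTable(rel.data[test_ids], kind=rel.kind)
train_recs = [r for r in records if r.sample_id in set(train_ids)]
test_recs = [r for r in records if r.sample_id in set(test_ids)]
print(f"train n={len(train_ids)}, test n={len(test_ids)} (stratified 7:3)")

report = rfcv_select(train, train_recs, seed=7)
print(f"cross-validation chose m = {report.chosen_m} genera (one-SE rule)")
hits = len(set(report.selected_taxa) & set(truth.signature_taxa))
print(f"{hits}/{report.chosen_m} selected genera belong to the planted signature")

model = train_classifier(train, train_recs, report.selected_taxa, "CCA", seed=7)
ev = evaluate(model, test, test_recs, "CCA")
print(f"held-out confusion: TP={ev.tp} FP={ev.fp} TN={ev.tn} FN={ev.fn}")
print(f"held-out AUC = {ev.auc:.3f}")
# The CV curve (report.cv_curve) shows how the error falls as genera are
# added; the one-SE rule picks the smallest signature whose error is
# statistically indistinguishable from the minimum.
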