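# Template configuration for `biletyper run-all`.
# Exactly one of `synthetic` / `input_paths` must be present.

out_dir: results/run1        # every stage writes here; manifest.json lists the outputs
seed: 1                      # master seed; stage seeds = seed + fixed offsets (mod 2^31)

# --- input: synthetic study cohort (omit this block to analyse real files)
synthetic:
  n_case: 20                 # CCA-like bile samples
  n_control: 20              # BBD-like bile samples
  n_taxa: 150
  signature_size: 17         # planted case-enriched genera
  subsignature_size: 7       # nested aggressive-subgroup genera
  fold_change_signature: 4.0
  fold_change_subsignature: 3.0
  aggressive_fraction: 0.25
  dispersion: 80.0           # Dirichlet concentration scale (lower = noisier)
  censor_rate: 0.3

# --- input: real tables (mutually exclusive with `synthetic`)
# input_paths:
#   abundance: data/genus_counts.tsv   # TSV, taxa as rows, samples as columns
#   metadata: data/metadata.tsv        # columns: sample_id, group[, tnm_stage,
#                                      #          survival_time, event, ...]
#   tree: data/genera.nwk              # optional, enables Faith's PD

# stages to run, in dependency order (default: all)
stages: [normalize, diversity, rank, lefse, biletype, rf, survival]

case_label: CCA
control_label: BBD
rarefy: true                 # subsample counts to the minimum depth first

# biletype sweep
k_max: 30
transform: log_z             # none | log | log_z
min_cluster_fraction: 0.1
n_label_permutations: 999    # permutation null for the association p
# force_k: 17                # override the automatic choice of k

# biomarker scan
lefse_alpha: 0.05
lda_threshold: 2.0

# community separation
permanova_permutations: 999

# random-forest selection
rf_ratio: 0.7
rf_rule: one_se              # one_se | min
rf_trees: 500
rf_trees_cv: 25
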