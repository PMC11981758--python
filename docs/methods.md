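# Methods

This note records the models, conventions and design choices behind
`biletyper`, in the spirit of a statistical methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and normalisation

Abundance tables are genus × sample matrices of counts or relative
abundances (columns summing to 1).  Library-size normalisation follows the
minimum-depth convention: every sample is subsampled *without replacement*
(multivariate hypergeometric draw) to the depth of the shallowest retained
sample, with an optional floor below which samples are dropped and
reported.  Sampling without replacement guarantees rarefied counts never
exceed the originals and column sums hit the target exactly; the draw is
deterministic given a seed.  Zero-total samples are treated as errors, not
silently dropped, because they always indicate an upstream problem.

## Synthetic cohorts

The generator emulates a small bile case/control study: a baseline
composition drawn once per cohort from a log-normal (σ = 2 on the log
scale, giving the heavy-tailed rank-abundance profile typical of genus
tables), a planted set of case-enriched "signature" genera, and a nested
"sub-signature" marking an aggressive case subgroup.  Counts are
Dirichlet-multinomial: the expected composition is scaled by the planted
fold changes, renormalised, perturbed by a Dirichlet draw (concentration =
composition × `dispersion`, default 80 — substantial overdispersion, in
line with 16S genus tables), and converted to counts by a multinomial at a
depth ~ Normal(30000, 8000) truncated at 1000.

Defaults describe the study scale the package targets: 20 cases vs 20
controls, 150 genera, 17 signature genera at fold change 4, 7 sub-signature
genera at a further fold change 3 in an aggressive quarter of the cases.
Because fold changes are applied before renormalisation, closure attenuates
them; the truth object records the realised per-genus ratios, and the
generator's correctness test checks large-n cohorts against that closed
form rather than the nominal factor.

TNM stage is advanced (III–IV) with probability 0.9 in the aggressive
subgroup and 0.4 in other cases.  Survival is exponential (baseline hazard
0.02/month, i.e. median ≈ 35 months; hazard ratio 3 for the aggressive
subgroup) under independent Uniform(0, u) censoring with u solved
numerically so the expected censoring fraction equals `censor_rate`
(default 30%).

What the generator does **not** emulate: taxonomic misassignment, batch and
primer effects between cohorts, phylogenetic correlation between genus
abundances, and non-proportional hazards.  Passing recovery tests therefore
demonstrates the *procedures* are correct and calibrated, not that real
bile cohorts will yield equally clean structure.

## Diagnostic ranking

Per-genus AUC uses midranks, so ties contribute ½ — identical to the
brute-force ordered-pair count, which the acceptance suite verifies
exactly.  Ranking is by oriented AUC max(AUC, 1−AUC) with a direction flag:
a consistently depleted genus is as informative as an enriched one, and the
published convention of reporting top-genus AUCs above 0.5 implies this
orientation.  Ties break lexicographically by genus id so rankings are
reproducible without a seed.

## Biletype discovery

**Feature transform.** Clustering operates on log₁₀(relative abundance +
10⁻⁶), z-scored per genus (configurable: `none` | `log` | `log_z`).  Raw
proportions let a single dominant genus swamp Euclidean distances; the
pseudocount is one order of magnitude below the smallest non-zero relative
abundance a ~30k-read sample can produce.

**Ward.D2.** Implemented directly via the Lance–Williams recurrence on
squared Euclidean distances, with heights equal to the Ward.D2
inter-cluster distance and deterministic tie-breaking by the smallest
(left, right) cluster-id pair.  The exposed implementation is validated
merge-by-merge against an exhaustive oracle that recomputes every candidate
merge cost from raw points and cluster means.  Inside the sweep's
permutation loop the identical linkage is delegated to scipy's compiled
Ward implementation for speed; a test asserts the two agree on random data.

**The sweep.** For k = 1..k_max (default 30) the top-k genera are
clustered and cut into two; cuts whose smaller side is below
`min_cluster_fraction` (default 10%) of samples are inadmissible, guarding
against 1-vs-rest degenerate splits.  The chosen k maximises |phi| against
the binary phenotype, with ties broken by smaller Fisher p then smaller k.
The full per-k trace is returned so a user can inspect the sweep or force a
particular k.

**Association inference.** The best-k association is selected over up to 30
correlated candidates, *and* the candidate features themselves were ranked
using the phenotype labels, so the chosen-k Fisher p is doubly
selection-biased.  The headline p-value is therefore a family-wise
permutation p: for each permuted label vector the entire analysis — AUC
ranking, top-k clustering, admissibility filtering, best-|phi| selection —
is re-run and the maximal |phi| recorded; the p-value is the fraction of
permutations (plus one) matching or beating the observed maximum.  Under a
null cohort this p is uniform by construction; the per-k Fisher p-values
remain available in the trace as descriptive statistics.

**Sub-biletypes and genus co-clusters.** Biletype B (the higher
case-fraction cluster) is re-clustered with the same feature set,
re-standardised within B.  B1 is the sub-cluster with the higher advanced
stage fraction; without stage information the smaller sub-cluster is
labelled B1 and the rule used is recorded.  Genus co-clustering runs
Ward.D2 over the standardised genus row-vectors; "cluster 1" is the block
with the higher mean abundance in B1.  The cluster-1 score is the mean
z-scored log abundance over the block's genera; its ROC sweeps all score
thresholds, and the AUC equals the Mann–Whitney statistic of the scores by
construction (asserted in tests).

## Biomarker scan (LEfSe-style)

A deliberate reimplementation of the idea, not of the original software:
Kruskal–Wallis screening at α = 0.05, then an effect size on the
conventional LDA scale — abundances per million, a shrinkage linear
discriminant fitted over 30 bootstrap subsamples (2/3 per class), each
feature's effect the average of its contribution along the unit
discriminant axis and its raw between-class mean difference, scored as
log₁₀(1 + effect).  The default threshold 2.0 demands ≈100 per-million
separation.  There is no subclass/all-against-all mode.  Calibration target
is honesty, not byte-level fidelity: on null data the pass fraction is
bounded by the screening level α.

## Random-forest selection

Stratified 7:3 train/test split.  Feature-count selection follows the rfcv
convention with leakage control: within each of 5×10 stratified CV folds
the importance ranking is recomputed on that fold's training portion
(the global-ranking shortcut is available behind a flag), and the
misclassification error of a forest on the top-m genera is measured on the
held-out portion for each m in {1..15, 20, 25, 30}.  The default selection
is the one-standard-error rule using the standard error of the mean CV
error (fold SD / √#folds).  The raw fold SD is not a usable yardstick here:
with ~3-sample fold test sets it is several times larger than the error
differences along the curve and degenerates the rule to "always pick
m = 1–2", so the conventional SE-of-the-mean form is used.

Forest sizes: 500 trees for the final model and full-train importance
ranking; 50 trees for per-fold ranking and 25 for per-m error estimation
inside CV, sizes at which the selection distribution is stable for cohorts
of this scale while a full 5×10×18-fit selection run stays interactive.

## Diversity and PERMANOVA

Shannon entropy defaults to log base 2 (the common amplicon-toolchain
convention; the base is an argument), Simpson is reported as Gini–Simpson
1 − Σp², and Faith's PD is root-inclusive (the minimal spanning subtree
connecting observed taxa to the root).  Bray–Curtis uses the standard
Σ|x−y| / Σ(x+y) form.  PCoA double-centres −D²/2 and reports all
eigenvalues, attaching coordinates only to positive axes.  PERMANOVA is the
one-way pseudo-F with free label permutation (no strata);
p = (1 + #{F* ≥ F}) / (1 + B).  For tiny cohorts an exhaustive mode
enumerates every distinct label arrangement and returns the exact p.  Note
that with duplicated points a random-permutation p can exceed the nominal
floor 1/(B+1) whenever a permutation re-creates the observed split; the
exact mode has no such granularity artefact.

## Survival

Kaplan–Meier product-limit estimation and the unweighted log-rank test are
delegated to lifelines behind a typed surface, with ties handled by the
standard simultaneous-risk-set convention.  Group comparisons of alpha
diversity default to Mann–Whitney for two groups and Kruskal–Wallis beyond.

## Pipeline determinism

Every stage seed is derived as (master seed + fixed stage offset) mod 2³¹,
so toggling one stage never shifts another's randomness.  The manifest
(config hash, stage seeds, file list) is byte-deterministic for a given
configuration; wall-clock timings go to a side file.  Clustering and
ranking are deterministic without seeds via explicit tie rules.

## Known limitations

- Biletype discovery assumes exactly two top-level community types; more
  are out of scope by design.
- The LEfSe-style scan will not numerically match the original software.
- The permutation association p re-runs the sweep per permutation; at
  B = 999 this costs ~10 s on a 40-sample cohort (B is a parameter).
- Problem sizes in the test suite (cohorts of 32–86 samples, 80–150
  genera, 100-cohort null batteries, 500-run calibration batteries) are
  chosen to exercise the estimators at the study's own scale while keeping
  a full verification run interactive.
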