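"""Biletype discovery: Ward.D2 clustering of samples on AUC-ranked genus
signatures, the top-k combination sweep, sub-biletyping, genus co-clustering
and cluster-signature ROC scoring.

The procedure mirrors enterotype-style community typing: genera are ranked
by oriented diagnostic AUC, the top-k genus combinations (k = 1..k_max) are
each fed to Ward.D2 agglomerative clustering on Euclidean distances, every
two-cluster partition is scored against the case/control phenotype, and the
k with the strongest association defines the biletypes.  Because the best k
is selected over many correlated candidates, the headline association
p-value is a label-permutation family-wise p of the maximal phi coefficient
across the sweep — under a null cohort it is uniform, so the sweep does not
manufacture significance.  Per-k Fisher p-values remain in the sweep trace.

Ward.D2 is implemented directly via the Lance-Williams recurrence on squared
Euclidean distances,

    d(k, i+j)^2 = [(n_i+n_k) d(k,i)^2 + (n_j+n_k) d(k,j)^2 - n_k d(i,j)^2]
                  / (n_i + n_j + n_k),

with deterministic tie-breaking by smallest (left, right) cluster index, so
runs are reproducible without a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from scipy.cluster.hierarchy import fcluster
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.stats import rankdata

from .data import AbundanceTable, CohortMetadata, metadata_frame
from .markers import RankedFeatureList, auc_mann_whitney, fisher_exact_2x2

__all__ = [
    "LinkageTree",
    "ward_d2_linkage",
    "cut_tree",
    "transform_features",
    "BiletypeResult",
    "biletype_sweep",
    "sub_biletype",
    "genus_coclusters",
    "ScoreRocResult",
    "cluster_score_roc",
]

DEFAULT_PSEUDOCOUNT = 1e-6


@dataclass
class LinkageTree:
    """Agglomerative merge list in the usual (left, right, height, size) form.

    Cluster ids follow the scipy convention: leaves are 0..n-1 and the
    cluster created by merge step t gets id n + t.
    """

    merges: np.ndarray  # (n-1, 4): left id, right id, height, merged size
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


def ward_d2_linkage(points, leaf_ids: list[str] | None = None) -> LinkageTree:
    """Ward.D2 agglomerative clustering of row vectors on Euclidean distances."""
    x = np.asarray(points, dtype=float)
    if hasattr(points, "index") and leaf_ids is None:
        leaf_ids = [str(i) for i in points.index]
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if np.isnan(x).any():
        raise ValueError("missing values in feature matrix")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]

    # squared Euclidean distances between singleton clusters
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1)
    size_total = 2 * n - 1
    d2 = np.full((size_total, size_total), np.inf)
    d2[:n, :n] = sq
    np.fill_diagonal(d2, np.inf)
    sizes = np.zeros(size_total, dtype=np.int64)
    sizes[:n] = 1
    active = np.zeros(size_total, dtype=bool)
    active[:n] = True

    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        idx = np.flatnonzero(active)
        sub = d2[np.ix_(idx, idx)]
        # smallest distance; ties -> smallest (left, right) id pair, which is
        # the first hit in row-major order over the upper triangle
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        best = float(vals.min())
        pick = int(np.flatnonzero(vals <= best + 1e-15)[0])
        i, j = int(idx[iu[0][pick]]), int(idx[iu[1][pick]])
        new = n + step
        height = float(np.sqrt(max(best, 0.0)))
        merges[step] = (i, j, height, sizes[i] + sizes[j])

        ni, nj = sizes[i], sizes[j]
        others = np.flatnonzero(active)
        others = others[(others != i) & (others != j)]
        nk = sizes[others]
        d2[new, others] = (
            (nk + ni) * d2[i, others]
            + (nk + nj) * d2[j, others]
            - nk * d2[i, j]
        ) / (ni + nj + nk)
        d2[others, new] = d2[new, others]
        sizes[new] = ni + nj
        active[i] = active[j] = False
        active[new] = True
    return LinkageTree(merges=merges, leaf_ids=list(leaf_ids))


def cut_tree(tree: LinkageTree, k: int) -> dict[str, int]:
    """Partition into k clusters by undoing the last k-1 merges.

    Returns leaf id -> cluster index; clusters are numbered 0..k-1 in order
    of their first leaf.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        left, right = int(tree.merges[step, 0]), int(tree.merges[step, 1])
        new = n + step
        parent[find(left)] = new
        parent[find(right)] = new
    roots: dict[int, int] = {}
    labels = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        labels[tree.leaf_ids[leaf]] = roots[r]
    return labels


def transform_features(
    table: AbundanceTable,
    taxa: list[str],
    transform: str = "log_z",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Samples x features matrix for clustering.

    ``transform`` is one of ``none`` (raw relative abundances), ``log``
    (log10 of relative abundance + pseudocount) or ``log_z`` (log then
    per-genus z-standardisation across the given samples).  The default
    log_z keeps one dominant genus from swamping Euclidean distances.
    """
    rel = table.relative()
    missing = [t for t in taxa if t not in rel.data.index]
    if missing:
        raise KeyError(f"taxa not in table: {missing}")
    feats = rel.data.loc[taxa].T.astype(float)  # samples x taxa
    if transform == "none":
        return feats
    if transform not in ("log", "log_z"):
        raise ValueError(f"unknown transform {transform!r}")
    feats = np.log10(feats + pseudocount)
    if transform == "log_z":
        sd = feats.std(axis=0, ddof=0)
        sd = sd.replace(0.0, 1.0)  # constant genus carries no signal
        feats = (feats - feats.mean(axis=0)) / sd
    return feats


def _phi(part: np.ndarray, case: np.ndarray) -> float:
    """Phi coefficient of a binary partition against a binary phenotype."""
    n = part.size
    s_p, s_c = part.sum(), case.sum()
    denom = s_p * (n - s_p) * s_c * (n - s_c)
    if denom == 0:
        return 0.0
    return float((n * (part & case).sum() - s_p * s_c) / np.sqrt(denom))


@dataclass
class BiletypeResult:
    """Outcome of the top-k biletype sweep.

    ``partition`` maps sample id to "A"/"B", with "B" the cluster holding
    the larger case fraction.  ``association`` carries the selection-adjusted
    (label-permutation, family-wise over the sweep) p-value and the phi
    effect size at the chosen k; the per-k Fisher p-values live in
    ``sweep_trace``.  ``confident`` is False when no k produced two
    admissible clusters.
    """

    confident: bool
    chosen_k: int | None
    feature_taxa: list[str]
    partition: dict[str, str] | None
    association: dict | None
    sweep_trace: pd.DataFrame
    case_label: str
    control_label: str
    sub_partition: dict[str, str] | None = None
    sub_rule: str | None = None
    genus_clusters: dict[str, int] | None = None
    transform: str = "log_z"
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def samples_in(self, label: str) -> list[str]:
        if self.partition is None:
            return []
        return [s for s, v in self.partition.items() if v == label]


def biletype_sweep(
    table: AbundanceTable,
    records: list[CohortMetadata],
    ranking: RankedFeatureList,
    k_max: int = 30,
    min_cluster_fraction: float = 0.1,
    transform: str = "log_z",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    n_label_permutations: int = 999,
    seed: int = 0,
    force_k: int | None = None,
) -> BiletypeResult:
    """Sweep top-k genus combinations, cluster with Ward.D2, pick the best k.

    For each k in 1..k_max the top-k genera (by oriented AUC) form the
    feature matrix, samples are Ward.D2-clustered and cut into two; cuts
    whose smaller cluster is below ``min_cluster_fraction`` of samples are
    skipped.  The chosen k maximises |phi| against the phenotype (ties:
    smaller Fisher p, then smaller k).  Clustering never sees the phenotype,
    so permuting labels leaves every partition unchanged; the association
    p-value is the family-wise permutation p of the maximal |phi|.
    """
    k_max = min(k_max, len(ranking.entries))
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    meta = metadata_frame(records).set_index("sample_id")
    groups = meta.loc[table.sample_ids, "group"].to_numpy()
    case = groups == ranking.case_label
    ctrl = groups == ranking.control_label
    if not case.any() or not ctrl.any():
        raise ValueError("both phenotype labels must be present")
    binary = case | ctrl
    n = table.n_samples
    min_size = min_cluster_fraction * n

    # transform every genus once; feature values never depend on the labels
    rel = table.relative()
    feats_full = transform_features(rel, rel.taxon_ids, transform, pseudocount)
    x = feats_full.to_numpy()
    taxa_arr = np.asarray(rel.taxon_ids)
    col_of = {t: i for i, t in enumerate(rel.taxon_ids)}
    cb = case[binary]

    def partitions_for(order_cols: np.ndarray):
        """Two-cluster Ward.D2 partitions of the top-k feature sets, k=1..k_max."""
        out = []
        for k in range(1, k_max + 1):
            z = _scipy_linkage(x[:, order_cols[:k]], method="ward")
            part = fcluster(z, 2, criterion="maxclust") == 1
            admissible = min(part.sum(), (~part).sum()) >= min_size
            out.append((part, admissible))
        return out

    obs_order = np.array([col_of[t] for t in ranking.top(k_max)])
    obs_parts = partitions_for(obs_order)

    rows = []
    partitions: dict[int, np.ndarray] = {}
    for k, (part, admissible) in enumerate(obs_parts, start=1):
        sizes = (int((~part).sum()), int(part.sum()))
        phi = np.nan
        fisher_p = np.nan
        if admissible:
            pb = part[binary]
            phi = abs(_phi(pb, cb))
            contingency = [
                [int((pb & cb).sum()), int((pb & ~cb).sum())],
                [int((~pb & cb).sum()), int((~pb & ~cb).sum())],
            ]
            _, fisher_p = fisher_exact_2x2(contingency)
            partitions[k] = part
        rows.append((k, sizes[0], sizes[1], admissible, phi, fisher_p))
    trace = pd.DataFrame(
        rows, columns=["k", "size_0", "size_1", "admissible", "abs_phi", "fisher_p"]
    )

    if not partitions:
        return BiletypeResult(
            confident=False,
            chosen_k=None,
            feature_taxa=[],
            partition=None,
            association=None,
            sweep_trace=trace,
            case_label=ranking.case_label,
            control_label=ranking.control_label,
            transform=transform,
            pseudocount=pseudocount,
        )

    admissible_trace = trace[trace["admissible"]]
    if force_k is not None:
        if force_k not in partitions:
            raise ValueError(f"force_k={force_k} is not an admissible sweep value")
        chosen_k = force_k
    else:
        best = admissible_trace.sort_values(
            ["abs_phi", "fisher_p", "k"], ascending=[False, True, True], kind="mergesort"
        ).iloc[0]
        chosen_k = int(best["k"])

    # Selection-adjusted association p: the genus ranking itself uses the
    # labels, so an honest null must redo the *whole* analysis -- AUC
    # ranking, top-k clustering, admissibility, best-|phi| selection -- on
    # every permuted label vector, not merely rescore fixed partitions.
    rng = np.random.default_rng(seed)
    rel_bin = rel.values[:, binary]
    rank_mat = rankdata(rel_bin, axis=1)  # per-genus midranks over binary samples
    nb = int(binary.sum())
    n_case_b = int(cb.sum())
    n_ctrl_b = nb - n_case_b

    def max_phi_for(y: np.ndarray) -> float:
        raw = (rank_mat @ y - n_case_b * (n_case_b + 1) / 2) / (n_case_b * n_ctrl_b)
        oriented = np.maximum(raw, 1.0 - raw)
        order = np.lexsort((taxa_arr, -oriented))
        best = -1.0
        for part, admissible in partitions_for(order):
            if admissible:
                best = max(best, abs(_phi(part[binary], y.astype(bool))))
        return best

    obs_max = float(np.nanmax(admissible_trace["abs_phi"]))
    y0 = cb.astype(float)
    exceed = 0
    for _ in range(n_label_permutations):
        if max_phi_for(y0[rng.permutation(nb)]) >= obs_max - 1e-12:
            exceed += 1
    family_p = float((1 + exceed) / (1 + n_label_permutations))

    part = partitions[chosen_k]
    # label "B" = cluster with the higher case fraction
    pb, cb = part[binary], case[binary]
    frac1 = cb[pb].mean() if pb.any() else 0.0
    frac0 = cb[~pb].mean() if (~pb).any() else 0.0
    b_is_one = frac1 >= frac0
    mapping = {True: "B" if b_is_one else "A", False: "A" if b_is_one else "B"}
    partition = {s: mapping[bool(v)] for s, v in zip(table.sample_ids, part)}

    chosen_row = trace.loc[trace["k"] == chosen_k].iloc[0]
    association = {
        "p_value": family_p,
        "effect_size": float(chosen_row["abs_phi"]),
        "fisher_p_at_chosen_k": float(chosen_row["fisher_p"]),
        "n_label_permutations": n_label_permutations,
    }
    return BiletypeResult(
        confident=True,
        chosen_k=chosen_k,
        feature_taxa=ranking.top(chosen_k),
        partition=partition,
        association=association,
        sweep_trace=trace,
        case_label=ranking.case_label,
        control_label=ranking.control_label,
        transform=transform,
        pseudocount=pseudocount,
    )


def sub_biletype(
    table: AbundanceTable,
    records: list[CohortMetadata],
    result: BiletypeResult,
) -> BiletypeResult:
    """Split biletype B into B1/B2 with the same feature set.

    Ward.D2 is rerun on B's samples only (features re-standardised within
    B).  B1 is the sub-cluster with the higher advanced-stage (TNM III-IV)
    fraction when stage information exists; otherwise the smaller
    sub-cluster, with the rule used recorded in ``sub_rule``.
    """
    if not result.confident or result.partition is None:
        raise ValueError("no confident biletype partition to subdivide")
    b_samples = result.samples_in("B")
    if len(b_samples) < 4:
        raise ValueError("biletype B must contain at least 4 samples")
    sub_table = AbundanceTable(table.data[b_samples], kind=table.kind)
    feats = transform_features(
        sub_table, result.feature_taxa, result.transform, result.pseudocount
    )
    tree = ward_d2_linkage(feats)
    labels = cut_tree(tree, 2)
    part = {s: labels[s] for s in b_samples}

    meta = metadata_frame(records).set_index("sample_id")
    adv_frac = {}
    for cl in (0, 1):
        samples = [s for s in b_samples if part[s] == cl]
        stages = meta.loc[samples, "tnm_stage"].dropna()
        adv_frac[cl] = (stages.isin(["III", "IV"]).mean()) if len(stages) else None
    if adv_frac[0] is not None and adv_frac[1] is not None and adv_frac[0] != adv_frac[1]:
        b1_cluster = 0 if adv_frac[0] > adv_frac[1] else 1
        rule = "advanced_stage_fraction"
    else:
        sizes = {cl: sum(1 for s in b_samples if part[s] == cl) for cl in (0, 1)}
        b1_cluster = min(sizes, key=lambda cl: (sizes[cl], cl))
        rule = "smaller_cluster"
    sub_partition = {
        s: ("B1" if part[s] == b1_cluster else "B2") for s in b_samples
    }
    return replace(result, sub_partition=sub_partition, sub_rule=rule)


def genus_coclusters(
    table: AbundanceTable,
    feature_taxa: list[str],
    n_clusters: int = 2,
    b1_samples: list[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, int]:
    """Ward.D2 co-clustering of signature genera (rows standardised across samples).

    Returns taxon -> 1-based cluster index.  Cluster 1 is the cluster with
    the higher mean transformed abundance in the given B1 samples (falling
    back to the overall mean when none are given), matching the convention
    that "Cluster 1" is the sub-biletype-B1-enriched block.
    """
    if len(feature_taxa) < 2:
        raise ValueError("need at least 2 feature taxa")
    if n_clusters > len(feature_taxa):
        raise ValueError("more clusters than taxa")
    feats = transform_features(table, feature_taxa, "log_z", pseudocount)
    rows = feats.T  # genera x samples, standardised per genus
    tree = ward_d2_linkage(rows)
    labels = cut_tree(tree, n_clusters)

    ref = rows[b1_samples].mean(axis=1) if b1_samples else rows.mean(axis=1)
    means = {}
    for cl in range(n_clusters):
        taxa = [t for t in feature_taxa if labels[t] == cl]
        means[cl] = float(ref.loc[taxa].mean())
    order = sorted(means, key=lambda cl: -means[cl])
    renumber = {cl: i + 1 for i, cl in enumerate(order)}
    return {t: renumber[labels[t]] for t in feature_taxa}


@dataclass
class ScoreRocResult:
    """Per-sample signature score with its ROC curve and AUC."""

    scores: pd.Series  # indexed by sample id
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    case_label: str


def cluster_score_roc(
    table: AbundanceTable,
    records: list[CohortMetadata],
    cluster_taxa: list[str],
    case_label: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ScoreRocResult:
    """Score samples by a genus cluster and evaluate it as a case classifier.

    The score is the mean over the cluster's genera of the z-standardised
    log10 relative abundance; the ROC sweeps every score threshold and the
    AUC is the Mann-Whitney probability that a case outscores a control.
    """
    if not cluster_taxa:
        raise ValueError("empty taxon set")
    feats = transform_features(table, list(cluster_taxa), "log_z", pseudocount)
    scores = feats.mean(axis=1)
    meta = metadata_frame(records).set_index("sample_id")
    groups = meta.loc[scores.index, "group"].to_numpy()
    case = groups == case_label
    if not case.any() or case.all():
        raise ValueError("need both case and non-case samples")
    fpr, tpr, thr = roc_curve(case.astype(int), scores.to_numpy())
    auc = auc_mann_whitney(scores.to_numpy()[case], scores.to_numpy()[~case])
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    scores.name = "score"
    scores.index.name = "sample_id"
    return ScoreRocResult(scores=scores, roc=roc, auc=float(auc), case_label=case_label)
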