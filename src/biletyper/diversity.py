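"""Alpha diversity, Bray-Curtis distances, PCoA and PERMANOVA.

Shannon entropy defaults to log base 2 (bits); Simpson is reported as the
Gini-Simpson index 1 - sum(p^2).  Faith's phylogenetic diversity is
root-inclusive: the branch lengths of the minimal subtree connecting the
observed taxa to the root.  PERMANOVA uses the classic one-way pseudo-F on a
distance matrix with free permutation of sample labels; for tiny cohorts the
exact null over all distinct label arrangements is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .data import AbundanceTable, CohortMetadata, metadata_frame

__all__ = [
    "shannon",
    "simpson",
    "faith_pd",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "OrdinationResult",
    "permanova",
    "PermanovaResult",
]


def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportion")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"proportions sum to {total}, not 1")
    return p


def shannon(proportions, base: float = 2.0) -> float:
    """Shannon entropy H = -sum p log_base p, with 0 log 0 := 0."""
    p = _check_proportions(proportions)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(base))


def simpson(proportions) -> float:
    """Gini-Simpson index 1 - sum p^2."""
    p = _check_proportions(proportions)
    return float(1.0 - (p**2).sum())


def faith_pd(present_taxa, tree: skbio.TreeNode) -> float:
    """Faith's PD: total branch length connecting the present taxa to the root."""
    present = set(present_taxa)
    leaves = {t.name for t in tree.tips()}
    missing = present - leaves
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    if not present:
        return 0.0
    total = 0.0
    marked: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            inc = node.name in present
        else:
            inc = any(marked[id(c)] for c in node.children)
        marked[id(node)] = inc
        if inc and node.length is not None and not node.is_root():
            total += node.length
    return float(total)


def alpha_diversity(
    table: AbundanceTable,
    tree: skbio.TreeNode | None = None,
    base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample Shannon, Gini-Simpson and (given a tree) Faith's PD."""
    rel = table.relative()
    rows = {}
    for sid in rel.sample_ids:
        p = rel.data[sid].to_numpy()
        row = {"shannon": shannon(p, base=base), "simpson": simpson(p)}
        if tree is not None:
            present = [t for t, v in zip(rel.taxon_ids, p) if v > 0]
            row["faith_pd"] = faith_pd(present, tree)
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def bray_curtis(table: AbundanceTable) -> skbio.DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples."""
    x = table.values.T  # samples x taxa
    zero = np.asarray(table.sample_ids)[x.sum(axis=1) == 0]
    if zero.size >= 2:
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {list(zero)}")
    d = squareform(pdist(x, metric="braycurtis"))
    return skbio.DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    sample_ids: list[str]
    eigenvalues: np.ndarray  # all eigenvalues, descending (may include negatives)
    coordinates: pd.DataFrame  # samples x positive axes, scaled by sqrt(eigenvalue)
    proportion_explained: np.ndarray  # per retained axis, of the positive eigenvalue mass


def pcoa(dist: skbio.DistanceMatrix, eig_tol: float = 1e-10) -> OrdinationResult:
    """Classical metric multidimensional scaling (principal coordinates).

    Double-centres -D^2/2, eigendecomposes, and returns coordinates on the
    axes with positive eigenvalues; negative eigenvalues (non-Euclidean
    distances) are reported but carry no coordinates.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > eig_tol * scale
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    prop = eigval[pos] / pos_sum if pos_sum > 0 else np.array([])
    ids = list(dist.ids)
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    frame.index.name = "sample_id"
    return OrdinationResult(
        sample_ids=ids,
        eigenvalues=eigval,
        coordinates=frame,
        proportion_explained=prop,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str = "monte-carlo"  # or "exhaustive"


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    a = len(groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: skbio.DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``p = (1 + #{permuted F >= observed F}) / (1 + n_permutations)`` with free
    label permutations; with ``exhaustive=True`` the p-value is the exact
    fraction of all distinct label arrangements (identity included) whose F
    meets or exceeds the observed one.
    """
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != len(dist.ids):
        raise ValueError("labels must align with the distance matrix samples")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, labels, groups)

    if exhaustive:
        seen = set()
        count = 0
        total = 0
        for perm in permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if _pseudo_f(d2, np.asarray(perm), groups) >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(
            pseudo_f=float(f_obs),
            p_value=count / total,
            n_permutations=total,
            method="exhaustive",
        )

    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    rng = np.random.default_rng(seed)
    # vectorised permutation null: per group, quadratic form of its indicator
    n = len(labels)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_permutations)])
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    a = len(groups)
    ss_within_perm = np.zeros(n_permutations)
    for g in groups:
        ng = float((labels == g).sum())
        # indicator of group g under each permutation of the labels
        perm_masks = (labels[perm_idx] == g).astype(float)
        ss_within_perm += np.einsum("bi,ij,bj->b", perm_masks, d2, perm_masks) / (2 * ng)
    ss_between_perm = ss_total - ss_within_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_between_perm / (a - 1)) / (ss_within_perm / (n - a))
    f_perm = np.nan_to_num(f_perm, nan=0.0, posinf=np.inf)
    count = int((f_perm >= f_obs - 1e-12).sum())
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=(1 + count) / (1 + n_permutations),
        n_permutations=n_permutations,
        method="monte-carlo",
    )


def group_alpha_comparison(
    table: AbundanceTable,
    records: list[CohortMetadata],
    metric: str = "shannon",
    tree: skbio.TreeNode | None = None,
) -> dict:
    """Compare an alpha metric between phenotype groups.

    Mann-Whitney for two groups, Kruskal-Wallis for more; returns the
    per-group medians and the test p-value.
    """
    from scipy import stats

    alpha = alpha_diversity(table, tree=tree)
    meta = metadata_frame(records).set_index("sample_id")
    groups = meta.loc[alpha.index, "group"]
    values = [alpha.loc[groups == g, metric].to_numpy() for g in groups.unique()]
    if len(values) < 2:
        raise ValueError("need at least two groups")
    if len(values) == 2:
        stat, p = stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
        test = "mann-whitney"
    else:
        stat, p = stats.kruskal(*values)
        test = "kruskal-wallis"
    return {
        "metric": metric,
        "test": test,
        "statistic": float(stat),
        "p_value": float(p),
        "medians": {g: float(np.median(v)) for g, v in zip(groups.unique(), values)},
    }
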