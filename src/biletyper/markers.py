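"""Per-genus diagnostic statistics: AUC ranking, a simplified LEfSe-style
biomarker scan, Fisher's exact test and Benjamini-Hochberg adjustment.

The single-genus area under the ROC curve is computed through the
Mann-Whitney identity: AUC = P(case value > control value) + 0.5 P(tie).
Genera are ranked by *oriented* AUC, max(AUC, 1-AUC), with a direction flag
recording whether the genus is enriched or depleted in cases, because a
consistently depleted genus is as diagnostic as an enriched one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .data import AbundanceTable, CohortMetadata, metadata_frame

__all__ = [
    "auc_mann_whitney",
    "RankedFeatureList",
    "rank_genera_by_auc",
    "LefseResult",
    "lefse_like",
    "fisher_exact_2x2",
    "bh_adjust",
]


def auc_mann_whitney(case_values, control_values) -> float:
    """AUC of case vs control values via midranks (ties count one half)."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([case, ctrl])
    ranks = stats.rankdata(pooled)
    r_case = ranks[: case.size].sum()
    u = r_case - case.size * (case.size + 1) / 2
    return float(u / (case.size * ctrl.size))


@dataclass
class RankedFeatureList:
    """Genera ordered by oriented diagnostic AUC.

    ``entries`` has columns taxon_id, raw_auc, oriented_auc, direction
    (enriched_in_case / depleted_in_case) and rank (1..n).  Ties in oriented
    AUC are broken lexicographically by taxon id.
    """

    entries: pd.DataFrame
    case_label: str
    control_label: str

    def top(self, k: int) -> list[str]:
        """Taxon ids of the k best-ranked genera."""
        if not 1 <= k <= len(self.entries):
            raise ValueError(f"k must be in [1, {len(self.entries)}]")
        return self.entries.sort_values("rank").head(k)["taxon_id"].tolist()


def rank_genera_by_auc(
    table: AbundanceTable,
    records: list[CohortMetadata],
    case_label: str,
    control_label: str,
) -> RankedFeatureList:
    """Rank every genus by its oriented case/control AUC on relative abundances."""
    rel = table.relative()
    meta = metadata_frame(records).set_index("sample_id")
    groups = meta.loc[rel.sample_ids, "group"].to_numpy()
    case_mask = groups == case_label
    ctrl_mask = groups == control_label
    if not case_mask.any():
        raise ValueError(f"no samples labelled {case_label!r}")
    if not ctrl_mask.any():
        raise ValueError(f"no samples labelled {control_label!r}")
    x = rel.values
    rows = []
    for i, taxon in enumerate(rel.taxon_ids):
        raw = auc_mann_whitney(x[i, case_mask], x[i, ctrl_mask])
        oriented = max(raw, 1.0 - raw)
        direction = "enriched_in_case" if raw >= 0.5 else "depleted_in_case"
        rows.append((taxon, raw, oriented, direction))
    df = pd.DataFrame(rows, columns=["taxon_id", "raw_auc", "oriented_auc", "direction"])
    df = df.sort_values(
        ["oriented_auc", "taxon_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankedFeatureList(entries=df, case_label=case_label, control_label=control_label)


@dataclass
class LefseResult:
    """Per-taxon Kruskal-Wallis p, discriminant effect size and pass flag."""

    entries: pd.DataFrame  # columns: taxon_id, kw_p, lda_score, passes
    alpha: float
    lda_threshold: float

    def passing(self) -> list[str]:
        return self.entries.loc[self.entries["passes"], "taxon_id"].tolist()


def lefse_like(
    table: AbundanceTable,
    records: list[CohortMetadata],
    class_labels: list[str] | None = None,
    alpha: float = 0.05,
    lda_threshold: float = 2.0,
    n_bootstrap: int = 30,
    subsample_fraction: float = 2 / 3,
    seed: int = 0,
) -> LefseResult:
    """Simplified LEfSe-style biomarker scan.

    Each taxon is screened with a Kruskal-Wallis test across classes at level
    ``alpha``.  Surviving taxa receive an effect size on the conventional LDA
    scale: abundances are expressed per million, a one-axis linear
    discriminant is fitted to the screened features over bootstrap subsamples
    (``subsample_fraction`` of each class), and each feature's effect is the
    mean over bootstraps of the average of (a) the absolute between-class
    difference of its contribution along the discriminant axis and (b) its
    absolute raw between-class mean difference; the score is log10(1 + that
    value), so a threshold of 2 demands roughly a 100-per-million separation.
    A taxon passes when kw_p < alpha and lda_score >= lda_threshold.

    This is deliberately a reimplementation of the idea (class screening +
    discriminant effect size), not a numerical replica of the original LEfSe
    software: there is no subclass mode and the bootstrap count is fixed.
    """
    rel = table.relative()
    meta = metadata_frame(records).set_index("sample_id")
    groups = meta.loc[rel.sample_ids, "group"].to_numpy()
    if class_labels is None:
        class_labels = sorted(set(groups))
    if len(class_labels) < 2:
        raise ValueError("need at least two classes")
    masks = {c: groups == c for c in class_labels}
    for c, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    keep = np.zeros(len(groups), dtype=bool)
    for m in masks.values():
        keep |= m
    x = rel.values[:, keep] * 1e6  # per-million scale, LEfSe convention
    y = groups[keep]

    kw_p = np.ones(rel.n_taxa)
    for i in range(rel.n_taxa):
        samples = [x[i, y == c] for c in class_labels]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples if s.size}) <= 1:
            kw_p[i] = 1.0
            continue
        try:
            kw_p[i] = stats.kruskal(*samples).pvalue
        except ValueError:  # all values identical
            kw_p[i] = 1.0

    screened = np.flatnonzero(kw_p < alpha)
    scores = np.zeros(rel.n_taxa)
    if screened.size:
        rng = np.random.default_rng(seed)
        feats = np.log10(x[screened, :].T + 1.0)  # samples x screened features
        effects = np.zeros((n_bootstrap, screened.size))
        class_idx = {c: np.flatnonzero(y == c) for c in class_labels}
        for b in range(n_bootstrap):
            take = np.concatenate(
                [
                    rng.choice(idx, size=max(2, int(round(subsample_fraction * idx.size))),
                               replace=False)
                    for idx in class_idx.values()
                ]
            )
            fb, yb = feats[take], y[take]
            w = _lda_axis(fb, yb)
            raw = x[screened, :].T[take]
            c0, c1 = class_labels[0], class_labels[-1]
            raw_diff = np.abs(raw[yb == c0].mean(axis=0) - raw[yb == c1].mean(axis=0))
            # per-feature contribution along the (unit) discriminant axis,
            # measured on the per-million scale, averaged with the raw difference
            effects[b] = 0.5 * (w * raw_diff + raw_diff)
        scores[screened] = np.log10(1.0 + effects.mean(axis=0))

    passes = (kw_p < alpha) & (scores >= lda_threshold)
    df = pd.DataFrame(
        {
            "taxon_id": rel.taxon_ids,
            "kw_p": kw_p,
            "lda_score": scores,
            "passes": passes,
        }
    )
    return LefseResult(entries=df, alpha=alpha, lda_threshold=lda_threshold)


def _lda_axis(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Unit vector of a two-class linear discriminant (shrinkage for stability)."""
    classes = np.unique(labels)
    if len(classes) != 2 or features.shape[1] == 1:
        return np.ones(features.shape[1]) / np.sqrt(features.shape[1])
    try:
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(features, labels)
        w = lda.coef_.ravel()
    except Exception:
        w = (features[labels == classes[1]].mean(axis=0)
             - features[labels == classes[0]].mean(axis=0))
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.ones(features.shape[1]) / np.sqrt(features.shape[1])
    return np.abs(w) / norm


def fisher_exact_2x2(table_2x2, mid_p: bool = False) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table (rows = exposure, columns = outcome).

    Returns (odds ratio ad/bc, two-sided p).  The two-sided p sums the
    hypergeometric probabilities of all tables with the observed margins
    whose point probability does not exceed the observed one; ``mid_p=True``
    instead counts the observed probability with weight one half.
    """
    t = np.asarray(table_2x2, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("negative cell count")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    a, b = t[0]
    c, d = t[1]
    odds = np.inf if b * c == 0 and a * d > 0 else (
        np.nan if b * c == 0 else a * d / (b * c)
    )
    n = t.sum()
    row1, col1 = a + b, a + c
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    eps = 1e-12
    if mid_p:
        p = pmf[pmf < p_obs - eps].sum() + 0.5 * pmf[np.abs(pmf - p_obs) <= eps].sum()
    else:
        p = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
    return float(odds), float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
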