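"""Random-forest biomarker selection with repeated cross-validation.

The procedure follows the rfcv convention: rank genera by mean decrease in
impurity, then for a grid of candidate feature counts m estimate the
classification error of a forest restricted to the top-m genera under
repeated stratified k-fold cross-validation.  By default the importance
ranking is recomputed inside every training fold so the m-feature error
estimates carry no selection leakage; the simpler global-ranking variant is
available behind a flag.  The final feature count follows the one-standard
-error rule (smallest m whose mean error is within one SD of the minimum),
favouring parsimonious signatures; the plain minimum rule is an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from .biletype import transform_features
from .data import AbundanceTable, CohortMetadata, metadata_frame
from .markers import auc_mann_whitney

__all__ = [
    "split_train_test",
    "rf_rank_importance",
    "RfSelectionReport",
    "rfcv_select",
    "train_classifier",
    "EvaluationReport",
    "evaluate",
    "DEFAULT_CANDIDATE_COUNTS",
]

DEFAULT_CANDIDATE_COUNTS = tuple(range(1, 16)) + (20, 25, 30)


def _features(table: AbundanceTable, taxa: list[str] | None = None) -> pd.DataFrame:
    taxa = taxa if taxa is not None else table.taxon_ids
    return transform_features(table, taxa, "log_z")


def _labels(records: list[CohortMetadata], sample_ids: list[str]) -> np.ndarray:
    meta = metadata_frame(records).set_index("sample_id")
    return meta.loc[sample_ids, "group"].to_numpy()


def split_train_test(
    sample_ids: list[str],
    labels,
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified train/test split preserving class proportions within rounding."""
    labels = np.asarray([str(x) for x in labels])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to stratify")
    train, test = train_test_split(
        list(sample_ids),
        train_size=ratio,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return list(train), list(test)


def rf_rank_importance(
    table: AbundanceTable,
    records: list[CohortMetadata],
    n_trees: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Mean-decrease-in-impurity importance of every genus, descending."""
    x = _features(table)
    y = _labels(records, table.sample_ids)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(x.to_numpy(), y)
    imp = pd.Series(forest.feature_importances_, index=x.columns, name="importance")
    return imp.sort_values(ascending=False, kind="mergesort")


@dataclass
class RfSelectionReport:
    """Cross-validated feature-count selection outcome."""

    importance: pd.Series  # full-train importance ranking, descending
    cv_curve: pd.DataFrame  # columns: m, mean_error, sd_error
    chosen_m: int
    selected_taxa: list[str]
    rule: str
    seed: int


def rfcv_select(
    table: AbundanceTable,
    records: list[CohortMetadata],
    candidate_counts=DEFAULT_CANDIDATE_COUNTS,
    n_repeats: int = 5,
    n_folds: int = 10,
    rule: str = "one_se",
    n_trees: int = 500,
    n_trees_cv: int = 25,
    n_trees_rank_cv: int = 50,
    recompute_per_fold: bool = True,
    seed: int = 0,
) -> RfSelectionReport:
    """Choose the number of biomarker genera by repeated k-fold cross-validation.

    For every fold, genera are ranked by forest importance on the fold's
    training portion (unless ``recompute_per_fold=False``, which reuses the
    full-train ranking) and the misclassification error of a forest on the
    top-m genera is measured on the held-out portion, for each m in
    ``candidate_counts``.  Errors are aggregated over ``n_repeats`` x
    ``n_folds`` folds.  ``rule="min"`` takes the smallest m attaining the
    minimal mean error; ``rule="one_se"`` the smallest m whose mean error is
    within one standard error of the mean (fold SD / sqrt(#folds)) of the
    minimum, the usual parsimony rule for CV curves.  Within each fold the
    ranking forest uses ``n_trees_rank_cv`` trees and the per-m error
    forests ``n_trees_cv``; the final full-train ranking uses ``n_trees``.
    """
    if rule not in ("min", "one_se"):
        raise ValueError("rule must be 'min' or 'one_se'")
    x = _features(table)
    y = _labels(records, table.sample_ids)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contain a single class")
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest class count {counts.min()}"
        )
    candidate_counts = sorted({int(m) for m in candidate_counts if 1 <= m <= x.shape[1]})
    if not candidate_counts:
        raise ValueError("no feasible candidate feature counts")

    global_rank = rf_rank_importance(table, records, n_trees=n_trees, seed=seed)
    xv = x.to_numpy()
    col_of = {t: i for i, t in enumerate(x.columns)}

    cv = RepeatedStratifiedKFold(
        n_splits=n_folds, n_repeats=n_repeats, random_state=seed
    )
    errors = np.zeros((cv.get_n_splits(), len(candidate_counts)))
    for f, (tr, te) in enumerate(cv.split(xv, y)):
        if recompute_per_fold:
            fold_forest = RandomForestClassifier(
                n_estimators=n_trees_rank_cv, random_state=seed + 1000 + f
            )
            fold_forest.fit(xv[tr], y[tr])
            order = np.argsort(fold_forest.feature_importances_)[::-1]
        else:
            order = np.array([col_of[t] for t in global_rank.index])
        for mi, m in enumerate(candidate_counts):
            cols = order[:m]
            forest = RandomForestClassifier(
                n_estimators=n_trees_cv, random_state=seed + 2000 + f
            )
            forest.fit(xv[np.ix_(tr, cols)], y[tr])
            pred = forest.predict(xv[np.ix_(te, cols)])
            errors[f, mi] = np.mean(pred != y[te])

    mean_err = errors.mean(axis=0)
    sd_err = errors.std(axis=0, ddof=1)
    se_err = sd_err / np.sqrt(errors.shape[0])
    curve = pd.DataFrame(
        {"m": candidate_counts, "mean_error": mean_err, "sd_error": sd_err,
         "se_error": se_err}
    )
    i_min = int(np.argmin(mean_err))
    if rule == "min":
        chosen_i = int(np.flatnonzero(mean_err <= mean_err[i_min] + 1e-12)[0])
    else:
        cutoff = mean_err[i_min] + se_err[i_min]
        chosen_i = int(np.flatnonzero(mean_err <= cutoff + 1e-12)[0])
    chosen_m = candidate_counts[chosen_i]
    selected = list(global_rank.index[:chosen_m])
    return RfSelectionReport(
        importance=global_rank,
        cv_curve=curve,
        chosen_m=chosen_m,
        selected_taxa=selected,
        rule=rule,
        seed=seed,
    )


def train_classifier(
    table: AbundanceTable,
    records: list[CohortMetadata],
    selected_taxa: list[str],
    case_label: str,
    n_trees: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the final forest on the selected genera; classes ordered (other, case)."""
    x = _features(table, selected_taxa)
    y = (_labels(records, table.sample_ids) == case_label).astype(int)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(x.to_numpy(), y)
    forest.selected_taxa_ = list(selected_taxa)
    return forest


@dataclass
class EvaluationReport:
    """Held-out confusion matrix (probability threshold 0.5) and ROC/AUC."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    roc: pd.DataFrame
    probabilities: pd.Series

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def evaluate(
    model: RandomForestClassifier,
    table: AbundanceTable,
    records: list[CohortMetadata],
    case_label: str,
    pseudocount_taxa_warning: bool = True,
) -> EvaluationReport:
    """Apply a trained forest to a test table and report confusion matrix and ROC.

    Selected genera missing from the test table are imputed as zero relative
    abundance (with a warning), mirroring how an absent genus reads in a new
    cohort.
    """
    if table.n_samples == 0:
        raise ValueError("empty test set")
    taxa = list(model.selected_taxa_)
    rel = table.relative()
    missing = [t for t in taxa if t not in rel.data.index]
    if missing:
        if pseudocount_taxa_warning:
            warnings.warn(f"test table missing selected taxa, imputing zero: {missing}",
                          stacklevel=2)
        filler = pd.DataFrame(0.0, index=missing, columns=rel.data.columns)
        rel = AbundanceTable(pd.concat([rel.data, filler]), kind="relative")
    feats = transform_features(rel, taxa, "log_z")
    y = (_labels(records, list(feats.index)) == case_label).astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("test set must contain both classes for evaluation")
    proba = model.predict_proba(feats.to_numpy())[:, list(model.classes_).index(1)]
    pred = (proba >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fpr, tpr, thr = roc_curve(y, proba)
    auc = auc_mann_whitney(proba[y == 1], proba[y == 0])
    probs = pd.Series(proba, index=feats.index, name="case_probability")
    return EvaluationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        auc=float(auc),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        probabilities=probs,
    )
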