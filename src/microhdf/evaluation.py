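"""Metrics, repeated stratified cross-validation and cross-study validation.

The evaluation protocol follows standard practice for imbalanced
phenotype prediction: stratified five-fold cross-validation repeated ten
times, scored by AUC, AUPR (more informative under class imbalance),
accuracy, recall and F1 for the case class at a 0.5 threshold.  Every
fold refits the full pipeline — clustering, feature ranking and wrapper
selection all happen inside the training fold, so no information leaks
from the held-out samples.

Batch-effect correction across cohorts is expected to be done upstream
(e.g. with MMUPHin in R); cross-study validation here assumes the two
profiles are already comparable and aligns them by taxon id.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .cascade import CascadeConfig, fit_microhdf
from .io_profiles import AbundanceProfile, SampleLabels, to_relative
from .tree import TaxonomyTree

__all__ = [
    "CohortSummary",
    "EvalReport",
    "imbalance_ratio",
    "binary_metrics",
    "repeated_cv",
    "cross_study",
    "cohort_summary",
]

METRICS = ("auc", "aupr", "accuracy", "recall", "f1")


@dataclass
class CohortSummary:
    n_case: int
    n_control: int
    n_features: int
    imbalance_ratio: float

    @property
    def total(self) -> int:
        return self.n_case + self.n_control


@dataclass
class EvalReport:
    records: pd.DataFrame  # one row per (repeat, fold) with the five metrics
    fold_assignments: dict  # (repeat, fold) -> held-out sample ids
    seed: int

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Metric -> (mean, sd) over all folds of all repeats."""
        return {
            m: (float(self.records[m].mean()), float(self.records[m].std(ddof=0)))
            for m in METRICS
        }

    def per_repeat(self) -> pd.DataFrame:
        return self.records.groupby("repeat")[list(METRICS)].mean()

    def mean(self, metric: str) -> float:
        return float(self.records[metric].mean())

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()


def imbalance_ratio(labels: SampleLabels) -> float:
    """Majority/minority class-count ratio, rounded half-up to 2 decimals."""
    n0, n1 = labels.counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("imbalance ratio undefined for a single-class cohort")
    ratio = max(n0, n1) / min(n0, n1)
    return float(Decimal(repr(ratio)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def cohort_summary(profile: AbundanceProfile, labels: SampleLabels) -> CohortSummary:
    n0, n1 = labels.counts()
    return CohortSummary(
        n_case=n1,
        n_control=n0,
        n_features=len(profile.taxon_ids),
        imbalance_ratio=imbalance_ratio(labels),
    )


def binary_metrics(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC, AUPR, accuracy, recall and F1 (case class) at the threshold.

    AUC uses the rank statistic with tie correction; AUPR is the
    precision-recall step integral.  Ties at the threshold resolve to
    the control class.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC/AUPR undefined for single-class y_true")
    pred = (scores > threshold).astype(int)
    return {
        "auc": float(roc_auc_score(y_true, scores)),
        "aupr": float(average_precision_score(y_true, scores)),
        "accuracy": float(accuracy_score(y_true, pred)),
        "recall": float(recall_score(y_true, pred, pos_label=1, zero_division=0)),
        "f1": float(f1_score(y_true, pred, pos_label=1, zero_division=0)),
    }


def _fit_predict(train_prof, train_labels, test_prof, tree, cfg):
    model = fit_microhdf(train_prof, train_labels, tree=tree, cfg=cfg)
    return model, model.predict_proba(test_prof)[:, 1]


def repeated_cv(
    profile: AbundanceProfile,
    labels: SampleLabels,
    tree: TaxonomyTree | None = None,
    cfg: CascadeConfig | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation repeated `repeats` times.

    Each fold refits the cascade on the training fold only; the held-out
    fold is scored with `binary_metrics`.
    """
    cfg = cfg if cfg is not None else CascadeConfig()
    labels.check_against(profile, training=True)
    sample_ids = [s for s in profile.sample_ids if s in labels.labels]
    prof = to_relative(profile.subset_samples(sample_ids))
    y = labels.vector(sample_ids)
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer samples than k={k}")
    rows = []
    assignments: dict = {}
    ids = np.array(sample_ids)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(skf.split(prof.values, y)):
            train_prof = prof.subset_samples(list(ids[tr]))
            test_prof = prof.subset_samples(list(ids[te]))
            train_labels = SampleLabels(
                {s: labels.labels[s] for s in ids[tr]}, labels.class_names
            )
            _, scores = _fit_predict(train_prof, train_labels, test_prof, tree, cfg)
            m = binary_metrics(y[te], scores, threshold=cfg.threshold)
            rows.append({"repeat": r, "fold": f, **m})
            assignments[(r, f)] = list(ids[te])
    return EvalReport(pd.DataFrame(rows), assignments, seed)


def cross_study(
    train_profile: AbundanceProfile,
    train_labels: SampleLabels,
    test_profile: AbundanceProfile,
    test_labels: SampleLabels,
    tree: TaxonomyTree | None = None,
    cfg: CascadeConfig | None = None,
) -> EvalReport:
    """Train on one cohort, evaluate once on another (taxa aligned by id)."""
    cfg = cfg if cfg is not None else CascadeConfig()
    shared = set(train_profile.taxon_ids) & set(test_profile.taxon_ids)
    if not shared:
        raise ValueError("no taxa shared between training and test cohorts")
    train_prof = to_relative(train_profile)
    model = fit_microhdf(train_prof, train_labels, tree=tree, cfg=cfg)
    scores = model.predict_proba(test_profile)[:, 1]
    y_test = test_labels.vector(test_profile.sample_ids)
    m = binary_metrics(y_test, scores, threshold=cfg.threshold)
    records = pd.DataFrame([{"repeat": 0, "fold": 0, **m}])
    return EvalReport(records, {(0, 0): list(test_profile.sample_ids)}, cfg.forest.seed)
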