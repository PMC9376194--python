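"""Cross-validation, zero-shot transfer and specificity evaluation.

The evaluation protocol mirrors a standard k-fold design: the cohort is
split into k stratified folds; for each fold a model is trained on the
remaining k-1 folds (80% of the sample for k=5) and evaluated on the
held-out fold. The k fitted models are then reusable as an ensemble-of-
folds on any external cohort: applied to an independent cohort generated
under the same law they measure transfer, and applied to a cohort in which
the discriminative signal is absent they measure specificity. Metrics are
reported per fold/model plus mean and standard deviation across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .datamodel import Cohort, CohortValidationError
from .model import StDNNConfig, TrainedModel, train

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass
class FoldAssignment:
    """Stratified fold labels for every subject in cohort order."""

    k: int
    fold_of_subject: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_subject == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_subject != fold)


@dataclass
class Metrics:
    """Accuracy, support-weighted precision/recall/F1, per-class values,
    and the 2x2 confusion table (rows = truth, columns = prediction)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    per_class: dict[str, np.ndarray] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {m: float(getattr(self, m)) for m in METRIC_NAMES}


@dataclass
class CVResult:
    models: list[TrainedModel]
    per_fold_metrics: list[Metrics]
    folds: FoldAssignment
    summary: dict[str, dict[str, float]]


def make_folds(labels, sites, k: int = 5, seed: int = 0,
               stratify_by_site: bool = True) -> FoldAssignment:
    """Deterministic stratified fold assignment.

    Always stratified by class; additionally by site when every
    site x class cell has at least k members (otherwise falls back to
    class-only stratification with a warning). Within each stratum,
    shuffled members are dealt round-robin with a running offset, so fold
    sizes and per-fold class proportions differ by at most one subject.
    """
    labels = np.asarray(labels, dtype=int)
    sites = np.asarray(sites)
    if k < 2:
        raise CohortValidationError("k must be >= 2")
    class_counts = np.bincount(labels, minlength=2)
    small = [c for c in (0, 1) if 0 < class_counts[c] < k]
    if small or np.any(class_counts == 0):
        raise CohortValidationError(
            f"every class needs >= {k} members; counts = {class_counts.tolist()}")

    use_site = stratify_by_site
    if use_site:
        for c in (0, 1):
            for s in np.unique(sites):
                n_cell = int(np.sum((labels == c) & (sites == s)))
                if 0 < n_cell < k:
                    warnings.warn(
                        f"site x class cell ({s}, {c}) has {n_cell} < {k} "
                        "members; falling back to class-only stratification",
                        stacklevel=2)
                    use_site = False
                    break
            if not use_site:
                break

    rng = np.random.default_rng(seed)
    fold = np.full(labels.size, -1, dtype=int)
    offset = 0
    strata = ([(c, s) for c in (0, 1) for s in np.unique(sites)]
              if use_site else [(c, None) for c in (0, 1)])
    for c, s in strata:
        members = np.flatnonzero((labels == c) if s is None
                                 else (labels == c) & (sites == s))
        if members.size == 0:
            continue
        members = members[rng.permutation(members.size)]
        fold[members] = (offset + np.arange(members.size)) % k
        offset += members.size
    return FoldAssignment(k, fold, seed)


def compute_metrics(predicted, truth) -> Metrics:
    """Classification metrics from hard binary predictions.

    Precision, recall and F1 are computed per class and support-weighted
    averaged; the raw per-class values are kept alongside for
    transparency. A class never predicted contributes precision 0.
    """
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.size == 0 or predicted.shape != truth.shape:
        raise CohortValidationError("predicted/truth must be equal-length, non-empty")
    conf = confusion_matrix(truth, predicted, labels=[0, 1])
    acc = np.trace(conf) / conf.sum()
    p, r, f, support = precision_recall_fscore_support(
        truth, predicted, labels=[0, 1], zero_division=0)
    w = support / support.sum()
    return Metrics(
        accuracy=float(acc),
        precision=float(np.sum(w * p)),
        recall=float(np.sum(w * r)),
        f1=float(np.sum(w * f)),
        confusion=conf,
        per_class={"precision": p, "recall": r, "f1": f, "support": support},
    )


def summarize(metrics_list: list[Metrics]) -> dict[str, dict[str, float]]:
    """Across-fold mean and sample standard deviation of each metric."""
    out = {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(x, m) for x in metrics_list])
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[m] = {"mean": float(vals.mean()), "sd": sd}
    return out


def crossvalidate(cohort: Cohort, config: StDNNConfig,
                  folds: FoldAssignment) -> CVResult:
    """Train/evaluate one model per fold; each trained on the other k-1."""
    if folds.fold_of_subject.size != len(cohort):
        raise CohortValidationError("fold assignment does not match cohort size")
    labels = cohort.labels
    models, metrics = [], []
    for j in range(folds.k):
        tr, te = folds.train_indices(j), folds.test_indices(j)
        try:
            model = train(cohort, tr, config)
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {j}: {exc}") from exc
        pred = model.predict_cohort(cohort.subset(te))
        models.append(model)
        metrics.append(compute_metrics(pred, labels[te]))
    return CVResult(models, metrics, folds, summarize(metrics))


def apply_models(models: list[TrainedModel], cohort: Cohort):
    """Evaluate each fold model on a full external cohort.

    Implements both the transfer test (external cohort, same generative
    law, unseen sites encoded all-zero) and the specificity test
    (signal-free cohort) — they differ only in the cohort passed in.
    Returns (per-model Metrics list, mean/sd summary).
    """
    truth = cohort.labels
    per_model = [compute_metrics(m.predict_cohort(cohort), truth)
                 for m in models]
    return per_model, summarize(per_model)
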