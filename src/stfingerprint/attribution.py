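"""Integrated-gradients fingerprints and group-level feature scores.

Integrated gradients attributes the target-class logit F to each input
cell by integrating the gradient of F along the straight path from a
baseline x' to the input x:

    IG_i(x) = (x_i - x'_i) * (1/m) * sum_{t=1..m} dF/dx_i evaluated at
              x' + (t - 0.5)/m * (x - x'),

a midpoint Riemann approximation of the path integral. It satisfies the
completeness axiom: the attributions sum to F(x) - F(x') as m grows, and
is exact at any m for (locally) affine F. The per-subject Nc x Nt signed
attribution matrix is the subject's "fingerprint".

Group-level consensus features are the median across target-group
subjects of the per-cell attributions (per fold model), then the median
across the k fold models; the top few percent of pooled consensus cells
mark the regions and timepoints that drive the classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Cohort, CohortValidationError, SubjectRecord
from .model import TrainedModel

_CHUNK = 256  # Riemann steps evaluated per forward/backward batch


@dataclass
class IGConfig:
    """Path-integral settings for integrated gradients."""

    n_steps: int = 50
    baseline: str = "zeros"            # "zeros" or "cohort-mean"
    target_class: int = 1

    def __post_init__(self) -> None:
        if self.n_steps < 8:
            raise CohortValidationError("n_steps must be >= 8")
        if self.baseline not in ("zeros", "cohort-mean"):
            raise CohortValidationError(f"unknown baseline {self.baseline!r}")


@dataclass
class AttributionMap:
    """Signed region x time attribution of the target-class logit."""

    subject_id: str
    scores: np.ndarray
    target_class: int


@dataclass
class FeatureScoreTable:
    """Group-level per-(region, time) scores and the top-percentile mask."""

    per_fold_scores: list[np.ndarray]
    median_scores: np.ndarray
    region_names: list[str]
    top_mask: np.ndarray | None = None
    threshold: float | None = None
    region_hits: list[tuple[str, int, float]] = field(default_factory=list)


def path_integrated_gradients(grad_fn, x: np.ndarray, baseline: np.ndarray,
                              n_steps: int) -> np.ndarray:
    """Midpoint-rule integrated gradients for an arbitrary gradient oracle.

    ``grad_fn`` maps a stacked batch of inputs (B, *x.shape) to the
    gradient of the scalar output at each, same shape.
    """
    diff = x - baseline
    alphas = (np.arange(1, n_steps + 1) - 0.5) / n_steps
    total = np.zeros_like(x)
    for start in range(0, n_steps, _CHUNK):
        a = alphas[start: start + _CHUNK]
        batch = baseline[None] + a[:, None, None] * diff[None]
        total += grad_fn(batch).sum(axis=0)
    return diff * (total / n_steps)


def integrated_gradients(model: TrainedModel, subject: SubjectRecord,
                         cfg: IGConfig,
                         cohort_mean: np.ndarray | None = None) -> AttributionMap:
    """Fingerprint of one subject under one fold model.

    The default baseline is the all-zero time series — after per-region
    z-scoring this is the cohort-typical "no signal" reference. The
    subject's site enters the model as its trained one-hot (all-zero for
    unseen sites) and is held fixed along the path, so completeness holds
    for the time-series input alone.
    """
    x = subject.timeseries
    if cfg.baseline == "cohort-mean":
        if cohort_mean is None:
            raise CohortValidationError(
                "cohort-mean baseline requires the cohort_mean matrix")
        baseline = np.broadcast_to(cohort_mean[:, : x.shape[1]], x.shape)
    else:
        baseline = np.zeros_like(x)
    site = model.site_onehot(subject.site)

    def grad_fn(batch):
        return model.input_gradient(batch, site, cfg.target_class)

    scores = path_integrated_gradients(grad_fn, x, baseline, cfg.n_steps)
    return AttributionMap(subject.subject_id, scores, cfg.target_class)


def attribute_cohort(models: list[TrainedModel], cohort: Cohort,
                     group: int, cfg: IGConfig) -> dict[int, list[AttributionMap]]:
    """Fingerprints of every group-``group`` subject under every fold model.

    Maps are cropped to the cohort-minimum number of timepoints so they
    can be stacked. Returns {fold index: [AttributionMap per subject]}.
    """
    nt = cohort.min_timepoints
    mean = None
    if cfg.baseline == "cohort-mean":
        mean = np.mean([s.timeseries[:, :nt] for s in cohort], axis=0)
    out: dict[int, list[AttributionMap]] = {}
    subjects = [s for s in cohort if s.class_label == group]
    if not subjects:
        raise CohortValidationError(f"no subjects in group {group}")
    for fold, model in enumerate(models):
        maps = []
        for s in subjects:
            cropped = SubjectRecord(s.subject_id, s.timeseries[:, :nt],
                                    s.class_label, s.site,
                                    s.symptom_scores, s.mean_fd)
            maps.append(integrated_gradients(model, cropped, cfg, mean))
        out[fold] = maps
    return out


def aggregate_group_features(per_fold_maps: dict[int, list[AttributionMap]],
                             region_names: list[str],
                             absolute: bool = False) -> FeatureScoreTable:
    """Nested-median consensus: median over subjects, then over folds.

    Signed attributions by default; ``absolute=True`` takes magnitudes
    first, for the variant that scores feature salience regardless of the
    direction of the contribution.
    """
    fold_scores = []
    for fold in sorted(per_fold_maps):
        maps = per_fold_maps[fold]
        if not maps:
            raise CohortValidationError(f"fold {fold} has no attribution maps")
        stack = [np.abs(m.scores) if absolute else m.scores for m in maps]
        fold_scores.append(np.median(stack, axis=0))
    consensus = np.median(fold_scores, axis=0)
    return FeatureScoreTable(fold_scores, consensus, list(region_names))


def threshold_top_features(table: FeatureScoreTable,
                           pct: float = 5.0) -> FeatureScoreTable:
    """Mark the top ``pct`` percent of pooled consensus cells.

    The threshold is the value of the ceil(pct% * Nc * Nt)-th largest
    consensus score; all cells at or above it are kept, so exact ties at
    the threshold expand the mask slightly beyond the nominal count.
    Fills ``top_mask``, ``threshold`` and ``region_hits`` (regions with at
    least one surviving cell, sorted by peak score, descending).
    """
    if not 0 < pct < 100:
        raise CohortValidationError("pct must lie in (0, 100)")
    scores = table.median_scores
    n_keep = math.ceil(pct / 100.0 * scores.size)
    thr = float(np.sort(scores, axis=None)[-n_keep])
    mask = scores >= thr
    hits = []
    for r in range(scores.shape[0]):
        n_cells = int(mask[r].sum())
        if n_cells:
            hits.append((table.region_names[r], n_cells,
                         float(scores[r][mask[r]].max())))
    hits.sort(key=lambda h: -h[2])
    table.top_mask = mask
    table.threshold = thr
    table.region_hits = hits
    return table


def subject_region_scores(attr_map: AttributionMap) -> np.ndarray:
    """Per-region scalar feature: temporal mean of the signed attribution."""
    return attr_map.scores.mean(axis=1)
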