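"""The spatiotemporal classifier and its margin-based training objective.

The classifier reads a regions x time matrix as a multichannel 1-D signal
(each brain region a channel), applies two convolution+ReLU blocks over
time, averages the resulting feature maps over time, concatenates a one-hot
encoding of the subject's acquisition site, and maps the result through a
single affine layer to two class logits. The class-1 probability is the
softmax of the logits, which for two classes equals a sigmoid of the logit
difference.

Training minimises a label-distribution-aware margin (LDAM) loss: a scaled
softmax cross-entropy in which the true class's logit is shifted down by a
per-class margin proportional to n_j^(-1/4), so rare classes are pushed to
larger decision margins. With zero margins and unit scale the loss reduces
exactly to the ordinary two-class softmax cross-entropy.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import network
from .datamodel import Cohort, CohortValidationError, encode_site_name, encode_sites


@dataclass
class StDNNConfig:
    """Architecture and training hyperparameters.

    ``site_vocab_size`` is normally filled in at training time from the
    cohort's site vocabulary.
    """

    n_regions: int
    conv_channels: tuple[int, int] = (64, 32)
    kernel_sizes: tuple[int, int] = (7, 5)
    strides: tuple[int, int] = (1, 1)
    site_vocab_size: int = 0
    ldam_C: float = 1.0
    ldam_max_margin: float = 0.5
    logit_scale: float = 30.0
    learning_rate: float = 3e-3
    epochs: int = 40
    batch_size: int = 16
    seed: int = 0
    loss: str = "ldam"                  # "ldam" or "cross_entropy"
    head: str = "cosine"                # "cosine" (normalized) or "linear"

    def __post_init__(self) -> None:
        f1, f2 = self.conv_channels
        k1, k2 = self.kernel_sizes
        if f1 < 1 or f2 < 1:
            raise ValueError("conv_channels must be >= 1")
        if k1 % 2 == 0 or k2 % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if min(self.strides) < 1:
            raise ValueError("strides must be >= 1")
        if self.loss not in ("ldam", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.head not in ("cosine", "linear"):
            raise ValueError(f"unknown head {self.head!r}")

    @property
    def receptive_field(self) -> int:
        return network.receptive_field(self.kernel_sizes, self.strides)

    @property
    def inference_head(self) -> str:
        """Output layer used at inference and for attribution.

        Cosine-trained models are scored through the "evidence" head
        (same argmax, positively homogeneous in the input) so that
        attribution magnitudes grade with signal strength.
        """
        return "evidence" if self.head == "cosine" else self.head


def ldam_margins(class_counts, C: float = 1.0,
                 max_margin: float | None = 0.5) -> np.ndarray:
    """Per-class margins Delta_j = C * n_j^(-1/4), rescaled to a cap.

    When ``max_margin`` is given, all margins are multiplied by one common
    constant so the largest margin (that of the rarest class) equals the
    cap; the constant absorbs C. With ``max_margin=None`` the raw
    C * n_j^(-1/4) values are returned.
    """
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 1):
        raise ValueError("every class count must be >= 1")
    if C <= 0:
        raise ValueError("C must be > 0")
    margins = C * counts ** -0.25
    if max_margin is not None:
        margins = margins * (max_margin / margins.max())
    return margins


@dataclass
class LDAMParams:
    """Margins and logit scale derived from training class counts."""

    class_counts: np.ndarray
    margins: np.ndarray
    scale: float

    @classmethod
    def from_counts(cls, class_counts, C: float = 1.0,
                    max_margin: float | None = 0.5,
                    scale: float = 30.0) -> "LDAMParams":
        counts = np.asarray(class_counts, dtype=float)
        return cls(counts, ldam_margins(counts, C, max_margin), float(scale))

    @classmethod
    def cross_entropy(cls, n_classes: int = 2) -> "LDAMParams":
        """Degenerate parameters making the loss plain cross-entropy."""
        return cls(np.ones(n_classes), np.zeros(n_classes), 1.0)


def ldam_loss(logits, label: int, params: LDAMParams) -> float:
    """LDAM loss for a single example.

    loss = -log softmax(s * (z - Delta .* onehot(y)))[y]; computed with a
    log-sum-exp for stability. Delta=0, s=1 recovers softmax cross-entropy.
    """
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    u = params.scale * (z - params.margins * np.eye(z.size)[label])
    c = u.max()
    return float(c + np.log(np.exp(u - c).sum()) - u[label])


def _ldam_batch(logits: np.ndarray, labels: np.ndarray, params: LDAMParams):
    """Mean LDAM loss over a batch and its gradient w.r.t. the logits."""
    onehot = np.eye(logits.shape[1])[labels]
    u = params.scale * (logits - params.margins[None, :] * onehot)
    c = u.max(axis=1, keepdims=True)
    expu = np.exp(u - c)
    p = expu / expu.sum(axis=1, keepdims=True)
    nll = -(u[np.arange(len(labels)), labels] - c[:, 0]
            - np.log(expu.sum(axis=1)))
    dlogits = params.scale * (p - onehot) / len(labels)
    return float(nll.mean()), dlogits


@dataclass
class TrainedModel:
    """A fitted classifier: config, learned weights, site vocabulary, log."""

    config: StDNNConfig
    parameters: dict[str, np.ndarray]
    site_vocabulary: list[str]
    training_log: list[float] = field(default_factory=list)

    # -- inference ---------------------------------------------------------

    def forward(self, timeseries: np.ndarray, site_onehot: np.ndarray):
        """Logits (logit_0, logit_1) for one subject."""
        ts = np.asarray(timeseries, dtype=float)
        if ts.ndim != 2 or ts.shape[0] != self.config.n_regions:
            raise CohortValidationError(
                f"expected {self.config.n_regions} region rows, "
                f"got shape {ts.shape}")
        site = np.asarray(site_onehot, dtype=float)
        if site.shape != (self.config.site_vocab_size,):
            raise CohortValidationError(
                f"site one-hot must have length {self.config.site_vocab_size}")
        logits = network.forward(
            self.parameters, self.config.strides, ts[None],
            np.array([ts.shape[1]]), site[None],
            head=self.config.inference_head)
        return float(logits[0, 0]), float(logits[0, 1])

    def logits_for_cohort(self, cohort: Cohort) -> np.ndarray:
        """(n_subjects, 2) logits; unseen sites encode as all-zero rows."""
        if cohort.n_regions != self.config.n_regions:
            raise CohortValidationError(
                f"cohort has {cohort.n_regions} regions, model expects "
                f"{self.config.n_regions}")
        enc = encode_sites(cohort, self.site_vocabulary)
        lengths = np.array([s.n_timepoints for s in cohort])
        x = np.zeros((len(cohort), cohort.n_regions, lengths.max()))
        for i, s in enumerate(cohort):
            x[i, :, : s.n_timepoints] = s.timeseries
        return network.forward(self.parameters, self.config.strides,
                               x, lengths, enc.matrix,
                               head=self.config.inference_head)

    def predict_cohort(self, cohort: Cohort) -> np.ndarray:
        """Hard class labels by argmax of the logits (margins are
        train-time only and play no role at inference)."""
        return self.logits_for_cohort(cohort).argmax(axis=1)

    def input_gradient(self, x_batch: np.ndarray, site_onehot: np.ndarray,
                       target_class: int) -> np.ndarray:
        """d(target-class logit)/d(input) for a batch of equal-length
        inputs sharing one site encoding. Used by attribution."""
        n, _, nt = x_batch.shape
        sites = np.tile(site_onehot[None, :], (n, 1))
        _, cache = network.forward(
            self.parameters, self.config.strides, x_batch,
            np.full(n, nt), sites, want_cache=True,
            head=self.config.inference_head)
        dlogits = np.zeros((n, 2))
        dlogits[:, target_class] = 1.0
        _, dx = network.backward(self.parameters, cache, dlogits)
        if not np.all(np.isfinite(dx)):
            raise FloatingPointError("non-finite input gradient")
        return dx

    def site_onehot(self, site: str) -> np.ndarray:
        return encode_site_name(site, self.site_vocabulary)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        """Single-file container: npz arrays + embedded JSON config."""
        meta = json.dumps({
            "config": asdict(self.config),
            "site_vocabulary": self.site_vocabulary,
            "training_log": self.training_log,
        })
        np.savez(os.fspath(path), __meta__=np.array(meta), **self.parameters)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedModel":
        with np.load(os.fspath(path), allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            params = {k: z[k] for k in z.files if k != "__meta__"}
        cfg = meta["config"]
        for key in ("conv_channels", "kernel_sizes", "strides"):
            cfg[key] = tuple(cfg[key])
        return cls(StDNNConfig(**cfg), params,
                   list(meta["site_vocabulary"]), list(meta["training_log"]))


def _make_batch(cohort: Cohort, idx: np.ndarray, site_matrix: np.ndarray):
    lengths = np.array([cohort.subjects[i].n_timepoints for i in idx])
    x = np.zeros((len(idx), cohort.n_regions, lengths.max()))
    for j, i in enumerate(idx):
        x[j, :, : lengths[j]] = cohort.subjects[i].timeseries
    labels = np.array([cohort.subjects[i].class_label for i in idx])
    return x, lengths, site_matrix[idx], labels


def train(cohort: Cohort, train_idx, config: StDNNConfig) -> TrainedModel:
    """Fit the classifier on the indexed subjects by minibatch Adam.

    Margins are computed once from the training-set class counts. Fully
    deterministic given ``config.seed``.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    if train_idx.size == 0:
        raise CohortValidationError("training index set is empty")
    labels = cohort.labels[train_idx]
    counts = np.bincount(labels, minlength=2)
    if np.any(counts == 0):
        raise CohortValidationError(
            "training set must contain both classes; counts "
            f"= {counts.tolist()}")
    short = [cohort.subjects[i].subject_id for i in train_idx
             if cohort.subjects[i].n_timepoints < config.receptive_field]
    if short:
        raise CohortValidationError(
            f"subjects shorter than the receptive field "
            f"({config.receptive_field} timepoints): {short}")

    vocab = list(cohort.site_vocabulary)
    cfg = StDNNConfig(**{**asdict(config),
                         "n_regions": cohort.n_regions,
                         "site_vocab_size": len(vocab)})
    if config.loss == "ldam":
        loss_params = LDAMParams.from_counts(
            counts, cfg.ldam_C, cfg.ldam_max_margin, cfg.logit_scale)
    else:
        # plain softmax cross-entropy; cosine logits live in [-1, 1] so
        # they still need the temperature to produce confident posteriors
        scale = cfg.logit_scale if cfg.head == "cosine" else 1.0
        loss_params = LDAMParams(counts.astype(float),
                                 np.zeros_like(counts, dtype=float), scale)

    rng = np.random.default_rng(cfg.seed)
    params = network.init_params(cfg.n_regions, cfg.conv_channels,
                                 cfg.kernel_sizes, len(vocab), rng)
    opt = network.Adam(params, lr=cfg.learning_rate)
    site_matrix = encode_sites(cohort, vocab).matrix

    log = []
    for _ in range(cfg.epochs):
        order = train_idx[rng.permutation(train_idx.size)]
        epoch_loss = 0.0
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start: start + cfg.batch_size]
            x, lengths, sites, y = _make_batch(cohort, batch, site_matrix)
            logits, cache = network.forward(
                params, cfg.strides, x, lengths, sites, want_cache=True,
                head=cfg.head)
            loss, dlogits = _ldam_batch(logits, y, loss_params)
            grads, _ = network.backward(params, cache, dlogits)
            opt.step(params, grads)
            epoch_loss += loss * batch.size
        log.append(epoch_loss / order.size)
    return TrainedModel(cfg, params, vocab, log)
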