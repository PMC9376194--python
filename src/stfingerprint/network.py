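"""Numerical core of the spatiotemporal classifier.

Pure-numpy forward and backward passes for a small network built from two
valid (unpadded) 1-D convolutions over time with brain regions as input
channels, ReLU activations, a masked temporal average, concatenation of a
site one-hot vector, and an affine two-logit head.

Variable-length inputs are right-padded to the batch maximum; every stage
masks positions whose receptive field would touch padding, and the temporal
average divides by each subject's true number of valid positions, so padded
and unpadded presentations of the same series yield identical logits.

All parameters live in a plain dict of ndarrays:
    W1 (F1, Nc, k1), b1 (F1,), W2 (F2, F1, k2), b2 (F2,),
    W3 (2, F2 + V), b3 (2,)
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_out_len(n_in: int, kernel: int, stride: int) -> int:
    """Number of valid convolution outputs; 0 if the input is too short."""
    if n_in < kernel:
        return 0
    return (n_in - kernel) // stride + 1


def receptive_field(kernel_sizes, strides) -> int:
    """Minimum input length producing at least one output of block 2."""
    k1, k2 = kernel_sizes
    s1 = strides[0]
    return k1 + (k2 - 1) * s1


def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int):
    """Valid 1-D convolution. x (B,C,L), w (F,C,k) -> (B,F,Lout)."""
    k = w.shape[2]
    win = sliding_window_view(x, k, axis=2)[:, :, ::stride, :]
    out = np.einsum("bclk,fck->bfl", win, w, optimize=True) + b[None, :, None]
    return out, win


def _conv1d_backward(dout: np.ndarray, win: np.ndarray, x_len: int,
                     w: np.ndarray, stride: int):
    """Gradients of a valid conv. Returns (dW, db, dX)."""
    dw = np.einsum("bclk,bfl->fck", win, dout, optimize=True)
    db = dout.sum(axis=(0, 2))
    n_batch, n_filt, l_out = dout.shape
    k = w.shape[2]
    if stride > 1:                      # dilate to undo the stride
        dil = np.zeros((n_batch, n_filt, (l_out - 1) * stride + 1))
        dil[:, :, ::stride] = dout
    else:
        dil = dout
    pad = np.pad(dil, ((0, 0), (0, 0), (k - 1, k - 1)))
    win2 = sliding_window_view(pad, k, axis=2)
    dx = np.einsum("bflk,fck->bcl", win2, w[:, :, ::-1], optimize=True)
    if dx.shape[2] < x_len:             # stride remainder: tail never touched
        dx = np.pad(dx, ((0, 0), (0, 0), (0, x_len - dx.shape[2])))
    return dw, db, dx[:, :, :x_len]


def _valid_mask(lengths: np.ndarray, total: int) -> np.ndarray:
    """(B, total) boolean mask of positions strictly before each length."""
    return np.arange(total)[None, :] < lengths[:, None]


_NORM_EPS = 1e-12


def init_params(n_regions: int, conv_channels, kernel_sizes, site_vocab_size: int,
                rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-normal conv weights, zero biases, small-random output head."""
    f1, f2 = conv_channels
    k1, k2 = kernel_sizes
    w1 = rng.normal(0.0, np.sqrt(2.0 / (n_regions * k1)), size=(f1, n_regions, k1))
    w2 = rng.normal(0.0, np.sqrt(2.0 / (f1 * k2)), size=(f2, f1, k2))
    w3 = rng.normal(0.0, np.sqrt(1.0 / (f2 + site_vocab_size)),
                    size=(2, f2 + site_vocab_size))
    return {
        "W1": w1, "b1": np.zeros(f1),
        "W2": w2, "b2": np.zeros(f2),
        "W3": w3, "b3": np.zeros(2),
    }


def forward(params: dict, strides, x: np.ndarray, lengths: np.ndarray,
            sites: np.ndarray, want_cache: bool = False,
            head: str = "cosine"):
    """Batched forward pass.

    Parameters
    ----------
    x : (B, Nc, Lmax) right-padded inputs (padding value irrelevant).
    lengths : (B,) true number of timepoints per subject.
    sites : (B, V) one-hot site rows (all-zero allowed for unseen sites).
    head : which output layer to apply to the pooled+site feature vector f.
        "cosine"  — logits are cosine similarities (f and the weight rows
        both L2-normalized, no bias). Used for the margin loss at training
        time: an unconstrained head could shrink its logit scale until any
        fixed additive margin is trivially satisfied, so margins only stay
        meaningful on normalized logits.
        "evidence" — logits f . w_j/||w_j|| (weight rows normalized, f
        not, no bias). Shares the argmax with "cosine" (the two differ by
        the positive factor 1/||f||), but remains positively homogeneous
        in the input, so attribution magnitudes grade with signal
        strength. Used at inference and for integrated gradients.
        "linear"  — plain affine layer.

    Returns logits (B, 2), and a cache dict when ``want_cache``.
    """
    s1, s2 = strides
    k1 = params["W1"].shape[2]
    k2 = params["W2"].shape[2]
    l1 = np.maximum(0, (lengths - k1) // s1 + 1) * (lengths >= k1)
    if np.any(l1 < k2):
        bad = int(lengths[np.argmin(l1)])
        need = receptive_field((k1, k2), (s1, s2))
        raise ValueError(
            f"input with {bad} timepoints is shorter than the receptive "
            f"field; need at least {need} timepoints")
    l2 = (l1 - k2) // s2 + 1

    z1, win1 = _conv1d(x, params["W1"], params["b1"], s1)
    m1 = (z1 > 0) & _valid_mask(l1, z1.shape[2])[:, None, :]
    h1 = np.where(m1, z1, 0.0)

    z2, win2 = _conv1d(h1, params["W2"], params["b2"], s2)
    m2 = (z2 > 0) & _valid_mask(l2, z2.shape[2])[:, None, :]
    h2 = np.where(m2, z2, 0.0)

    pooled = h2.sum(axis=2) / l2[:, None]          # masked temporal average
    feats = np.concatenate([pooled, sites], axis=1)
    if head in ("cosine", "evidence"):
        wnorm = np.linalg.norm(params["W3"], axis=1, keepdims=True) + _NORM_EPS
        v = params["W3"] / wnorm
        if head == "cosine":
            fnorm = np.linalg.norm(feats, axis=1, keepdims=True) + _NORM_EPS
            u = feats / fnorm
            logits = u @ v.T
        else:
            logits = feats @ v.T
    elif head == "linear":
        logits = feats @ params["W3"].T + params["b3"]
    else:
        raise ValueError(f"unknown head {head!r}")
    if not want_cache:
        return logits
    cache = dict(x=x, win1=win1, m1=m1, h1=h1, win2=win2, m2=m2,
                 l2=l2, feats=feats, strides=(s1, s2), head=head)
    if head == "cosine":
        cache.update(fnorm=fnorm, wnorm=wnorm, u=u, v=v, logits=logits)
    elif head == "evidence":
        cache.update(wnorm=wnorm, v=v, logits=logits)
    return logits, cache


def backward(params: dict, cache: dict, dlogits: np.ndarray):
    """Gradients w.r.t. all parameters and the input batch.

    Returns (grads dict, dX with the same shape as the padded input).
    """
    s1, s2 = cache["strides"]
    f2 = params["W2"].shape[0]
    grads = {}
    if cache["head"] == "cosine":
        u, v = cache["u"], cache["v"]
        # d(u.v_j)/dw_j = (u - (u.v_j) v_j)/||w_j|| ; likewise for features
        grads["W3"] = (dlogits.T @ u
                       - (dlogits * cache["logits"]).sum(0)[:, None] * v
                       ) / cache["wnorm"]
        grads["b3"] = np.zeros_like(params["b3"])
        dfeats = (dlogits @ v
                  - (dlogits * cache["logits"]).sum(1, keepdims=True) * u
                  ) / cache["fnorm"]
    elif cache["head"] == "evidence":
        v = cache["v"]
        grads["W3"] = (dlogits.T @ cache["feats"]
                       - (dlogits * cache["logits"]).sum(0)[:, None] * v
                       ) / cache["wnorm"]
        grads["b3"] = np.zeros_like(params["b3"])
        dfeats = dlogits @ v
    else:
        grads["W3"] = dlogits.T @ cache["feats"]
        grads["b3"] = dlogits.sum(axis=0)
        dfeats = dlogits @ params["W3"]
    dpooled = dfeats[:, :f2]
    dh2 = (dpooled[:, :, None] / cache["l2"][:, None, None]) \
        * cache["m2"].astype(float)
    grads["W2"], grads["b2"], dh1 = _conv1d_backward(
        dh2, cache["win2"], cache["h1"].shape[2], params["W2"], s2)
    dh1 = np.where(cache["m1"], dh1, 0.0)
    grads["W1"], grads["b1"], dx = _conv1d_backward(
        dh1, cache["win1"], cache["x"].shape[2], params["W1"], s1)
    return grads, dx


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (
                np.sqrt(self.v[k] / c2) + self.eps)
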