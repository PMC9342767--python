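"""Losses, schedules, partitioning, augmentation, local training, and AUC.

The binary loss is the class-weighted cross entropy used for the
imbalanced series-classification task,

    L(X, y) = -w(1) * y * log p  -  w(0) * (1 - y) * log(1 - p),

with w(1) the pooled positive prevalence over the joint training set
and w(0) = 1 - w(1).  Note the convention: w(1) multiplies the
*positive* log-term, so the minority class is down-weighted by its
prevalence — the exact printed form, which is the opposite of the
common prevalence-inverse weighting.  ``conventional=True`` swaps the
weights for users who want the usual convention; it is off by default.

The multi-label loss is the plain sum of per-class binary cross
entropies over the (default 14) pathology labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .crypto.bundle import WeightBundle
from .nn.network import Network
from .nn.optim import OptimizerConfig, make_optimizer

__all__ = [
    "ClassWeights",
    "class_weights",
    "weighted_bce",
    "multilabel_bce",
    "softmax_cross_entropy",
    "step_decay_lr",
    "PlateauScheduler",
    "partition_early_sharing",
    "augment",
    "local_train",
    "auc",
    "EPS",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

EPS = 1e-7
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class ClassWeights:
    """Binary class weights with w0 = 1 - w1."""

    w1: float
    w0: float

    def __post_init__(self):
        if not (0 < self.w1 < 1):
            raise ValueError("w1 must lie in (0, 1)")
        if abs(self.w0 - (1 - self.w1)) > 1e-12:
            raise ValueError("w0 must equal 1 - w1")


def class_weights(pos_counts: Sequence[int], total_counts: Sequence[int]) -> ClassWeights:
    """Pooled-prevalence weights over one or more joint training sets.

    w1 = sum(positives) / sum(totals); w0 = 1 - w1.  With the two
    knee-MRI training sets (139/552 and 208/1130) this gives
    w1 = 347/1682 ~ 0.2063.
    """
    pos = int(np.sum(pos_counts))
    tot = int(np.sum(total_counts))
    if tot <= 0 or pos <= 0 or pos >= tot:
        raise ValueError("need 0 < sum(pos) < sum(total)")
    w1 = pos / tot
    return ClassWeights(w1=w1, w0=1.0 - w1)


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def weighted_bce(p, y, w: ClassWeights, conventional: bool = False) -> float:
    """Class-weighted binary cross entropy; mean over a batch.

    ``conventional=True`` applies w(0) to the positive term instead
    (prevalence-inverse weighting); the default follows the printed
    formula exactly.
    """
    p = _clamp(np.asarray(p, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    w1, w0 = (w.w0, w.w1) if conventional else (w.w1, w.w0)
    loss = -w1 * y * np.log(p) - w0 * (1 - y) * np.log(1 - p)
    return float(np.mean(loss))


def multilabel_bce(p, y, n_labels: int = 14) -> float:
    """Sum of per-label binary cross entropies; mean over a batch.

    Inputs are (n_labels,) vectors or (batch, n_labels) matrices; a
    length other than ``n_labels`` is rejected.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if p.shape[1] != n_labels or y.shape != p.shape:
        raise ValueError(f"expected {n_labels} labels per item, got p{p.shape} y{y.shape}")
    p = _clamp(p)
    per_item = (-y * np.log(p) - (1 - y) * np.log(1 - p)).sum(axis=1)
    return float(per_item.mean())


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean CE over a batch and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(_clamp(probs[np.arange(n), labels])).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


def step_decay_lr(ce: int, lr0: float = 0.01) -> float:
    """Step decay from the initial rate: lr(ce) = lr0 * 0.5^floor(ce/2)."""
    if ce < 0:
        raise ValueError("central-epoch index must be >= 0")
    return lr0 * 0.5 ** (ce // 2)


class PlateauScheduler:
    """Multiply the rate by ``factor`` when the metric stalls for ``patience`` epochs.

    Called once per central epoch with the monitored validation loss;
    the patience counter resets after each reduction.
    """

    def __init__(self, lr0: float, factor: float = 0.3, patience: int = 5, min_delta: float = 0.0):
        if lr0 <= 0:
            raise ValueError("lr0 must be positive")
        self.lr = lr0
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self._best = np.inf
        self._bad = 0

    def update(self, metric: float) -> float:
        if metric < self._best - self.min_delta:
            self._best = metric
            self._bad = 0
        else:
            self._bad += 1
            if self._bad >= self.patience:
                self.lr *= self.factor
                self._bad = 0
        return self.lr


def partition_early_sharing(indices: Sequence[int], n_parts: int = 20, seed: int = 0) -> list[np.ndarray]:
    """Uniform random split of local indices into near-equal parts.

    A seeded shuffle followed by a contiguous split; part sizes differ
    by at most one (e.g. 19,617 items over 20 parts -> 17x981 + 3x980).
    The trainer then runs one local pass per part before sharing
    weights, which keeps the shared weight from drifting too far toward
    any single local shard (early sharing).
    """
    idx = np.asarray(indices)
    if idx.size < n_parts:
        raise ValueError(f"cannot split {idx.size} items into {n_parts} parts")
    rng = np.random.default_rng(seed)
    return list(np.array_split(rng.permutation(idx), n_parts))


def augment(
    image: np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_rotation_deg: float = 45.0,
    mean: np.ndarray | None = None,
    std: np.ndarray | None = None,
) -> np.ndarray:
    """Random horizontal flip, rotation up to ±45°, then normalization.

    The image is channel-first in [0, 1].  Normalization uses the
    ImageNet per-channel mean/std for 3-channel input unless custom
    constants are given; single-channel input defaults to mean 0.5,
    std 0.25.  Fully deterministic for a given seed.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3:
        raise ValueError(f"expected channel-first (C,H,W) image, got shape {img.shape}")
    c = img.shape[0]
    if mean is None:
        mean = IMAGENET_MEAN if c == 3 else np.full(c, 0.5, dtype=np.float32)
    if std is None:
        std = IMAGENET_STD if c == 3 else np.full(c, 0.25, dtype=np.float32)
    if rng is None:
        rng = np.random.default_rng(seed)
    if rng.random() < 0.5:
        img = img[:, :, ::-1]
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    if angle != 0.0:
        img = ndimage.rotate(img, angle, axes=(1, 2), reshape=False, order=1, mode="nearest")
    img = (img - np.asarray(mean, dtype=np.float32)[:, None, None]) / np.asarray(std, dtype=np.float32)[:, None, None]
    return img.astype(np.float32)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _xy(item) -> tuple[np.ndarray, object]:
    """Accept (x, y) pairs or the synthetic dataset record types."""
    if isinstance(item, tuple):
        return item
    if hasattr(item, "images"):
        return item.images, item.label
    if hasattr(item, "image"):
        return item.image, item.labels
    raise TypeError(f"unsupported data item type {type(item).__name__}")


def local_train(
    spec,
    bundle: WeightBundle,
    data: Sequence[tuple[np.ndarray, object]],
    epochs: int,
    opt,
    loss: str = "weighted_bce",
    weights: ClassWeights | None = None,
    rng: np.random.Generator | None = None,
    batch_size: int = 8,
) -> tuple[WeightBundle, list[float]]:
    """Run local epochs starting from the received weights W∘V.

    ``loss`` selects the objective and the data layout:

    - ``"weighted_bce"``: series exams ``(s,C,H,W)`` with binary labels,
      one optimizer step per exam (the slice axis is the batch);
    - ``"multilabel_bce"``: single images with multi-hot label vectors,
      minibatched at ``batch_size``;
    - ``"softmax"``: single images with integer class labels, run
      through the *full* base model (vertical pretraining of M).

    ``opt`` is a stateful optimizer (or an :class:`OptimizerConfig`,
    from which a fresh one is built); optimizer state persists across
    calls when the caller keeps the instance.  Returns the post-trained
    bundle and the per-epoch mean losses.  ``epochs=0`` returns the
    bundle unchanged.
    """
    if loss not in ("weighted_bce", "multilabel_bce", "softmax"):
        raise ValueError(f"unknown loss {loss!r}")
    if loss == "weighted_bce" and weights is None:
        weights = ClassWeights(w1=0.5, w0=0.5)
    if isinstance(opt, OptimizerConfig):
        opt = make_optimizer(opt)
    if rng is None:
        rng = np.random.default_rng(0)
    net = Network.from_bundle(spec, bundle)
    history: list[float] = []
    n = len(data)
    for _ in range(int(epochs)):
        order = rng.permutation(n)
        losses: list[float] = []
        if loss == "weighted_bce":
            for i in order:
                exam, y = _xy(data[i])
                logit = net.forward(np.asarray(exam))[0, 0]
                p = float(_clamp(_sigmoid(np.float64(logit))))
                losses.append(weighted_bce(p, y, weights))
                dlogit = np.float32(weights.w1 * y * (p - 1.0) + weights.w0 * (1 - y) * p)
                grads = net.backward(np.array([[dlogit]], dtype=np.float32))
                opt.step(net.params, grads)
        else:
            full_base = loss == "softmax"
            for start in range(0, n, batch_size):
                batch = order[start : start + batch_size]
                xs = np.stack([np.asarray(_xy(data[i])[0]) for i in batch])
                logits = net.forward(xs, full_base=full_base)
                if loss == "softmax":
                    ys = np.array([_xy(data[i])[1] for i in batch], dtype=np.int64)
                    l, dlogits = softmax_cross_entropy(logits, ys)
                else:
                    ys = np.stack([np.asarray(_xy(data[i])[1], dtype=np.float64) for i in batch])
                    p = _sigmoid(logits.astype(np.float64))
                    l = multilabel_bce(p, ys, n_labels=ys.shape[1])
                    dlogits = ((np.asarray(_clamp(p)) - ys) / len(batch)).astype(np.float32)
                losses.append(l)
                grads = net.backward(dlogits)
                opt.step(net.params, grads)
        history.append(float(np.mean(losses)) if losses else float("nan"))
    return net.to_bundle(), history


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equal scores across the class boundary count one half; requires
    both classes present.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
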