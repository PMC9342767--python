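"""Seeded generators for desk-scale datasets with the study's statistical skeleton.

These emulate the *structure* of the imaging data the system was built
for — variable-length exam series with imbalanced binary labels,
multi-label chest-film-like images, a small multi-class pretraining
corpus — without any photometric realism.  Images are smooth random
backgrounds plus noise; positive findings are planted Gaussian blobs
whose amplitude (``signal_strength``) controls task difficulty.  The
blob family is shared between the pretraining classes and the series
positives, so features learned in vertical pretraining genuinely
transfer downstream.

Everything is driven by an explicit seed: identical seeds produce
bit-identical datasets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SeriesExam",
    "MultiLabelImage",
    "gen_series_dataset",
    "gen_multilabel_dataset",
    "gen_pretrain_dataset",
    "inject_label_noise",
    "split_non_iid",
    "save_series_dataset",
]


@dataclass
class SeriesExam:
    """One exam: a stack of s slices (s, C, H, W) in [0,1] and a binary label."""

    images: np.ndarray
    label: int

    def __post_init__(self):
        if self.images.ndim != 4 or self.images.shape[0] < 1:
            raise ValueError("images must be (s, C, H, W) with s >= 1")


@dataclass
class MultiLabelImage:
    """One image (C, H, W) in [0,1] with a multi-hot label vector."""

    image: np.ndarray
    labels: np.ndarray


def _background(rng: np.random.Generator, c: int, h: int, w: int, noise_sd: float) -> np.ndarray:
    """Smooth anatomy-like background: a few broad Gaussians plus pixel noise."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    img = np.zeros((h, w), dtype=np.float32)
    for _ in range(3):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sig = rng.uniform(h / 4, h / 2)
        amp = rng.uniform(0.1, 0.3)
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    img = img + 0.2
    out = np.repeat(img[None], c, axis=0)
    out = out + rng.normal(0, noise_sd, size=(c, h, w)).astype(np.float32)
    return out


def _blob(rng: np.random.Generator, h: int, w: int, amplitude: float,
          center: tuple[float, float] | None = None, sigma: float | None = None) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    if center is None:
        center = (rng.uniform(h * 0.25, h * 0.75), rng.uniform(w * 0.25, w * 0.75))
    if sigma is None:
        sigma = rng.uniform(h / 12, h / 8)
    cy, cx = center
    return (amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))).astype(np.float32)


def gen_series_dataset(
    n_exams: int,
    pos_fraction: float = 208 / 1130,
    s_range: tuple[int, int] = (1, 3),
    image_size: int = 32,
    channels: int = 1,
    signal_strength: float = 0.6,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[SeriesExam]:
    """Imbalanced binary series exams with a planted blob in positives.

    Each exam holds ``s`` slices with ``s`` uniform in ``s_range``.
    Positive exams carry a bright Gaussian blob in at least one slice,
    ``signal_strength`` above the local background; negatives are
    background only.  Labels are i.i.d. Bernoulli(``pos_fraction``), so
    the positive count matches the target fraction in expectation —
    the default fraction mirrors a 208-positive / 1130-exam cohort.
    """
    if not 0 < pos_fraction < 1:
        raise ValueError("pos_fraction must lie in (0, 1)")
    if s_range[0] < 1 or s_range[1] < s_range[0]:
        raise ValueError("invalid s_range")
    if image_size < 8:
        raise ValueError("image_size too small")
    rng = np.random.default_rng(seed)
    h = w = image_size
    exams = []
    for _ in range(n_exams):
        label = int(rng.random() < pos_fraction)
        s = int(rng.integers(s_range[0], s_range[1] + 1))
        slices = np.stack([_background(rng, channels, h, w, noise_sd) for _ in range(s)])
        if label:
            n_hit = int(rng.integers(1, s + 1))
            hit = rng.choice(s, size=n_hit, replace=False)
            for si in hit:
                slices[si] += _blob(rng, h, w, signal_strength)[None]
        exams.append(SeriesExam(images=np.clip(slices, 0, 1), label=label))
    return exams


def _label_centers(n_labels: int, h: int, w: int) -> list[tuple[float, float]]:
    """A fixed grid of per-label blob locations (label identity = location)."""
    cols = int(np.ceil(np.sqrt(n_labels)))
    rows = int(np.ceil(n_labels / cols))
    centers = []
    for i in range(n_labels):
        r, c = divmod(i, cols)
        centers.append((h * (r + 1) / (rows + 1), w * (c + 1) / (cols + 1)))
    return centers


def gen_multilabel_dataset(
    n_images: int,
    n_labels: int = 14,
    prevalence=None,
    image_size: int = 32,
    channels: int = 1,
    signal_strength: float = 0.6,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[MultiLabelImage]:
    """Multi-label images: each label plants a blob at a label-specific site.

    Labels are sampled independently with the given prevalences (default
    0.1 each, roughly the sparsity of multi-label chest-film data), so
    co-occurrence arises naturally.
    """
    if prevalence is None:
        prevalence = np.full(n_labels, 0.1)
    prevalence = np.asarray(prevalence, dtype=float)
    if prevalence.shape != (n_labels,) or not np.all((0 < prevalence) & (prevalence < 1)):
        raise ValueError("prevalence must be n_labels values in (0,1)")
    rng = np.random.default_rng(seed)
    h = w = image_size
    centers = _label_centers(n_labels, h, w)
    sigma = h / 10
    out = []
    for _ in range(n_images):
        labels = (rng.random(n_labels) < prevalence).astype(np.int8)
        img = _background(rng, channels, h, w, noise_sd)
        for li in np.flatnonzero(labels):
            img += _blob(rng, h, w, signal_strength, center=centers[li], sigma=sigma)[None]
        out.append(MultiLabelImage(image=np.clip(img, 0, 1), labels=labels))
    return out


def gen_pretrain_dataset(
    n_images: int,
    n_classes: int = 10,
    image_size: int = 32,
    channels: int = 1,
    signal_strength: float = 0.6,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> list[tuple[np.ndarray, int]]:
    """Balanced multi-class surrogate for a large natural-image pretraining corpus.

    Class identity is a blob at a class-specific location, drawn from
    the same blob family as the downstream positives so that vertical
    pretraining learns transferable blob-detection features.  Class
    counts are balanced to within one image.
    """
    rng = np.random.default_rng(seed)
    h = w = image_size
    centers = _label_centers(n_classes, h, w)
    sigma = h / 10
    labels = np.array([i % n_classes for i in range(n_images)])
    labels = rng.permutation(labels)
    data = []
    for y in labels:
        img = _background(rng, channels, h, w, noise_sd)
        img += _blob(rng, h, w, signal_strength, center=centers[int(y)], sigma=sigma)[None]
        data.append((np.clip(img, 0, 1), int(y)))
    return data


def inject_label_noise(dataset, flip_rate: float, seed: int = 0):
    """Flip each binary label independently with probability ``flip_rate``.

    Models the ~10% label error rate of automatically text-mined
    labels.  Returns (noisy dataset, flip mask) so flips are auditable;
    applying the same mask twice restores the original labels.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    noisy = []
    mask = []
    for item in dataset:
        if isinstance(item, SeriesExam):
            flip = bool(rng.random() < flip_rate)
            noisy.append(SeriesExam(images=item.images, label=item.label ^ flip))
            mask.append(flip)
        elif isinstance(item, MultiLabelImage):
            flips = rng.random(item.labels.shape) < flip_rate
            noisy.append(MultiLabelImage(image=item.image, labels=item.labels ^ flips))
            mask.append(flips)
        else:
            x, y = item
            flip = bool(rng.random() < flip_rate)
            noisy.append((x, int(y) ^ flip))
            mask.append(flip)
    return noisy, np.asarray(mask)


def _item_class(item) -> int:
    if isinstance(item, SeriesExam):
        return item.label
    if isinstance(item, MultiLabelImage):
        nz = np.flatnonzero(item.labels)
        return int(nz[0]) + 1 if nz.size else 0
    return int(item[1])


def split_non_iid(dataset, n_trainers: int, skew: float = 1.0, seed: int = 0) -> list[np.ndarray]:
    """Label-skewed shards via per-class Dirichlet allocation.

    ``skew`` is the Dirichlet concentration: large values approach an
    i.i.d. split, small values concentrate each class on few trainers.
    Shards are disjoint and exhaustive.
    """
    if n_trainers < 2:
        raise ValueError("need at least 2 trainers")
    if len(dataset) < n_trainers:
        raise ValueError("more trainers than data items")
    rng = np.random.default_rng(seed)
    classes = np.array([_item_class(it) for it in dataset])
    shards: list[list[int]] = [[] for _ in range(n_trainers)]
    for c in np.unique(classes):
        idx = rng.permutation(np.flatnonzero(classes == c))
        props = rng.dirichlet(np.full(n_trainers, skew))
        cuts = (np.cumsum(props)[:-1] * idx.size).round().astype(int)
        for t, part in enumerate(np.split(idx, cuts)):
            shards[t].extend(part.tolist())
    return [np.sort(np.array(s, dtype=int)) for s in shards]


def save_series_dataset(exams: list[SeriesExam], out_dir: str | Path) -> Path:
    """Write a series dataset as PNG slices plus a CSV manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["exam_id", "slice_index", "path", "label"])
        for ei, exam in enumerate(exams):
            for si in range(exam.images.shape[0]):
                arr = (exam.images[si] * 255).clip(0, 255).astype(np.uint8)
                img = arr[0] if arr.shape[0] == 1 else arr.transpose(1, 2, 0)
                path = out / f"exam{ei:04d}_s{si}.png"
                Image.fromarray(img).save(path)
                wr.writerow([ei, si, path.name, exam.label])
    return manifest
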