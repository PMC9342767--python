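"""Vertical model composition: a shared base M extended by a task head Mi.

A :class:`ModelSpec` is an ordered layer table with an input shape.  A
base spec may designate a *feature cut*: layers before the cut form the
feature extractor that a composed head consumes, while layers after it
(e.g. a pretraining classifier) remain part of the stored weight vector
W but are bypassed in the composed forward pass.  This mirrors how a
backbone pretrained for classification is reused for a different task:
the classifier weights ride along in the checkpoint even though the
downstream model never evaluates them.

``compose(M, Mi)`` dimension-checks head input against the base feature
output; composing with a null head leaves the base model unchanged
(M composed with the empty modification is M itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crypto.bundle import WeightBundle
from .nn.layers import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    DenseBlock,
    Flatten,
    GlobalAvgPool,
    GlobalMaxPool,
    Linear,
    MaxPool2d,
    ReLU,
    SeriesMax,
    Sigmoid,
    Transition,
)

__all__ = [
    "ModelSpec",
    "ComposedModelSpec",
    "CompositionError",
    "compose",
    "count_trainable",
    "build_mri_model",
    "build_xray_model",
    "build_tiny_model",
    "split_base",
    "attach_head",
]


class CompositionError(ValueError):
    """Base and head shapes are incompatible."""


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer table; trainable parameter count derives from it alone."""

    layers: tuple
    input_dim: tuple
    feature_cut: int | None = None
    name: str = ""

    def __init__(self, layers, input_dim, feature_cut=None, name=""):
        object.__setattr__(self, "layers", tuple(layers))
        object.__setattr__(self, "input_dim", tuple(input_dim))
        object.__setattr__(self, "feature_cut", feature_cut)
        object.__setattr__(self, "name", name)
        self.shape_trace()  # validate layer compatibility eagerly

    def shape_trace(self) -> list[tuple]:
        """Per-layer output shapes, starting from input_dim."""
        trace = []
        shape = self.input_dim
        for layer in self.layers:
            shape = layer.out_shape(shape)
            trace.append(shape)
        return trace

    @property
    def output_dim(self) -> tuple:
        trace = self.shape_trace()
        return trace[-1] if trace else self.input_dim

    @property
    def feature_dim(self) -> tuple:
        """Shape consumed by a composed head (= output_dim when no cut)."""
        if self.feature_cut is None:
            return self.output_dim
        trace = self.shape_trace()
        return trace[self.feature_cut - 1] if self.feature_cut else self.input_dim

    def param_shapes(self) -> dict[str, tuple]:
        shapes: dict[str, tuple] = {}
        shape = self.input_dim
        for i, layer in enumerate(self.layers):
            kind = type(layer).__name__.lower()
            for pname, pshape in layer.param_shapes(shape).items():
                shapes[f"{i:03d}.{kind}.{pname}"] = pshape
            shape = layer.out_shape(shape)
        return shapes

    @property
    def n_trainable(self) -> int:
        return int(sum(int(np.prod(s)) for s in self.param_shapes().values()))


@dataclass(frozen=True)
class ComposedModelSpec:
    """Base M with head Mi; base feature output feeds the head input."""

    base: ModelSpec
    head: ModelSpec | None = None

    @property
    def input_dim(self) -> tuple:
        return self.base.input_dim

    @property
    def output_dim(self) -> tuple:
        return self.base.output_dim if self.head is None else self.head.output_dim

    @property
    def n_trainable(self) -> int:
        n = self.base.n_trainable
        if self.head is not None:
            n += self.head.n_trainable
        return n

    def param_shapes(self) -> dict[str, tuple]:
        shapes = {f"base/{k}": v for k, v in self.base.param_shapes().items()}
        if self.head is not None:
            shapes.update({f"head/{k}": v for k, v in self.head.param_shapes().items()})
        return shapes


def compose(base: ModelSpec, head: ModelSpec | None) -> ComposedModelSpec:
    """Compose base and head; a null head returns the base unchanged."""
    if head is not None and head.input_dim != base.feature_dim:
        raise CompositionError(
            f"head input {head.input_dim} does not match base feature output {base.feature_dim}"
        )
    return ComposedModelSpec(base=base, head=head)


def count_trainable(spec: ModelSpec | ComposedModelSpec) -> int:
    """Exact count of trainable scalars (weights and biases of retained layers)."""
    return spec.n_trainable


def build_mri_model() -> ComposedModelSpec:
    """Series-classification model: AlexNet backbone + GAP/series-max/linear head.

    The base is the standard 1000-class AlexNet.  Its classifier is
    retained in the weight vector (it is part of W as checkpointed)
    although the composed forward path stops at the 256x6x6 feature
    maps.  The head averages each slice's feature maps spatially,
    max-pools across the series axis, and maps 256 features to one
    logit: s x 3 x 224 x 224 -> s x 256 x 6 x 6 -> s x 256 -> 256 -> 1.
    """
    base = ModelSpec(
        layers=[
            Conv2d(3, 64, 11, stride=4, padding=2), ReLU(), MaxPool2d(3, 2),
            Conv2d(64, 192, 5, padding=2), ReLU(), MaxPool2d(3, 2),
            Conv2d(192, 384, 3, padding=1), ReLU(),
            Conv2d(384, 256, 3, padding=1), ReLU(),
            Conv2d(256, 256, 3, padding=1), ReLU(), MaxPool2d(3, 2),
            # classifier tail: stored in W, unused by the composed forward
            Flatten(), Linear(9216, 4096), ReLU(), Linear(4096, 4096), ReLU(),
            Linear(4096, 1000),
        ],
        input_dim=(3, 224, 224),
        feature_cut=13,
        name="alexnet",
    )
    head = ModelSpec(
        layers=[GlobalAvgPool(), SeriesMax(), Linear(256, 1)],
        input_dim=(256, 6, 6),
        name="series-head",
    )
    return compose(base, head)


def build_xray_model(n_labels: int = 14, input_hw: int = 224) -> ComposedModelSpec:
    """Multi-label model: DenseNet-121 backbone with a sigmoid head.

    Standard DenseNet-121 (init features 64, growth 32, blocks
    6/12/24/16, batch norm); the original 1024-to-1000 classifier is
    *replaced* by a 1024-to-``n_labels`` linear layer with sigmoid
    outputs, one probability per pathology.
    """
    layers = [
        Conv2d(3, 64, 7, stride=2, padding=3, bias=False),
        BatchNorm2d(64), ReLU(), MaxPool2d(3, 2, padding=1),
    ]
    ch = 64
    blocks = (6, 12, 24, 16)
    for bi, n_layers in enumerate(blocks):
        layers.append(DenseBlock(ch, n_layers))
        ch += 32 * n_layers
        if bi < len(blocks) - 1:
            layers.append(Transition(ch, ch // 2))
            ch //= 2
    layers += [BatchNorm2d(ch), ReLU(), GlobalAvgPool()]
    base = ModelSpec(layers=layers, input_dim=(3, input_hw, input_hw), name="densenet121")
    head = ModelSpec(
        layers=[Linear(1024, n_labels), Sigmoid()],
        input_dim=(1024,),
        name="sigmoid-head",
    )
    return compose(base, head)


def build_tiny_model(
    input_dim: tuple = (1, 32, 32),
    base_out: int = 16,
    head_out: int = 1,
    n_pretrain_classes: int = 10,
    series: bool = True,
) -> ComposedModelSpec:
    """Desk-scale two-conv backbone with a linear head; trains in seconds on CPU.

    The base ends (like the large backbones) with a pretraining
    classifier tail after the feature cut, so the full vertical-then-
    horizontal workflow — pretrain M, ship W, compose a head — runs
    identically at toy scale.  ``series=True`` gives the series head
    (global spatial max, max over slices, linear -> ``head_out``
    logits): focal findings must survive the spatial reduction, so the
    head max-pools rather than averages.  ``series=False`` gives a
    per-image head on the flattened coarse feature maps, keeping the
    spatial layout the multi-label task needs.
    """
    c = input_dim[0]
    base_layers = [
        Conv2d(c, 8, 3, padding=1), ReLU(), MaxPool2d(2, 2),
        Conv2d(8, base_out, 3, padding=1), ReLU(), MaxPool2d(2, 2),
    ]
    cut = len(base_layers)
    probe = ModelSpec(layers=base_layers, input_dim=input_dim)
    fc, fh, fw = probe.output_dim
    base = ModelSpec(
        layers=base_layers + [  # pretraining classifier tail
            Flatten(), Linear(fc * fh * fw, n_pretrain_classes),
        ],
        input_dim=input_dim,
        feature_cut=cut,
        name="tiny",
    )
    if series:
        head_layers = [GlobalMaxPool(), SeriesMax(), Linear(base_out, head_out)]
    else:
        head_layers = [Flatten(), Linear(fc * fh * fw, head_out)]
    head = ModelSpec(layers=head_layers, input_dim=(fc, fh, fw), name="tiny-head")
    return compose(base, head)


def split_base(bundle: WeightBundle) -> WeightBundle:
    """Extract the base namespace W from a composed bundle W∘V."""
    base = bundle.select("base/")
    if len(base) == 0:
        raise ValueError("bundle contains no base/ entries")
    return base


def attach_head(base_bundle: WeightBundle, head_spec: ModelSpec, init_seed: int) -> WeightBundle:
    """Return W∘V: the received base weights plus a freshly initialized head.

    Head initialization is deterministic in ``init_seed`` (He-uniform
    fan-in bounds for conv/linear weights, zeros for biases), so two
    trainers attaching with the same seed build identical heads.
    """
    from .nn.network import HEAD_INIT_GAIN, init_layer_params

    base = split_base(base_bundle)
    head_params = init_layer_params(head_spec, seed=init_seed, namespace="head", gain=HEAD_INIT_GAIN)
    return base.merge(WeightBundle(head_params))
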