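"""Parameter storage and forward/backward execution for model specs."""

from __future__ import annotations

import numpy as np

from ..crypto.bundle import WeightBundle
from .layers import BatchNorm2d, Conv2d, DenseBlock, Linear, Transition

__all__ = ["init_layer_params", "Network"]

_F32 = np.float32


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_F32)


def init_layer_params(spec, seed: int, namespace: str, gain: float = 1.0) -> dict[str, np.ndarray]:
    """He-uniform weights (times ``gain``), zero biases, unit BN scales; seeded.

    Parameters are generated in sorted-name order so the draw sequence
    (hence every value) is reproducible for a given seed.  ``gain``
    rescales the weight draws; the default full-scale He init is used
    throughout (it gives the base its strongest early gradient signal
    when a fresh head is attached).
    """
    rng = np.random.default_rng(seed)
    shapes = spec.param_shapes()
    params: dict[str, np.ndarray] = {}
    for local_name in sorted(shapes):
        shape = shapes[local_name]
        leaf = local_name.rsplit(".", 1)[-1]
        if leaf == "bias":
            arr = np.zeros(shape, dtype=_F32)
        elif "norm" in local_name or len(shape) == 1:
            # batch-norm scale (weight of a norm layer): start at identity
            arr = np.ones(shape, dtype=_F32)
        elif len(shape) == 4:  # conv weight
            fan_in = shape[1] * shape[2] * shape[3]
            arr = gain * _he_uniform(rng, shape, fan_in)
        else:  # linear weight
            arr = gain * _he_uniform(rng, shape, shape[1])
        params[f"{namespace}/{local_name}"] = arr
    return params


HEAD_INIT_GAIN = 1.0


class Network:
    """Executable model: a (composed) spec plus concrete parameter arrays.

    The forward path of a composed network runs the base feature layers
    per slice, then the head; base layers after the feature cut (a
    pretraining classifier tail) hold parameters that are stored and
    shipped but neither evaluated nor updated.  ``forward_full`` runs
    the *entire* base including the tail — that is the model M itself,
    used during vertical pretraining.
    """

    def __init__(self, spec, params: dict[str, np.ndarray]):
        self.spec = spec
        expected = spec.param_shapes()
        if set(params) != set(expected):
            missing = sorted(set(expected) - set(params))[:3]
            extra = sorted(set(params) - set(expected))[:3]
            raise ValueError(f"parameter mismatch: missing={missing} extra={extra}")
        for name, arr in params.items():
            if tuple(arr.shape) != tuple(expected[name]):
                raise ValueError(f"shape mismatch for {name}: {arr.shape} != {expected[name]}")
        self.params = {n: np.asarray(a, dtype=_F32) for n, a in params.items()}
        self._caches: list | None = None
        self._executed: list | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_seed(cls, spec, seed: int) -> "Network":
        params = init_layer_params(spec.base, seed, "base")
        if spec.head is not None:
            params.update(init_layer_params(spec.head, seed + 1, "head", gain=HEAD_INIT_GAIN))
        return cls(spec, params)

    @classmethod
    def from_bundle(cls, spec, bundle: WeightBundle) -> "Network":
        return cls(spec, dict(bundle.entries))

    def to_bundle(self) -> WeightBundle:
        return WeightBundle(dict(self.params))

    def load_bundle(self, bundle: WeightBundle) -> None:
        fresh = Network(self.spec, dict(bundle.entries))
        self.params = fresh.params

    # -- execution ---------------------------------------------------------

    def _layer_params(self, ns: str, idx: int, layer) -> dict[str, np.ndarray]:
        kind = type(layer).__name__.lower()
        prefix = f"{ns}/{idx:03d}.{kind}."
        return {n[len(prefix):]: a for n, a in self.params.items() if n.startswith(prefix)}

    def _plan(self, full_base: bool) -> list[tuple[str, int, object]]:
        base = self.spec.base
        if full_base or self.spec.head is None:
            return [("base", i, l) for i, l in enumerate(base.layers)]
        cut = base.feature_cut if base.feature_cut is not None else len(base.layers)
        plan = [("base", i, l) for i, l in enumerate(base.layers[:cut])]
        plan += [("head", i, l) for i, l in enumerate(self.spec.head.layers)]
        return plan

    def forward(self, x: np.ndarray, full_base: bool = False) -> np.ndarray:
        """Run the composed forward pass (or the full base when asked).

        ``x`` is (N, C, H, W); N is the slice axis for series models.
        Caches are retained for a subsequent :meth:`backward`.
        """
        x = np.asarray(x, dtype=_F32)
        plan = self._plan(full_base)
        caches = []
        for ns, idx, layer in plan:
            p = self._layer_params(ns, idx, layer)
            x, cache = layer.forward(x, p)
            caches.append((ns, idx, layer, p, cache))
        self._caches = caches
        return x

    def backward(self, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate the loss gradient through the last forward pass."""
        if self._caches is None:
            raise RuntimeError("backward called before forward")
        grads: dict[str, np.ndarray] = {}
        dy = np.asarray(dy, dtype=_F32)
        for ns, idx, layer, p, cache in reversed(self._caches):
            dy, layer_grads = layer.backward(dy, cache, p)
            kind = type(layer).__name__.lower()
            for pname, g in layer_grads.items():
                grads[f"{ns}/{idx:03d}.{kind}.{pname}"] = g
        self._caches = None
        return grads

    @property
    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.params.values()))
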