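"""SGD and Adam updates over named parameter dictionaries.

Only parameters that received a gradient are updated — a frozen
classifier tail riding along in the weight vector is left untouched,
including by weight decay.  Weight decay is the classical L2 form
(added to the gradient before the update), matching the convention of
mainstream deep-learning optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OptimizerConfig", "SGD", "Adam", "make_optimizer"]

_F32 = np.float32


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters for a local-training optimizer."""

    kind: str = "adam"  # adam | amsgrad | sgd
    lr: float = 1e-3
    weight_decay: float = 0.0
    momentum: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.kind not in ("adam", "amsgrad", "sgd"):
            raise ValueError(f"unknown optimizer kind {self.kind!r}")


class SGD:
    def __init__(self, cfg: OptimizerConfig):
        self.cfg = cfg
        self.lr = cfg.lr
        self._velocity: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        for name, g in grads.items():
            g = g + c.weight_decay * params[name] if c.weight_decay else g
            if c.momentum:
                v = self._velocity.get(name)
                v = c.momentum * v + g if v is not None else g.copy()
                self._velocity[name] = v
                g = v
            params[name] = (params[name] - self.lr * g).astype(_F32)


class Adam:
    def __init__(self, cfg: OptimizerConfig):
        self.cfg = cfg
        self.lr = cfg.lr
        self.amsgrad = cfg.kind == "amsgrad"
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._vmax: dict[str, np.ndarray] = {}
        self._t: dict[str, int] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        for name, g in grads.items():
            g = g + c.weight_decay * params[name] if c.weight_decay else g
            t = self._t.get(name, 0) + 1
            self._t[name] = t
            m = self._m.get(name, np.zeros_like(g))
            v = self._v.get(name, np.zeros_like(g))
            m = c.beta1 * m + (1 - c.beta1) * g
            v = c.beta2 * v + (1 - c.beta2) * g * g
            self._m[name], self._v[name] = m, v
            mhat = m / (1 - c.beta1**t)
            if self.amsgrad:
                vmax = np.maximum(self._vmax.get(name, v), v)
                self._vmax[name] = vmax
                vhat = vmax / (1 - c.beta2**t)
            else:
                vhat = v / (1 - c.beta2**t)
            params[name] = (params[name] - self.lr * mhat / (np.sqrt(vhat) + c.eps)).astype(_F32)


def make_optimizer(cfg: OptimizerConfig):
    return SGD(cfg) if cfg.kind == "sgd" else Adam(cfg)
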