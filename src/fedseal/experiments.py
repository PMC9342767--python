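"""Config-driven experiment runs: end-to-end simulation, attack demos, noise study.

Every run is pure in (config, seed): reruns produce identical
transcripts and reports.  A report carries the exact configuration it
was produced from, the transcript, per-round metrics, detection
events, and communication totals — everything in it is recomputable
from config + transcript.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compose import ComposedModelSpec, attach_head, build_tiny_model, compose
from .crypto.bundle import WeightBundle
from .crypto.codec import kgen
from .nn.network import Network
from .nn.optim import OptimizerConfig
from .protocol import (
    ServerState,
    Trainer,
    Transcript,
    account_communication,
    make_schedule,
    run_protocol,
)
from .synthetic import gen_pretrain_dataset, gen_series_dataset, inject_label_noise
from .training import ClassWeights, auc, class_weights

__all__ = ["E2EConfig", "RunReport", "run_e2e", "noisy_label_study", "evaluate_bundle"]


@dataclass(frozen=True)
class E2EConfig:
    """Desk-scale vertical-then-horizontal run configuration."""

    seed: int = 0
    n_horizontal: int = 2
    central_epochs: int = 4
    image_size: int = 32
    base_out: int = 16
    n_pretrain: int = 200
    n_pretrain_classes: int = 10
    n_exams_per_trainer: int = 100
    n_heldout: int = 100
    pos_fraction: float = 0.3
    signal_strength: float = 0.8
    s_range: tuple[int, int] = (1, 3)
    lr: float = 2e-3
    optimizer: str = "adam"
    server_mode: str = "honest"
    tamper_at_fetch: int | None = None
    label_flip_rate: float = 0.0
    vertical_pretraining: bool = True
    vertical_epochs: int = 3
    replay_protection: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    config: dict
    final_auc: float | None
    per_round_auc: list[float]
    per_round_loss: list[float]
    detection_events: list[dict]
    communication: dict
    n_parameters: int
    upload_hashes: list[str]
    completed: bool

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_bundle(
    spec: ComposedModelSpec,
    bundle: WeightBundle,
    exams,
    head_seed: int = 0,
) -> float:
    """Held-out AUC of a bundle under the composed spec.

    A base-only bundle (as uploaded by the vertical trainer) gets a
    fresh seeded head attached first, mirroring what a receiving
    horizontal trainer would do.
    """
    if spec.head is not None and not bundle.select("head/"):
        bundle = attach_head(bundle, spec.head, init_seed=head_seed)
    net = Network.from_bundle(spec, bundle)
    scores = [float(net.forward(e.images)[0, 0]) for e in exams]
    return auc(scores, [e.label for e in exams])


def _build_world(cfg: E2EConfig):
    """Datasets, specs, trainers, and evaluator for a config; all seeded."""
    rng_base = cfg.seed
    key = kgen()
    spec_series = build_tiny_model(
        input_dim=(1, cfg.image_size, cfg.image_size),
        base_out=cfg.base_out,
        head_out=1,
        n_pretrain_classes=cfg.n_pretrain_classes,
        series=True,
    )
    spec_vert = compose(spec_series.base, None)

    gen_kw = dict(
        pos_fraction=cfg.pos_fraction,
        s_range=cfg.s_range,
        image_size=cfg.image_size,
        signal_strength=cfg.signal_strength,
    )
    local = [
        gen_series_dataset(cfg.n_exams_per_trainer, seed=rng_base * 1000 + 21 + i, **gen_kw)
        for i in range(cfg.n_horizontal)
    ]
    held = gen_series_dataset(cfg.n_heldout, seed=rng_base * 1000 + 20, **gen_kw)
    if cfg.label_flip_rate > 0:
        local = [
            inject_label_noise(d, cfg.label_flip_rate, seed=rng_base * 1000 + 71 + i)[0]
            for i, d in enumerate(local)
        ]

    # pooled prevalence over the horizontal trainers' (noisy) label counts
    pos = [sum(e.label for e in d) for d in local]
    tot = [len(d) for d in local]
    weights = class_weights(pos, tot) if 0 < sum(pos) < sum(tot) else ClassWeights(0.5, 0.5)

    opt = OptimizerConfig(kind=cfg.optimizer, lr=cfg.lr)
    trainers: dict[int, Trainer] = {}
    if cfg.vertical_pretraining:
        pre = gen_pretrain_dataset(
            cfg.n_pretrain, n_classes=cfg.n_pretrain_classes,
            image_size=cfg.image_size, signal_strength=cfg.signal_strength,
            seed=rng_base * 1000 + 11,
        )
        trainers[0] = Trainer(0, key, spec_vert, pre, opt, loss="softmax", seed=rng_base * 1000 + 100)
    for i in range(cfg.n_horizontal):
        trainers[i + 1] = Trainer(
            i + 1, key, spec_series, local[i], opt,
            loss="weighted_bce", weights=weights, seed=rng_base * 1000 + 101 + i,
        )

    def eval_fn(bundle: WeightBundle) -> float:
        return evaluate_bundle(spec_series, bundle, held, head_seed=rng_base * 1000 + 101)

    return key, spec_series, trainers, eval_fn


def run_e2e(cfg: E2EConfig) -> tuple[RunReport, Transcript]:
    """Generate data, run the protocol, evaluate per round, build the report."""
    _, spec_series, trainers, eval_fn = _build_world(cfg)
    schedule = make_schedule(cfg.n_horizontal, cfg.central_epochs, seed=cfg.seed * 1000 + 7)
    server = ServerState(
        mode=cfg.server_mode, seed=cfg.seed * 1000 + 5, tamper_at_fetch=cfg.tamper_at_fetch
    )
    transcript, final = run_protocol(
        trainers, server, schedule,
        replay_protection=cfg.replay_protection, eval_fn=eval_fn,
        vertical_epochs=cfg.vertical_epochs,
    )
    aucs = [e.auc for e in transcript.events if e.auc is not None]
    losses = [e.loss for e in transcript.events if e.loss is not None]
    detections = [
        {"round": e.round, "trainer": e.trainer_id, "cause": e.cause}
        for e in transcript.detection_events
    ]
    report = RunReport(
        config=cfg.to_dict(),
        final_auc=aucs[-1] if aucs else None,
        per_round_auc=[float(a) for a in aucs],
        per_round_loss=[float(l) for l in losses],
        detection_events=detections,
        communication=account_communication(transcript),
        n_parameters=spec_series.n_trainable,
        upload_hashes=transcript.upload_hashes,
        completed=not detections,
    )
    return report, transcript


def noisy_label_study(cfg: E2EConfig) -> dict:
    """Paired runs on noisy labels: with vs without vertical pretraining.

    Both arms share datasets, schedule, and seeds; only the presence of
    the clean-label vertical phase differs.  Reports both final AUCs
    and their difference (positive = pretraining helped).
    """
    with_pre = dataclasses.replace(cfg, vertical_pretraining=True)
    without_pre = dataclasses.replace(cfg, vertical_pretraining=False)
    rep_with, _ = run_e2e(with_pre)
    rep_without, _ = run_e2e(without_pre)
    return {
        "flip_rate": cfg.label_flip_rate,
        "auc_with_pretraining": rep_with.final_auc,
        "auc_without_pretraining": rep_without.final_auc,
        "auc_difference": (rep_with.final_auc or 0) - (rep_without.final_auc or 0),
        "config": cfg.to_dict(),
    }
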