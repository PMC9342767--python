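"""The collaborative-training protocol around an untrusted parameter server.

One shared authenticated-encryption key is held by all trainers; the
server only ever stores and returns opaque ciphertexts.  A round is:
fetch E from the server, verify-and-decrypt, train locally for at most
two local epochs, re-encrypt, upload.  Any server-side modification of
E fails tag verification at the next trainer and surfaces as a
:class:`DetectionEvent`; the run then halts (fail closed) — no weight
derived from an unverified ciphertext ever touches trainer state.

Replay is the one manipulation the MAC cannot see (a replayed
ciphertext is authentic), so each plaintext is framed with a monotone
upload counter that receiving trainers check for staleness.  This is a
documented extension with an off switch (``replay_protection=False``).

The server can also be instantiated in one of several malicious modes
(bit flips, the CBC IV-XOR attack, replay, drop) to exercise the
detection machinery.
"""

from __future__ import annotations

import csv
import hashlib
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .compose import ComposedModelSpec, attach_head
from .crypto.bundle import (
    FormatError,
    WeightBundle,
    deserialize_weights,
    serialize_weights,
    write_ciphertext,
)
from .crypto.codec import (
    AuthCiphertext,
    IntegrityError,
    SymmetricKeyPair,
    aead_decrypt,
    aead_encrypt,
    cbc_iv_flip_attack,
)
from .nn.network import Network
from .nn.optim import OptimizerConfig, make_optimizer
from .training import ClassWeights, local_train

__all__ = [
    "ServerState",
    "Schedule",
    "Transcript",
    "TranscriptEvent",
    "DetectionEvent",
    "Trainer",
    "server_store",
    "server_fetch",
    "make_schedule",
    "group_runs",
    "trainer_round",
    "run_protocol",
    "run_direct",
    "account_communication",
    "pack_payload",
    "unpack_payload",
]

SERVER_MODES = ("honest", "tamper_bitflip", "tamper_iv_xor", "replay", "drop")


# --------------------------------------------------------------------------
# payload framing: monotone upload counter || serialized bundle
# --------------------------------------------------------------------------

def pack_payload(counter: int, bundle: WeightBundle) -> bytes:
    return struct.pack("<Q", counter) + serialize_weights(bundle)


def unpack_payload(data: bytes) -> tuple[int, WeightBundle]:
    if len(data) < 8:
        raise FormatError("payload shorter than its counter header")
    (counter,) = struct.unpack("<Q", data[:8])
    return counter, deserialize_weights(data[8:])


# --------------------------------------------------------------------------
# server
# --------------------------------------------------------------------------

@dataclass
class ServerState:
    """The parameter server: a ciphertext store with a behaviour mode.

    The server never holds a key.  ``tamper_at_fetch`` delays the
    malicious behaviour until the given fetch index (counting from 0);
    ``None`` misbehaves at every opportunity.
    """

    mode: str = "honest"
    seed: int = 0
    tamper_at_fetch: int | None = None
    stored: AuthCiphertext | None = None
    replay_cache: list[AuthCiphertext] = field(default_factory=list)
    fetch_count: int = 0

    def __post_init__(self):
        if self.mode not in SERVER_MODES:
            raise ValueError(f"unknown server mode {self.mode!r}")
        self._rng = np.random.default_rng(self.seed)


def server_store(state: ServerState, ct: AuthCiphertext) -> ServerState:
    state.stored = ct
    state.replay_cache.append(ct)
    return state


def _flip_bit(data: bytes, bit_index: int) -> bytes:
    b = bytearray(data)
    b[bit_index // 8] ^= 1 << (bit_index % 8)
    return bytes(b)


def server_fetch(state: ServerState) -> AuthCiphertext | None:
    """Return the stored ciphertext, honestly or after the mode's manipulation."""
    idx = state.fetch_count
    state.fetch_count += 1
    ct = state.stored
    active = state.mode != "honest" and (
        state.tamper_at_fetch is None or idx == state.tamper_at_fetch
    )
    if ct is None or not active:
        return ct
    if state.mode == "drop":
        return None
    if state.mode == "replay":
        return state.replay_cache[0]
    if state.mode == "tamper_iv_xor":
        r = state._rng.integers(0, 256, size=16, dtype=np.uint8).tobytes()
        iv, body = cbc_iv_flip_attack(ct.iv, ct.body, r)
        return AuthCiphertext(iv=iv, body=body, tag=ct.tag)
    # tamper_bitflip: one random bit anywhere in iv || body || tag
    raw = ct.iv + ct.body + ct.tag
    bit = int(state._rng.integers(0, len(raw) * 8))
    raw = _flip_bit(raw, bit)
    return AuthCiphertext(iv=raw[:16], body=raw[16:-64], tag=raw[-64:])


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Schedule:
    """Order of trainer turns; grouped runs are capped at max_run local epochs."""

    order: tuple[int, ...]
    max_run: int = 2

    def counts(self) -> dict[int, int]:
        ids, cnt = np.unique(np.array(self.order), return_counts=True)
        return dict(zip(ids.tolist(), cnt.tolist()))

    def is_valid(self, central_epochs: int) -> bool:
        counts = self.counts()
        if any(c != central_epochs for c in counts.values()):
            return False
        if len(counts) > 1:
            run = 0
            prev = None
            for tid in self.order:
                run = run + 1 if tid == prev else 1
                prev = tid
                if run > self.max_run:
                    return False
        return True


def make_schedule(n_trainers: int, central_epochs: int, max_run: int = 2, seed: int = 0) -> Schedule:
    """Random turn order: each trainer appears exactly ``central_epochs`` times,
    never more than ``max_run`` times consecutively; deterministic in ``seed``.

    Construction is greedy with a feasibility guard: a candidate next
    trainer is admissible only if, afterwards, every trainer j still
    fits its remaining turns into the gaps left by the others
    (rem[j] <= max_run * (others + 1), adjusted for the current run).
    """
    if n_trainers < 1 or central_epochs < 1:
        raise ValueError("n_trainers and central_epochs must be >= 1")
    ids = list(range(1, n_trainers + 1))
    if n_trainers == 1:
        return Schedule(order=tuple([ids[0]] * central_epochs), max_run=max_run)
    rng = np.random.default_rng(seed)
    rem = {t: central_epochs for t in ids}
    order: list[int] = []
    last, run = None, 0

    def feasible(rem, last, run) -> bool:
        total = sum(rem.values())
        for j, rj in rem.items():
            if rj == 0:
                continue
            others = total - rj
            cap = max_run * (others + 1)
            if j == last:
                cap -= run
            if rj > cap:
                return False
        return True

    for _ in range(n_trainers * central_epochs):
        cands = [
            t for t in ids
            if rem[t] > 0 and not (t == last and run >= max_run)
        ]
        ok = []
        for t in cands:
            rem[t] -= 1
            nlast, nrun = t, (run + 1 if t == last else 1)
            if feasible(rem, nlast, nrun):
                ok.append(t)
            rem[t] += 1
        if not ok:
            raise RuntimeError("schedule construction dead-ended (infeasible constraints)")
        t = ok[int(rng.integers(0, len(ok)))]
        rem[t] -= 1
        run = run + 1 if t == last else 1
        last = t
        order.append(t)
    sched = Schedule(order=tuple(order), max_run=max_run)
    assert sched.is_valid(central_epochs)
    return sched


def group_runs(schedule: Schedule) -> list[tuple[int, int]]:
    """Run-length encode the order, capping runs at ``max_run``.

    Each group becomes one trainer round with local_epochs = run length
    (a lone turn is 1 local epoch; a doubled turn is 2).
    """
    groups: list[tuple[int, int]] = []
    for tid in schedule.order:
        if groups and groups[-1][0] == tid and groups[-1][1] < schedule.max_run:
            groups[-1] = (tid, groups[-1][1] + 1)
        else:
            groups.append((tid, 1))
    return groups


# --------------------------------------------------------------------------
# transcript
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptEvent:
    round: int
    direction: str  # "up" | "down"
    trainer_id: int
    nbytes: int
    integrity_ok: bool
    local_epochs: int = 0
    loss: float | None = None
    auc: float | None = None
    payload_sha256: str | None = None
    cause: str | None = None


@dataclass
class Transcript:
    """Append-only ordered log of protocol messages and integrity events."""

    events: list[TranscriptEvent] = field(default_factory=list)

    def append(self, event: TranscriptEvent) -> None:
        self.events.append(event)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def detection_events(self) -> list[TranscriptEvent]:
        return [e for e in self.events if not e.integrity_ok]

    @property
    def upload_hashes(self) -> list[str]:
        return [e.payload_sha256 for e in self.events if e.direction == "up" and e.payload_sha256]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["round", "trainer", "direction", "bytes", "integrity_ok",
                         "local_epochs", "loss", "auc", "cause"])
            for e in self.events:
                wr.writerow([e.round, e.trainer_id, e.direction, e.nbytes,
                             int(e.integrity_ok), e.local_epochs,
                             "" if e.loss is None else f"{e.loss:.6f}",
                             "" if e.auc is None else f"{e.auc:.4f}",
                             e.cause or ""])


@dataclass(frozen=True)
class DetectionEvent:
    """A trainer rejected the served ciphertext: tampering or staleness."""

    trainer_id: int
    round: int
    cause: str  # "tag_mismatch" | "format_error" | "stale_round"


# --------------------------------------------------------------------------
# trainers
# --------------------------------------------------------------------------

class Trainer:
    """One participant: key, composed model, local data, stateful optimizer."""

    def __init__(
        self,
        trainer_id: int,
        key: SymmetricKeyPair,
        spec: ComposedModelSpec,
        data,
        opt: OptimizerConfig,
        loss: str = "weighted_bce",
        weights: ClassWeights | None = None,
        seed: int = 0,
        batch_size: int = 8,
    ):
        self.id = trainer_id
        self.key = key
        self.spec = spec
        self.data = data
        self.opt = make_optimizer(opt)
        self.loss = loss
        self.weights = weights
        self.seed = seed
        self.batch_size = batch_size
        self.bundle: WeightBundle | None = None
        self.last_counter = -1
        self.last_losses: list[float] = []

    def init_bundle(self) -> WeightBundle:
        return Network.from_seed(self.spec, self.seed).to_bundle()


def trainer_round(
    trainer: Trainer,
    payload: AuthCiphertext | None,
    local_epochs: int,
    round_index: int,
    replay_protection: bool = True,
) -> AuthCiphertext | DetectionEvent:
    """One full trainer turn: obtain weights, train locally, re-encrypt.

    With payload ⊥ the trainer initializes weights itself; otherwise the
    ciphertext is verified and decrypted, a fresh head is attached the
    first time a base-only bundle arrives, and staleness is checked.
    On any integrity failure the round aborts before any training
    (fail closed) and a :class:`DetectionEvent` is returned.
    """
    if payload is None:
        bundle = trainer.init_bundle()
    else:
        try:
            plain = aead_decrypt(trainer.key, payload)
        except IntegrityError:
            return DetectionEvent(trainer_id=trainer.id, round=round_index, cause="tag_mismatch")
        try:
            counter, bundle = unpack_payload(plain)
        except FormatError:
            return DetectionEvent(trainer_id=trainer.id, round=round_index, cause="format_error")
        if replay_protection and counter <= trainer.last_counter:
            return DetectionEvent(trainer_id=trainer.id, round=round_index, cause="stale_round")
        trainer.last_counter = counter
        if trainer.spec.head is not None and not bundle.select("head/"):
            bundle = attach_head(bundle, trainer.spec.head, init_seed=trainer.seed)
    rng = np.random.default_rng([trainer.seed, round_index])
    bundle, losses = local_train(
        trainer.spec, bundle, trainer.data, local_epochs, trainer.opt,
        loss=trainer.loss, weights=trainer.weights, rng=rng,
        batch_size=trainer.batch_size,
    )
    trainer.bundle = bundle
    trainer.last_losses = losses
    return aead_encrypt(trainer.key, pack_payload(round_index, bundle))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def _sha(bundle: WeightBundle) -> str:
    return hashlib.sha256(serialize_weights(bundle)).hexdigest()


def run_protocol(
    trainers: dict[int, Trainer],
    server: ServerState,
    schedule: Schedule,
    replay_protection: bool = True,
    eval_fn=None,
    vertical_epochs: int = 1,
) -> tuple[Transcript, WeightBundle | None]:
    """Vertical-then-horizontal training through the parameter server.

    If trainer 0 exists and is absent from the schedule it is the
    vertical trainer and runs first (its initial fetch returns ⊥); its
    one-off pretraining pass may run ``vertical_epochs`` local epochs —
    the at-most-two rule governs the shared horizontal schedule, not
    the pretraining phase that precedes any sharing.  Each schedule
    group then performs one fetch + one trainer round + one upload.
    On a DetectionEvent the run halts with the event logged; the last
    *verified* bundle is returned.

    ``eval_fn(bundle) -> float`` is an optional held-out metric logged
    with each upload.
    """
    transcript = Transcript()
    last_bundle: WeightBundle | None = None
    turn = 0

    vertical = 0 in trainers and 0 not in schedule.order
    turns: list[tuple[int, int]] = ([(0, vertical_epochs)] if vertical else []) + group_runs(schedule)

    for tid, run_len in turns:
        trainer = trainers[tid]
        served = server_fetch(server)
        transcript.append(TranscriptEvent(
            round=turn, direction="down", trainer_id=tid,
            nbytes=0 if served is None else len(write_ciphertext(served)),
            integrity_ok=True,
        ))
        result = trainer_round(trainer, served, run_len, turn, replay_protection)
        if isinstance(result, DetectionEvent):
            transcript.append(TranscriptEvent(
                round=turn, direction="up", trainer_id=tid, nbytes=0,
                integrity_ok=False, cause=result.cause,
            ))
            return transcript, last_bundle
        server_store(server, result)
        last_bundle = trainer.bundle
        transcript.append(TranscriptEvent(
            round=turn, direction="up", trainer_id=tid,
            nbytes=len(write_ciphertext(result)), integrity_ok=True,
            local_epochs=run_len,
            loss=trainer.last_losses[-1] if trainer.last_losses else None,
            auc=eval_fn(last_bundle) if eval_fn else None,
            payload_sha256=_sha(last_bundle),
        ))
        turn += 1
    return transcript, last_bundle


def run_direct(
    trainers: dict[int, Trainer],
    schedule: Schedule,
    vertical_epochs: int = 1,
) -> list[WeightBundle]:
    """Serverless hand-off baseline: the same rounds, bundles passed by hand.

    With an honest server and identical seeds, :func:`run_protocol`'s
    upload sequence is bit-identical to this one — the encrypted
    channel is transparent.
    """
    bundles: list[WeightBundle] = []
    prev: WeightBundle | None = None
    turn = 0
    vertical = 0 in trainers and 0 not in schedule.order
    turns = ([(0, vertical_epochs)] if vertical else []) + group_runs(schedule)
    for tid, run_len in turns:
        trainer = trainers[tid]
        if prev is None:
            bundle = trainer.init_bundle()
        else:
            bundle = prev
            if trainer.spec.head is not None and not bundle.select("head/"):
                bundle = attach_head(bundle, trainer.spec.head, init_seed=trainer.seed)
        rng = np.random.default_rng([trainer.seed, turn])
        bundle, _ = local_train(
            trainer.spec, bundle, trainer.data, run_len, trainer.opt,
            loss=trainer.loss, weights=trainer.weights, rng=rng,
            batch_size=trainer.batch_size,
        )
        trainer.bundle = bundle
        prev = bundle
        bundles.append(bundle)
        turn += 1
    return bundles


def account_communication(
    transcript: Transcript,
    per_message_bytes: int | None = None,
) -> dict[int, dict[str, int]]:
    """Per-trainer upload/download byte totals.

    With ``per_message_bytes`` set, every logged message is costed at
    that size instead of its actual encoded length — useful for
    projecting full-scale traffic (e.g. 234 MB weight bundles over
    20 central epochs: 234 MB x 20 x 2 = 9.36 GB per trainer).
    """
    totals: dict[int, dict[str, int]] = {}
    for e in transcript.events:
        if not e.integrity_ok:
            continue
        if e.nbytes == 0:  # ⊥ fetches carry no payload in either costing
            continue
        slot = totals.setdefault(e.trainer_id, {"up": 0, "down": 0})
        size = per_message_bytes if per_message_bytes is not None else e.nbytes
        slot[e.direction] += size
    return totals
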