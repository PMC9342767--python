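"""Server behaviour, schedules, trainer rounds, detection, transcripts."""

import numpy as np
import pytest

from fedseal.compose import build_tiny_model, compose
from fedseal.crypto.bundle import serialize_weights, write_ciphertext
from fedseal.crypto.codec import aead_encrypt, kgen
from fedseal.nn.network import Network
from fedseal.nn.optim import OptimizerConfig
from fedseal.protocol import (
    DetectionEvent,
    Schedule,
    ServerState,
    Trainer,
    Transcript,
    TranscriptEvent,
    account_communication,
    group_runs,
    make_schedule,
    pack_payload,
    run_direct,
    run_protocol,
    server_fetch,
    server_store,
    trainer_round,
    unpack_payload,
)
from fedseal.synthetic import gen_pretrain_dataset, gen_series_dataset
from fedseal.training import ClassWeights

# the published 40-turn example order for two trainers over 20 central epochs
PRINTED_ORDER = (1, 2, 2, 1, 1, 2, 1, 2, 2, 1, 1, 2, 1, 2, 1, 2, 2, 1, 1, 2,
                 1, 2, 1, 2, 1, 2, 2, 1, 2, 1, 1, 2, 1, 2, 2, 1, 2, 1, 1, 2)


@pytest.fixture()
def tiny_world(key):
    spec = build_tiny_model(input_dim=(1, 16, 16), base_out=8, head_out=1)
    vert = compose(spec.base, None)
    w = ClassWeights(0.3, 0.7)
    opt = OptimizerConfig(kind="adam", lr=2e-3)

    def make_trainers():
        pre = gen_pretrain_dataset(40, n_classes=10, image_size=16, seed=11)
        d1 = gen_series_dataset(24, pos_fraction=0.3, image_size=16, seed=21)
        d2 = gen_series_dataset(24, pos_fraction=0.3, image_size=16, seed=22)
        return {
            0: Trainer(0, key, vert, pre, opt, loss="softmax", seed=100),
            1: Trainer(1, key, spec, d1, opt, weights=w, seed=101),
            2: Trainer(2, key, spec, d2, opt, weights=w, seed=102),
        }

    return spec, vert, make_trainers


class TestServer:
    def test_store_then_honest_fetch_identity(self, key):
        ct = aead_encrypt(key, b"payload-bytes")
        srv = ServerState(mode="honest")
        server_store(srv, ct)
        assert server_fetch(srv) == ct

    def test_fetch_before_store_is_bottom(self):
        assert server_fetch(ServerState()) is None

    def test_last_writer_wins(self, key):
        srv = ServerState()
        a, b = aead_encrypt(key, b"one"), aead_encrypt(key, b"two")
        server_store(srv, a)
        server_store(srv, b)
        assert server_fetch(srv) == b

    def test_server_never_sees_keys(self, key):
        """The server state holds ciphertext only — no key material."""
        srv = ServerState()
        server_store(srv, aead_encrypt(key, b"x"))
        assert not any(
            hasattr(srv, attr) for attr in ("key", "enc_key", "mac_key")
        )

    @pytest.mark.parametrize("mode", ["tamper_bitflip", "tamper_iv_xor"])
    def test_tampered_fetch_differs_from_stored(self, key, mode):
        srv = ServerState(mode=mode, seed=3)
        ct = aead_encrypt(key, b"weights" * 10)
        server_store(srv, ct)
        assert server_fetch(srv) != ct

    def test_drop_mode_returns_bottom(self, key):
        srv = ServerState(mode="drop")
        server_store(srv, aead_encrypt(key, b"x"))
        assert server_fetch(srv) is None

    def test_replay_returns_oldest(self, key):
        srv = ServerState(mode="replay")
        a, b = aead_encrypt(key, b"old"), aead_encrypt(key, b"new")
        server_store(srv, a)
        server_store(srv, b)
        assert server_fetch(srv) == a


class TestSchedule:
    def test_printed_order_is_valid(self):
        sched = Schedule(order=PRINTED_ORDER)
        assert sched.counts() == {1: 20, 2: 20}
        assert sched.is_valid(central_epochs=20)

    def test_printed_order_grouping_prefix(self):
        """(1,2,2,1,1,2,...) groups as (1,1),(2,2),(1,2),(2,1),..."""
        groups = group_runs(Schedule(order=(1, 2, 2, 1, 1, 2)))
        assert groups == [(1, 1), (2, 2), (1, 2), (2, 1)]

    def test_alternating_order_all_singletons(self):
        groups = group_runs(Schedule(order=(1, 2) * 5))
        assert all(n == 1 for _, n in groups)

    def test_grouping_is_rle_inverse(self):
        sched = Schedule(order=PRINTED_ORDER)
        rebuilt = [t for t, n in group_runs(sched) for _ in range(n)]
        assert tuple(rebuilt) == PRINTED_ORDER

    def test_single_trainer_schedule(self):
        sched = make_schedule(1, central_epochs=5, seed=0)
        assert sched.order == (1,) * 5
        assert all(n <= 2 for _, n in group_runs(sched))

    @pytest.mark.parametrize("seed", range(50))
    def test_generated_schedules_valid(self, seed):
        sched = make_schedule(2, central_epochs=20, seed=seed)
        assert sched.is_valid(central_epochs=20)

    def test_distinct_seeds_distinct_orders(self):
        orders = {make_schedule(3, 10, seed=s).order for s in range(20)}
        assert len(orders) > 15

    @pytest.mark.parametrize("n,ce", [(3, 7), (4, 5), (5, 3)])
    def test_many_trainer_schedules_valid(self, n, ce):
        for seed in range(10):
            assert make_schedule(n, ce, seed=seed).is_valid(central_epochs=ce)

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(0, 5, seed=0)


class TestPayloadFraming:
    def test_counter_round_trip(self, bundle):
        data = pack_payload(17, bundle)
        counter, out = unpack_payload(data)
        assert counter == 17 and out == bundle

    def test_short_payload_rejected(self):
        from fedseal.crypto.bundle import FormatError

        with pytest.raises(FormatError):
            unpack_payload(b"abc")


class TestTrainerRound:
    def test_bottom_initializes_and_returns_ciphertext(self, key, tiny_world):
        _, _, make_trainers = tiny_world
        t0 = make_trainers()[0]
        result = trainer_round(t0, None, 1, 0)
        assert not isinstance(result, DetectionEvent)
        # the upload decrypts to a base-only bundle under the shared key
        from fedseal.crypto.codec import aead_decrypt

        counter, b = unpack_payload(aead_decrypt(key, result))
        assert counter == 0
        assert len(b.select("base/")) > 0 and len(b.select("head/")) == 0

    def test_receiving_base_only_attaches_head(self, key, tiny_world):
        _, _, make_trainers = tiny_world
        trainers = make_trainers()
        up0 = trainer_round(trainers[0], None, 1, 0)
        up1 = trainer_round(trainers[1], up0, 1, 1)
        from fedseal.crypto.codec import aead_decrypt

        _, b = unpack_payload(aead_decrypt(key, up1))
        assert len(b.select("head/")) > 0

    def test_bit_flip_yields_detection_no_training(self, key, tiny_world):
        _, _, make_trainers = tiny_world
        trainers = make_trainers()
        up0 = trainer_round(trainers[0], None, 1, 0)
        raw = bytearray(up0.iv + up0.body + up0.tag)
        raw[5] ^= 0x10
        from fedseal.crypto.codec import AuthCiphertext

        tampered = AuthCiphertext(bytes(raw[:16]), bytes(raw[16:-64]), bytes(raw[-64:]))
        result = trainer_round(trainers[1], tampered, 1, 1)
        assert isinstance(result, DetectionEvent)
        assert result.cause == "tag_mismatch"
        assert trainers[1].bundle is None  # fail closed: no state was updated

    def test_stale_counter_detected(self, key, tiny_world):
        _, _, make_trainers = tiny_world
        trainers = make_trainers()
        up0 = trainer_round(trainers[0], None, 1, 0)
        up1 = trainer_round(trainers[1], up0, 1, 1)
        assert not isinstance(up1, DetectionEvent)
        replayed = trainer_round(trainers[1], up0, 1, 2)  # older counter again
        assert isinstance(replayed, DetectionEvent)
        assert replayed.cause == "stale_round"

    def test_replay_protection_off_switch(self, key, tiny_world):
        _, _, make_trainers = tiny_world
        trainers = make_trainers()
        up0 = trainer_round(trainers[0], None, 1, 0)
        trainer_round(trainers[1], up0, 1, 1)
        result = trainer_round(trainers[1], up0, 1, 2, replay_protection=False)
        assert not isinstance(result, DetectionEvent)


class TestRunProtocol:
    def test_honest_run_completes_with_clean_transcript(self, tiny_world):
        _, _, make_trainers = tiny_world
        sched = make_schedule(2, 4, seed=7)
        transcript, final = run_protocol(make_trainers(), ServerState(), sched)
        assert final is not None
        assert all(e.integrity_ok for e in transcript.events)
        # conservation: one fetch + one upload per turn (vertical + groups)
        n_turns = 1 + len(group_runs(sched))
        assert len(transcript.events) == 2 * n_turns

    def test_tamper_halts_at_the_tampered_round(self, tiny_world):
        _, _, make_trainers = tiny_world
        sched = make_schedule(2, 4, seed=7)
        srv = ServerState(mode="tamper_bitflip", seed=5, tamper_at_fetch=3)
        transcript, _ = run_protocol(make_trainers(), srv, sched)
        bad = transcript.detection_events
        assert len(bad) == 1 and bad[0].round == 3
        assert transcript.events[-1] is bad[0]  # nothing logged afterwards

    @pytest.mark.parametrize("mode", ["tamper_bitflip", "tamper_iv_xor"])
    def test_detection_completeness(self, tiny_world, mode):
        """Across randomized tamper rounds, the first receiving trainer detects."""
        _, _, make_trainers = tiny_world
        rng = np.random.default_rng(0)
        for trial in range(10):
            sched = make_schedule(2, 3, seed=int(rng.integers(1 << 16)))
            at = int(rng.integers(1, 4))
            srv = ServerState(mode=mode, seed=trial, tamper_at_fetch=at)
            transcript, _ = run_protocol(make_trainers(), srv, sched)
            bad = transcript.detection_events
            assert len(bad) == 1 and bad[0].round == at
            assert bad[0].cause == "tag_mismatch"

    def test_replay_detected_as_stale(self, tiny_world):
        _, _, make_trainers = tiny_world
        sched = Schedule(order=(1, 2, 1, 2, 1, 2))
        srv = ServerState(mode="replay", tamper_at_fetch=3)
        transcript, _ = run_protocol(make_trainers(), srv, sched)
        bad = transcript.detection_events
        assert len(bad) == 1 and bad[0].cause == "stale_round"

    def test_honest_path_equals_direct_handoff(self, tiny_world):
        """The encrypted server channel is transparent: bundle sequences match bit-exactly."""
        import hashlib

        _, _, make_trainers = tiny_world
        sched = make_schedule(2, 3, seed=13)
        transcript, _ = run_protocol(make_trainers(), ServerState(), sched)
        direct = run_direct(make_trainers(), sched)
        direct_hashes = [
            hashlib.sha256(serialize_weights(b)).hexdigest() for b in direct
        ]
        assert transcript.upload_hashes == direct_hashes

    def test_final_bundle_loads_into_every_composed_model(self, tiny_world):
        spec, _, make_trainers = tiny_world
        sched = make_schedule(2, 2, seed=3)
        _, final = run_protocol(make_trainers(), ServerState(), sched)
        net = Network.from_bundle(spec, final)
        out = net.forward(np.random.default_rng(0).random((2, 1, 16, 16)))
        assert out.shape == (1, 1)

    def test_transcript_byte_sizes_match_encoded_lengths(self, key, tiny_world):
        _, _, make_trainers = tiny_world
        sched = make_schedule(2, 2, seed=3)
        transcript, _ = run_protocol(make_trainers(), ServerState(), sched)
        ups = [e for e in transcript.events if e.direction == "up"]
        t = make_trainers()[0]
        ct = trainer_round(t, None, 1, 0)
        assert ups[0].nbytes == len(write_ciphertext(ct))


class TestCommunicationAccounting:
    def _paper_scale_transcript(self, n_trainers=2, central_epochs=20, nbytes=234_000_000):
        tr = Transcript()
        rnd = 0
        for _ in range(central_epochs):
            for tid in range(1, n_trainers + 1):
                tr.append(TranscriptEvent(rnd, "down", tid, nbytes, True))
                tr.append(TranscriptEvent(rnd, "up", tid, nbytes, True, 1))
                rnd += 1
        return tr

    def test_full_scale_projection_936_gb(self):
        """20 central epochs x 234 MB x up+down = 9.36 GB per trainer."""
        tr = self._paper_scale_transcript()
        totals = account_communication(tr)
        for tid in (1, 2):
            assert totals[tid]["up"] + totals[tid]["down"] == 9_360_000_000

    def test_empty_transcript(self):
        assert account_communication(Transcript()) == {}

    def test_early_sharing_projection_34_gb(self):
        """4 trainers x 15 central epochs x 20 parts x 28 MB uploads ~ 34 GB."""
        tr = Transcript()
        rnd = 0
        for _ in range(15 * 20):
            for tid in range(1, 5):
                tr.append(TranscriptEvent(rnd, "up", tid, 28_000_000, True, 1))
                rnd += 1
        totals = account_communication(tr)
        total_up = sum(t["up"] for t in totals.values())
        assert total_up == 4 * 15 * 20 * 28_000_000 == 33_600_000_000

    def test_per_message_override(self):
        tr = self._paper_scale_transcript(nbytes=123)
        totals = account_communication(tr, per_message_bytes=234_000_000)
        assert totals[1]["up"] == 20 * 234_000_000
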