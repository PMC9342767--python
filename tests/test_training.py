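"""Loss formulas, schedules, partitioning, augmentation, AUC — with oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedseal.training import (
    ClassWeights,
    PlateauScheduler,
    auc,
    augment,
    class_weights,
    local_train,
    multilabel_bce,
    partition_early_sharing,
    step_decay_lr,
    weighted_bce,
)


class TestClassWeights:
    def test_joint_mri_training_sets(self):
        """Pooled prevalence of the two knee-MRI cohorts: 347/1682 ~ 0.2063."""
        w = class_weights([139, 208], [552, 1130])
        assert w.w1 == pytest.approx(347 / 1682)
        assert w.w1 == pytest.approx(0.2063, abs=5e-5)
        assert w.w0 == pytest.approx(0.7937, abs=5e-5)

    def test_balanced(self):
        w = class_weights([50], [100])
        assert w.w1 == w.w0 == 0.5

    def test_single_dataset(self):
        assert class_weights([208], [1130]).w1 == pytest.approx(208 / 1130)

    def test_sum_exact(self):
        w = class_weights([7], [123])
        assert w.w1 + w.w0 == 1.0

    @pytest.mark.parametrize("pos,tot", [([0], [10]), ([10], [10]), ([1], [0])])
    def test_degenerate_counts_rejected(self, pos, tot):
        with pytest.raises(ValueError):
            class_weights(pos, tot)


class TestWeightedBCE:
    def test_perfect_prediction_zero(self):
        w = ClassWeights(0.2063, 0.7937)
        assert weighted_bce(1 - 1e-7, 1, w) == pytest.approx(0.0, abs=1e-5)
        assert weighted_bce(1e-7, 0, w) == pytest.approx(0.0, abs=1e-5)

    def test_hand_evaluated_midpoint(self):
        """y=1, p=0.5: loss = w1 * ln 2 ~ 0.1430."""
        w = ClassWeights(0.2063, 1 - 0.2063)
        assert weighted_bce(0.5, 1, w) == pytest.approx(0.2063 * math.log(2), abs=1e-6)
        assert weighted_bce(0.5, 1, w) == pytest.approx(0.1430, abs=1e-4)

    def test_unit_weights_reduce_to_plain_bce(self):
        w = ClassWeights(0.5, 0.5)
        p, y = 0.73, 1
        assert 2 * weighted_bce(p, y, w) == pytest.approx(-math.log(p))

    def test_conventional_switch_swaps_weights(self):
        w = ClassWeights(0.2, 0.8)
        assert weighted_bce(0.3, 1, w, conventional=True) == pytest.approx(
            0.8 * -math.log(0.3)
        )

    @given(st.floats(0.0, 1.0), st.integers(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative(self, p, y):
        assert weighted_bce(p, y, ClassWeights(0.2063, 0.7937)) >= 0.0

    def test_extreme_probabilities_clamped(self):
        w = ClassWeights(0.5, 0.5)
        assert np.isfinite(weighted_bce(0.0, 1, w))
        assert np.isfinite(weighted_bce(1.0, 0, w))


class TestMultilabelBCE:
    def test_perfect_prediction(self):
        y = np.zeros(14)
        y[3] = 1
        p = np.clip(y, 1e-7, 1 - 1e-7)
        assert multilabel_bce(p, y) == pytest.approx(0.0, abs=1e-4)

    def test_uniform_predictions_closed_form(self):
        """All p=0.5: loss = 14 ln 2 ~ 9.7041, for any label vector."""
        for y in [np.zeros(14), np.ones(14), (np.arange(14) % 2)]:
            assert multilabel_bce(np.full(14, 0.5), y) == pytest.approx(
                14 * math.log(2), abs=1e-9
            )
            assert multilabel_bce(np.full(14, 0.5), y) == pytest.approx(9.7041, abs=1e-4)

    def test_decomposes_into_unit_weight_binary_terms(self, rng):
        p = rng.uniform(0.05, 0.95, 14)
        y = rng.integers(0, 2, 14)
        total = sum(
            2 * weighted_bce(p[c], y[c], ClassWeights(0.5, 0.5)) for c in range(14)
        )
        assert multilabel_bce(p, y) == pytest.approx(total)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            multilabel_bce(np.full(13, 0.5), np.zeros(13))


class TestSchedules:
    def test_step_decay_values(self):
        assert step_decay_lr(0) == 0.01
        assert step_decay_lr(2) == 0.005
        assert step_decay_lr(3) == 0.005
        assert step_decay_lr(14) == pytest.approx(0.01 * 0.5**7) == pytest.approx(7.8125e-5)

    def test_step_decay_non_increasing(self):
        lrs = [step_decay_lr(ce) for ce in range(15)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_plateau_constant_while_improving(self):
        s = PlateauScheduler(lr0=1e-5, factor=0.3, patience=5)
        for m in [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4]:
            assert s.update(m) == 1e-5

    def test_plateau_reduces_once_then_resets(self):
        s = PlateauScheduler(lr0=1e-5, factor=0.3, patience=5)
        s.update(1.0)
        for _ in range(4):
            assert s.update(1.0) == 1e-5
        assert s.update(1.0) == pytest.approx(3e-6)
        for _ in range(4):
            assert s.update(1.0) == pytest.approx(3e-6)

    def test_two_plateaus_compound(self):
        s = PlateauScheduler(lr0=1e-5, factor=0.3, patience=5)
        s.update(1.0)
        for _ in range(10):
            s.update(1.0)
        assert s.lr == pytest.approx(1e-5 * 0.09)


class TestPartitioner:
    def test_early_sharing_arithmetic(self):
        """A quarter of 78,468 images over 20 parts: sizes 981/980 (int part 980)."""
        parts = partition_early_sharing(np.arange(78_468 // 4), n_parts=20, seed=0)
        sizes = sorted(len(p) for p in parts)
        assert 78_468 // 4 == 19_617
        assert sizes.count(980) == 3 and sizes.count(981) == 17
        assert min(sizes) == 78_468 // (4 * 20) == 980

    def test_identity_partition(self):
        parts = partition_early_sharing(np.arange(17), n_parts=1, seed=3)
        assert sorted(parts[0].tolist()) == list(range(17))

    @pytest.mark.parametrize("seed", range(25))
    def test_disjoint_exhaustive_balanced(self, seed):
        idx = np.arange(103)
        parts = partition_early_sharing(idx, n_parts=7, seed=seed)
        merged = np.concatenate(parts)
        assert sorted(merged.tolist()) == idx.tolist()
        sizes = [len(p) for p in parts]
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            partition_early_sharing(np.arange(5), n_parts=6, seed=0)


class TestAugment:
    def test_channel_mean_image_maps_to_zero(self):
        """A constant image at the channel means normalizes to all zeros."""
        img = np.empty((3, 16, 16), dtype=np.float32)
        img[0], img[1], img[2] = 0.485, 0.456, 0.406

        class NoOpRng:
            def random(self):
                return 0.9  # no flip

            def uniform(self, lo, hi):
                return 0.0  # no rotation

        out = augment(img, rng=NoOpRng())
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_seed_determinism(self, rng):
        img = rng.random((3, 24, 24)).astype(np.float32)
        a = augment(img, seed=42)
        b = augment(img, seed=42)
        c = augment(img, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_wrong_layout_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((16, 16), dtype=np.float32), seed=0)


def brute_force_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = sum(1.0 if sp > sn else 0.5 if sp == sn else 0.0 for sp in pos for sn in neg)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auc([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0]) == 0.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_pair_counting_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 40))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
        labels = np.r_[1, 0, rng.integers(0, 2, n - 2)]  # both classes present
        assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(60)
        labels = np.r_[np.ones(20), np.zeros(40)].astype(int)
        a = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(a)
        assert auc(3 * scores - 7, labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestLocalTrain:
    def test_zero_epochs_is_identity(self):
        from fedseal.compose import build_tiny_model
        from fedseal.nn.network import Network
        from fedseal.nn.optim import OptimizerConfig
        from fedseal.synthetic import gen_series_dataset

        spec = build_tiny_model()
        b = Network.from_seed(spec, 1).to_bundle()
        data = gen_series_dataset(4, seed=0)
        out, hist = local_train(spec, b, data, 0, OptimizerConfig(lr=1e-3))
        assert out == b and hist == []

    def test_loss_decreases_on_separable_data(self):
        from fedseal.compose import build_tiny_model
        from fedseal.nn.network import Network
        from fedseal.nn.optim import OptimizerConfig, make_optimizer
        from fedseal.synthetic import gen_series_dataset
        from fedseal.training import ClassWeights

        spec = build_tiny_model()
        data = gen_series_dataset(60, pos_fraction=0.3, signal_strength=0.8, seed=3)
        b = Network.from_seed(spec, 1).to_bundle()
        opt = make_optimizer(OptimizerConfig(kind="adam", lr=2e-3))
        losses = []
        for ep in range(5):
            b, h = local_train(
                spec, b, data, 1, opt,
                weights=ClassWeights(0.3, 0.7), rng=np.random.default_rng(ep),
            )
            losses.append(h[0])
        assert losses[-1] < losses[0]

    def test_two_single_epochs_equal_one_double_epoch(self):
        """With a shared rng and optimizer, 1+1 local epochs reproduce a
        single 2-epoch call bit-exactly (the data-order contract)."""
        from fedseal.compose import build_tiny_model
        from fedseal.nn.network import Network
        from fedseal.nn.optim import OptimizerConfig, make_optimizer
        from fedseal.synthetic import gen_series_dataset
        from fedseal.training import ClassWeights

        spec = build_tiny_model()
        data = gen_series_dataset(20, seed=3)
        start = Network.from_seed(spec, 1).to_bundle()
        w = ClassWeights(0.3, 0.7)

        opt1 = make_optimizer(OptimizerConfig(lr=1e-3))
        rng1 = np.random.default_rng(99)
        b1, _ = local_train(spec, start, data, 1, opt1, weights=w, rng=rng1)
        b1, _ = local_train(spec, b1, data, 1, opt1, weights=w, rng=rng1)

        opt2 = make_optimizer(OptimizerConfig(lr=1e-3))
        rng2 = np.random.default_rng(99)
        b2, _ = local_train(spec, start, data, 2, opt2, weights=w, rng=rng2)
        assert b1 == b2
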