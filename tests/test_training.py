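import hashlib

import numpy as np
import pytest

from tonguecrack import (
    TrainConfig,
    class_scheduler,
    downsample_mask,
    init_params,
    train_decnet,
    train_segnet,
)
from tonguecrack.synthdata import CRACKED, NON_CRACKED, TongueSample


def _state_hash(net):
    h = hashlib.sha256()
    for key in sorted(net.state_dict()):
        h.update(net.state_dict()[key].tobytes())
    return h.hexdigest()


class TestDownsampleMask:
    def test_all_zero(self):
        assert downsample_mask(np.zeros((32, 32), np.uint8)).sum() == 0

    def test_single_pixel_lights_exactly_one_cell(self):
        mask = np.zeros((64, 64), np.uint8)
        mask[19, 42] = 1
        target = downsample_mask(mask)
        assert target.sum() == 1
        assert target[19 // 8, 42 // 8] == 1

    def test_400_to_50(self):
        assert downsample_mask(np.ones((400, 400), np.uint8)).shape == (50, 50)

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError, match="width"):
            downsample_mask(np.zeros((32, 33), np.uint8))


class TestScheduler:
    def test_even_is_cracked_odd_is_not(self):
        assert class_scheduler(0) == CRACKED
        assert class_scheduler(1) == NON_CRACKED
        assert all(class_scheduler(2 * k) == CRACKED for k in range(50))

    def test_balanced_over_any_even_window(self):
        draws = [class_scheduler(i) for i in range(2 * 137)]
        assert draws.count(CRACKED) == draws.count(NON_CRACKED) == 137


class TestTrainSegnet:
    def test_sample_without_mask_rejected(self, tiny_dataset):
        samples = list(tiny_dataset)
        broken = TongueSample(image=samples[0].image, mask=None, label=CRACKED)
        samples[0] = broken
        with pytest.raises(ValueError, match="mask"):
            train_segnet(samples, TrainConfig(epochs_seg=1))

    def test_single_class_rejected(self, tiny_dataset):
        positives = [s for s in tiny_dataset if s.label == CRACKED]
        with pytest.raises(ValueError, match="non-cracked"):
            train_segnet(positives, TrainConfig(epochs_seg=1))

    def test_zero_learning_rate_keeps_weights(self, tiny_dataset):
        seg0, _ = init_params(0)
        before = {k: v.copy() for k, v, _ in seg0.params()}
        train_segnet(tiny_dataset, TrainConfig(learning_rate=0.0, epochs_seg=4), params=seg0)
        for key, value, _ in seg0.params():
            assert np.array_equal(before[key], value), key

    def test_training_is_deterministic(self, tiny_dataset):
        cfg = TrainConfig(epochs_seg=8, seed=3)
        a = train_segnet(tiny_dataset, cfg)
        b = train_segnet(tiny_dataset, cfg)
        assert a.train_loss == b.train_loss
        assert _state_hash(a) == _state_hash(b)

    def test_loss_decreases_on_fixed_set(self, small_cfg):
        from tonguecrack import generate_dataset

        samples = generate_dataset(4, 4, small_cfg, 21)
        seg = train_segnet(samples, TrainConfig(epochs_seg=200, seed=0))
        start = np.mean(seg.train_loss[:5])
        end = np.mean(seg.train_loss[-20:])
        assert end < start

    def test_median_final_loss_below_initial_across_seeds(self, tiny_dataset):
        """Loss decrease should not be a fluke of one seed: the median over
        5 training seeds must drop between the first and last iterations."""
        starts, ends = [], []
        for seed in range(5):
            seg = train_segnet(tiny_dataset, TrainConfig(epochs_seg=30, seed=seed))
            starts.append(seg.train_loss[0])
            ends.append(np.mean(seg.train_loss[-5:]))
        assert np.median(ends) < np.median(starts)


@pytest.fixture(scope="module")
def trained_seg(tiny_dataset):
    return train_segnet(tiny_dataset, TrainConfig(epochs_seg=120, seed=0))


class TestTrainDecnet:
    def test_segmentation_weights_frozen_bitwise(self, tiny_dataset, trained_seg):
        before = _state_hash(trained_seg)
        train_decnet(tiny_dataset, trained_seg, TrainConfig(epochs_dec=40, seed=0))
        assert _state_hash(trained_seg) == before

    def test_zero_learning_rate_keeps_decision_weights(self, tiny_dataset, trained_seg):
        _, dec0 = init_params(0)
        before = {k: v.copy() for k, v, _ in dec0.params()}
        train_decnet(
            tiny_dataset, trained_seg,
            TrainConfig(learning_rate=0.0, epochs_dec=4), params=dec0,
        )
        for key, value, _ in dec0.params():
            assert np.array_equal(before[key], value), key

    def test_separable_toy_set_reaches_full_training_accuracy(self, tiny_dataset, trained_seg):
        """High-contrast synthetic cracks are linearly separable from the
        pooled segmentation outputs; decision training should fit them
        perfectly within 500 iterations."""
        from tonguecrack import dec_forward, seg_forward

        dec = train_decnet(tiny_dataset, trained_seg, TrainConfig(epochs_dec=500, seed=0))
        correct = 0
        for s in tiny_dataset:
            logit = dec_forward(seg_forward(s.image, trained_seg), dec)
            correct += (logit > 0) == (s.label == CRACKED)
        assert correct == len(tiny_dataset)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-0.1)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(loss="hinge")
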