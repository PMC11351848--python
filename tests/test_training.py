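"""Patch extraction, the combined loss, the plateau schedule, thresholding."""

import math

import numpy as np
import pytest

from coroseg.phantoms import make_cardiac_phantom
from coroseg.preprocess import minmax_normalize
from coroseg.resdense_unet import NetworkSpec, build_network
from coroseg.training import (
    PatchSet,
    PlateauSchedule,
    TrainConfig,
    bce_dice_loss,
    binarize,
    extract_patches,
    split_by_case,
    train,
)
from coroseg.volume import Mask, Volume


class TestExtractPatches:
    def test_empty_mask_slices_excluded(self, rng):
        vol = Volume(data=rng.random((10, 32, 32)))
        mask_data = np.zeros((10, 32, 32), dtype=np.uint8)
        for z in (2, 5, 6):
            mask_data[z, 10:14, 10:14] = 1
        patches = extract_patches(vol, Mask(data=mask_data), size=32)
        assert len(patches) == 3

    def test_larger_slice_centre_cropped(self, rng):
        vol = Volume(data=rng.random((2, 300, 300)))
        mask = Mask(data=np.ones((2, 300, 300), dtype=np.uint8))
        patches = extract_patches(vol, mask, size=256)
        assert patches.images.shape == (2, 256, 256)
        # central crop: compare against manual standardization of the window
        manual = vol.data[0, 22:278, 22:278]
        manual = (manual - manual.mean()) / manual.std()
        np.testing.assert_allclose(patches.images[0], manual, atol=1e-5)

    def test_smaller_slice_zero_padded(self, rng):
        vol = Volume(data=rng.random((1, 20, 20)))
        mask = Mask(data=np.ones((1, 20, 20), dtype=np.uint8))
        patches = extract_patches(vol, mask, size=32)
        assert patches.images.shape == (1, 32, 32)
        assert patches.masks[0, :6].sum() == 0  # padded border

    def test_all_empty_mask_raises(self, rng):
        vol = Volume(data=rng.random((5, 16, 16)))
        with pytest.raises(ValueError, match="empty"):
            extract_patches(vol, Mask(data=np.zeros((5, 16, 16), dtype=np.uint8)))

    def test_misaligned_inputs_rejected(self, rng):
        vol = Volume(data=rng.random((5, 16, 16)))
        mask = Mask(data=np.zeros((4, 16, 16), dtype=np.uint8))
        with pytest.raises(ValueError, match="misaligned"):
            extract_patches(vol, mask)


class TestLoss:
    def test_perfect_prediction_near_zero(self, rng):
        target = (rng.random((1, 32, 32)) > 0.5).astype(np.float64)
        pred = np.clip(target, 1e-7, 1 - 1e-7)
        assert bce_dice_loss(pred, target) < 1e-3

    def test_closed_form_half_ones(self):
        """pred=0.5 on a half-ones target: BCE=ln2, softDice=0.5, sum≈1.1931."""
        n = 64 * 64
        target = np.zeros(n)
        target[: n // 2] = 1.0
        pred = np.full(n, 0.5)
        loss = bce_dice_loss(pred, target, weights=(1.0, 1.0))
        assert loss == pytest.approx(math.log(2.0) + 0.5, abs=1e-6)

    def test_all_background_target(self):
        """Empty target with near-zero prediction: dice term ≈ 1, bce ≈ 0."""
        target = np.zeros(1000)
        pred = np.full(1000, 1e-7)
        loss = bce_dice_loss(pred, target)
        # oracle: direct formula with the shared epsilon convention
        p = np.clip(pred, 1e-7, 1 - 1e-7)
        bce = float(np.mean(-np.log(1 - p)))
        soft = 2 * float((p * target).sum()) / (float(p.sum() + target.sum()) + 1e-7)
        assert loss == pytest.approx(bce + (1 - soft), abs=1e-12)
        assert loss == pytest.approx(1.0, abs=1e-3)

    def test_weight_convention_is_sum(self):
        target = np.ones(100)
        pred = np.full(100, 0.7)
        both = bce_dice_loss(pred, target, weights=(1.0, 1.0))
        bce_only = bce_dice_loss(pred, target, weights=(1.0, 0.0))
        dice_only = bce_dice_loss(pred, target, weights=(0.0, 1.0))
        assert both == pytest.approx(bce_only + dice_only, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            bce_dice_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_non_negative(self, rng):
        for _ in range(20):
            pred = rng.random((8, 8))
            target = (rng.random((8, 8)) > 0.5).astype(float)
            assert bce_dice_loss(pred, target) >= 0.0


class TestSchedule:
    def test_lr_halves_after_three_flat_epochs(self):
        sched = PlateauSchedule(1e-4, 0.5, 3, 5)
        sched.update(0.5)  # improvement (baseline)
        lrs = [sched.update(0.5)[0] for _ in range(3)]
        assert lrs[:2] == [1e-4, 1e-4]
        assert lrs[2] == pytest.approx(5e-5)

    def test_stops_after_five_flat_epochs(self):
        sched = PlateauSchedule(1e-4, 0.5, 3, 5)
        sched.update(0.5)
        stops = [sched.update(0.5)[1] for _ in range(5)]
        assert stops == [False, False, False, False, True]

    def test_improvement_resets_both_counters(self):
        sched = PlateauSchedule(1e-4, 0.5, 3, 5)
        sched.update(0.5)
        sched.update(0.5)
        sched.update(0.5)
        lr, stop = sched.update(0.6)  # real improvement
        assert lr == 1e-4 and not stop
        assert sched.lr_wait == 0 and sched.stop_wait == 0

    def test_sub_min_delta_gain_is_not_improvement(self):
        sched = PlateauSchedule(1e-4, 0.5, 3, 5, min_delta=1e-4)
        sched.update(0.5)
        sched.update(0.50005)
        assert sched.stop_wait == 1


class TestSplit:
    def test_case_ids_disjoint(self, rng):
        images = rng.random((40, 8, 8)).astype(np.float32)
        masks = (rng.random((40, 8, 8)) > 0.5).astype(np.uint8)
        ids = [f"case_{i % 10}" for i in range(40)]
        ps = PatchSet(images=images, masks=masks, case_ids=ids)
        tr, va = split_by_case(ps, 0.8, seed=3)
        assert set(tr.case_ids).isdisjoint(va.case_ids)
        assert len(tr) + len(va) == 40
        assert len(set(va.case_ids)) >= 1

    def test_single_case_rejected(self, rng):
        ps = PatchSet(
            images=rng.random((4, 8, 8)).astype(np.float32),
            masks=np.zeros((4, 8, 8), dtype=np.uint8),
            case_ids=["only"] * 4,
        )
        with pytest.raises(ValueError):
            split_by_case(ps, 0.8, seed=0)


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def small_run(self):
        """A short real training run on two easy phantom cases."""
        sets = []
        for i, seed in enumerate((11, 12, 13)):
            from coroseg.phantoms import PhantomSpec

            vol, heart, _ = make_cardiac_phantom(
                PhantomSpec(size=32, heart_center=(16, 16, 16),
                            heart_axes=(11, 12, 12), seed=seed)
            )
            sets.append(
                extract_patches(
                    minmax_normalize(vol), heart, size=32, case_id=f"c{i}"
                )
            )
        patches = PatchSet.concat(sets)
        model = build_network(NetworkSpec(n_levels=3, base_channels=4), seed=0)
        cfg = TrainConfig(max_epochs=3, batch_size=8, seed=0)
        result = train(model, patches, cfg)
        return model, result, cfg

    def test_history_records_epochs(self, small_run):
        _, result, _ = small_run
        assert 1 <= len(result.history) <= 3
        for row in result.history:
            assert {"epoch", "lr", "train_loss", "val_dsc"} <= set(row)

    def test_gradient_norms_clipped(self, small_run):
        _, result, cfg = small_run
        assert result.grad_norms  # at least one step happened
        assert max(result.grad_norms) <= cfg.clip_norm + 1e-6

    def test_best_epoch_tracked(self, small_run):
        _, result, _ = small_run
        dscs = [row["val_dsc"] for row in result.history]
        assert result.best_val_dsc == pytest.approx(max(dscs))


class TestBinarize:
    def test_strict_threshold_at_half(self):
        prob = Volume(data=np.full((2, 2, 2), 0.5))
        out = binarize(prob, 0.5)
        np.testing.assert_array_equal(out.data, 0)

    def test_values_split_around_threshold(self):
        out = binarize(np.array([[[0.2, 0.7]]]), 0.5)
        np.testing.assert_array_equal(out.ravel(), [0, 1])

    def test_idempotent(self, rng):
        prob = rng.random((4, 4, 4))
        once = binarize(prob)
        np.testing.assert_array_equal(binarize(once.astype(float)), once)
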