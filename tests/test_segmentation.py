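"""Segmentation stage: preprocessing, Dice, loss API, augmentation,
training loop behaviour and kidney-side assignment."""

import numpy as np
import pytest

from petmtv.core import BinaryMask, ImageVolume, ORGAN_LABELS, VoxelGrid
from petmtv.errors import GeometryError
from petmtv.segmentation import (
    AugmentRanges,
    TrainConfig,
    augment_pair,
    combined_loss,
    dice_coefficient,
    fine_tune,
    preprocess_ct,
    split_cases,
    train_segmentation,
    _assign_kidney_sides,
)
from petmtv.unet import UNetConfig, build_residual_unet


class TestPreprocess:
    def test_constant_volume_maps_to_zeros(self):
        out = preprocess_ct(np.full((4, 4, 4), 17.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_standardized_moments(self):
        rng = np.random.default_rng(0)
        out = preprocess_ct(rng.normal(40, 25, size=(16, 16, 16)))
        assert out.mean() == pytest.approx(0.0, abs=1e-6)
        assert out.std() == pytest.approx(1.0, abs=1e-6)

    def test_three_value_volume_hand_computed(self):
        # values {0, 50, 100}: max 100 -> clip to [1, 99] -> {1, 50, 99};
        # mean 50, SD 49*sqrt(2/3) -> standardized {-sqrt(3/2), 0, +sqrt(3/2)}
        v = np.array([0.0, 50.0, 100.0]).reshape(3, 1, 1)
        out = preprocess_ct(v)
        expected = np.array([-np.sqrt(1.5), 0.0, np.sqrt(1.5)]).reshape(3, 1, 1)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_negative_values_shifted_before_clipping(self):
        # CT in HU: shift so the clip range is computed on nonnegative values
        v = np.array([-1000.0, 0.0, 1000.0]).reshape(3, 1, 1)
        out = preprocess_ct(v)
        assert out[0, 0, 0] < 0 < out[2, 0, 0]
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_percentile_mode(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 10, size=(12, 12, 12))
        out = preprocess_ct(v, mode="percentile")
        assert out.std() == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(ValueError):
            preprocess_ct(v, mode="nope")


class TestDice:
    grid = VoxelGrid((4, 4, 4), (1, 1, 1))

    def _mask(self, coords):
        m = np.zeros(self.grid.shape, bool)
        for c in coords:
            m[c] = True
        return BinaryMask(self.grid, m)

    def test_identical_masks(self):
        a = self._mask([(0, 0, 0), (1, 1, 1)])
        assert dice_coefficient(a, a) == 1.0

    def test_disjoint_masks(self):
        a = self._mask([(0, 0, 0)])
        b = self._mask([(3, 3, 3)])
        assert dice_coefficient(a, b) == 0.0

    def test_half_overlap(self):
        a = self._mask([(0, 0, 0), (0, 0, 1), (0, 0, 2), (0, 0, 3)])
        b = self._mask([(0, 0, 2), (0, 0, 3), (1, 0, 0), (1, 0, 1)])
        assert dice_coefficient(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        e = self._mask([])
        assert dice_coefficient(e, e) == 1.0

    def test_symmetry(self):
        a = self._mask([(0, 0, 0), (1, 1, 1), (2, 2, 2)])
        b = self._mask([(1, 1, 1), (3, 3, 3)])
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_grid_mismatch(self):
        other = BinaryMask(VoxelGrid((4, 4, 4), (2, 2, 2)),
                           np.zeros((4, 4, 4), bool))
        with pytest.raises(GeometryError):
            dice_coefficient(self._mask([]), other)


class TestCombinedLoss:
    def test_perfect_prediction(self):
        t = np.random.default_rng(0).integers(0, 3, size=(1, 4, 4))
        probs = np.zeros((1, 3, 4, 4))
        idx = np.indices((1, 4, 4))
        probs[idx[0], t, idx[1], idx[2]] = 1.0
        assert combined_loss(probs, t) <= 1e-6

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        z = rng.random((2, 4, 5, 5))
        probs = z / z.sum(axis=1, keepdims=True)
        t = rng.integers(0, 4, size=(2, 5, 5))
        assert combined_loss(probs, t) >= 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            combined_loss(np.ones((1, 2, 4, 4)) / 2, np.zeros((1, 3, 3), int))


class TestAugment:
    rng_img = np.random.default_rng(0).normal(size=(32, 32)).astype(np.float32)
    labels = np.zeros((32, 32), dtype=np.uint8)
    labels[4:10, 4:10] = ORGAN_LABELS["kidney_left"]
    labels[22:28, 4:10] = ORGAN_LABELS["kidney_right"]

    def test_identity_ranges_leave_pair_unchanged(self):
        img, lab = augment_pair(self.rng_img, self.labels, AugmentRanges.none(), 0)
        np.testing.assert_array_equal(img, self.rng_img)
        np.testing.assert_array_equal(lab, self.labels)

    def test_flip_swaps_kidney_sides_and_is_involutive(self):
        always_flip = AugmentRanges(0.0, 0.0, (1.0, 1.0), 1.0)
        img1, lab1 = augment_pair(self.rng_img, self.labels, always_flip, 0)
        # the kidney at small x keeps the "left" label after mirroring
        left_x = np.argwhere(lab1 == ORGAN_LABELS["kidney_left"])[:, 0].mean()
        right_x = np.argwhere(lab1 == ORGAN_LABELS["kidney_right"])[:, 0].mean()
        assert left_x < right_x
        img2, lab2 = augment_pair(img1, lab1, always_flip, 1)
        np.testing.assert_array_equal(img2, self.rng_img)
        np.testing.assert_array_equal(lab2, self.labels)

    def test_same_seed_same_transform(self):
        ranges = AugmentRanges(10.0, 8.0, (0.9, 1.1), 0.5)
        out1 = augment_pair(self.rng_img, self.labels, ranges, 42)
        out2 = augment_pair(self.rng_img, self.labels, ranges, 42)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_rotation_preserves_label_pixel_counts_approximately(self):
        ranges = AugmentRanges(10.0, 0.0, (1.0, 1.0), 0.0)
        _, lab = augment_pair(self.rng_img, self.labels, ranges, 3)
        for val in (ORGAN_LABELS["kidney_left"], ORGAN_LABELS["kidney_right"]):
            n0 = (self.labels == val).sum()
            n1 = (lab == val).sum()
            assert abs(n1 - n0) <= 0.3 * n0


def _tiny_cases(n=3, seed=0):
    """Small labeled volumes (32x32x32 at 8 mm) for fast training tests."""
    grid = VoxelGrid((32, 32, 32), (8.0, 8.0, 8.0))
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        ct = np.zeros(grid.shape, dtype=np.float32)
        lab = np.zeros(grid.shape, dtype=np.uint8)
        cx, cy, cz = rng.integers(8, 24, 3)
        ct[cx - 4:cx + 4, cy - 4:cy + 4, cz - 4:cz + 4] = 50.0
        lab[cx - 4:cx + 4, cy - 4:cy + 4, cz - 4:cz + 4] = 1
        ct += rng.normal(0, 1, grid.shape)
        cases.append((ImageVolume(grid, ct, "CT"), lab))
    return cases


TINY_NET = UNetConfig(base_channels=2, max_channels=4)
TINY_CFG = TrainConfig(max_epochs=5, seed=0, val_interval=0, batch_size=4,
                       slices_per_volume=6, crop_size=None,
                       augment=AugmentRanges.none())


class TestTraining:
    def test_loss_decreases_on_easy_task(self):
        model = build_residual_unet(TINY_NET, seed=0)
        _, hist = train_segmentation(model, _tiny_cases(), TINY_CFG)
        assert hist.final_loss < hist.initial_loss

    def test_training_is_deterministic_under_seed(self):
        h = []
        for _ in range(2):
            model = build_residual_unet(TINY_NET, seed=0)
            _, hist = train_segmentation(model, _tiny_cases(), TINY_CFG)
            h.append(hist.epoch_loss)
        assert h[0] == h[1]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_segmentation(build_residual_unet(TINY_NET), [], TINY_CFG)

    def test_lr_schedule_decays_at_absolute_epoch(self):
        # the step-down happens at a fixed epoch (default 60), so shorter
        # desk-scale budgets train at the full rate throughout
        cfg = TrainConfig(max_epochs=30)
        assert cfg.lr_decay_epoch == 60
        assert cfg.max_epochs < cfg.lr_decay_epoch

    def test_split_ratio(self):
        cases = list(range(50))
        tr, va, te = split_cases(cases, (5, 1, 4), np.random.default_rng(0))
        assert (len(tr), len(va), len(te)) == (25, 5, 20)
        assert sorted(tr + va + te) == cases


class TestFineTune:
    def test_reset_changes_predictions(self):
        model = build_residual_unet(TINY_NET, seed=0)
        x = np.random.default_rng(1).normal(size=(1, 1, 32, 32)).astype(np.float32)
        before = model.forward(x, train=False).copy()
        cfg = TrainConfig(max_epochs=0, seed=5)
        model, _ = fine_tune(model, _tiny_cases(), cfg)
        after = model.forward(x, train=False)
        assert not np.allclose(before, after)

    def test_zero_epochs_returns_reset_state(self):
        m1 = build_residual_unet(TINY_NET, seed=0)
        m2 = build_residual_unet(TINY_NET, seed=0)
        cfg = TrainConfig(max_epochs=0, seed=5)
        m1, _ = fine_tune(m1, _tiny_cases(), cfg)
        m2.reset_head(np.random.default_rng(5))
        np.testing.assert_array_equal(m1.classifier.w.data, m2.classifier.w.data)

    def test_final_layer_only_freezes_backbone(self):
        model = build_residual_unet(TINY_NET, seed=0)
        backbone_before = model.enc[0].conv1.w.data.copy()
        head_before = model.classifier.w.data.copy()
        cfg = TrainConfig(max_epochs=2, seed=5, batch_size=4, slices_per_volume=4,
                          crop_size=None, augment=AugmentRanges.none(),
                          trainable_scope="final_layer_only", val_interval=0)
        model, _ = fine_tune(model, _tiny_cases(), cfg)
        np.testing.assert_array_equal(model.enc[0].conv1.w.data, backbone_before)
        assert not np.array_equal(model.classifier.w.data, head_before)


class TestKidneySides:
    def test_components_reassigned_by_x_centroid(self):
        lab = np.zeros((20, 10, 10), dtype=np.uint8)
        # deliberately mislabel: left-side blob called "right" and vice versa
        lab[2:5, 4:7, 4:7] = ORGAN_LABELS["kidney_right"]
        lab[14:17, 4:7, 4:7] = ORGAN_LABELS["kidney_left"]
        fixed = _assign_kidney_sides(lab)
        assert (fixed[2:5, 4:7, 4:7] == ORGAN_LABELS["kidney_left"]).all()
        assert (fixed[14:17, 4:7, 4:7] == ORGAN_LABELS["kidney_right"]).all()

    def test_single_component_assigned_by_grid_midline(self):
        lab = np.zeros((20, 10, 10), dtype=np.uint8)
        lab[2:5, 4:7, 4:7] = ORGAN_LABELS["kidney_right"]
        fixed = _assign_kidney_sides(lab)
        assert (fixed[2:5, 4:7, 4:7] == ORGAN_LABELS["kidney_left"]).all()

    def test_no_kidney_voxels_is_noop(self):
        lab = np.zeros((4, 4, 4), dtype=np.uint8)
        np.testing.assert_array_equal(_assign_kidney_sides(lab), lab)
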