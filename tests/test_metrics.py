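"""Dice scores, the multiclass soft dice loss, and image-quality measures."""

import numpy as np
import pytest

from mrenhance import (
    DiceInputs,
    LabelMap,
    RegionMasks,
    Volume3D,
    dice_score,
    image_quality,
    multiclass_dice_loss,
    region_dice,
)


def _lmap(arr):
    return LabelMap(np.asarray(arr, dtype=np.int16))


class TestDiceScore:
    def test_closed_forms(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, :3] = True
        assert dice_score(a, a) == 1.0
        b = np.zeros_like(a)
        b[3, 3, :3] = True
        assert dice_score(a, b) == 0.0
        # |pred|=4, |true|=6, overlap 3 -> 0.6
        pred = np.zeros((4, 4, 4), dtype=bool)
        true = np.zeros_like(pred)
        pred.ravel()[:4] = True
        true.ravel()[1:7] = True
        assert dice_score(pred, true) == pytest.approx(0.6)

    def test_empty_vs_empty_is_one(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        assert dice_score(e, e) == 1.0

    def test_symmetry_and_permutation_invariance(self, rng):
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        assert dice_score(a, b) == dice_score(b, a)
        perm = rng.permutation(125)
        ap = a.ravel()[perm].reshape(a.shape)
        bp = b.ravel()[perm].reshape(b.shape)
        assert dice_score(ap, bp) == dice_score(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_score(np.zeros((2, 2, 2), dtype=bool), np.zeros((3, 3, 3), dtype=bool))


class TestRegionDice:
    def test_self_comparison_is_perfect(self, small_phantom):
        _, labels = small_phantom
        assert region_dice(labels, labels) == (1.0, 1.0, 1.0)

    def test_background_only_prediction_scores_zero(self, small_phantom):
        _, labels = small_phantom
        empty = _lmap(np.zeros(labels.shape))
        assert region_dice(empty, labels) == (0.0, 0.0, 0.0)

    def test_toy_counts_match_voxel_counting_oracle(self):
        rng = np.random.default_rng(5)
        pred = _lmap(rng.choice([0, 1, 2, 4], size=(4, 4, 4)))
        truth = _lmap(rng.choice([0, 1, 2, 4], size=(4, 4, 4)))
        got = region_dice(pred, truth)
        for idx, labset in enumerate([{1, 2, 4}, {1, 4}, {4}]):
            inter = npred = ntrue = 0
            for p, t in zip(pred.labels.ravel(), truth.labels.ravel()):
                pin, tin = int(p) in labset, int(t) in labset
                npred += pin
                ntrue += tin
                inter += pin and tin
            expected = 1.0 if npred + ntrue == 0 else 2.0 * inter / (npred + ntrue)
            assert got[idx] == pytest.approx(expected, abs=0)

    def test_unknown_labels_named_in_error(self):
        bad = _lmap(np.full((2, 2, 2), 3))
        good = _lmap(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="3"):
            region_dice(bad, good)

    def test_region_masks_nested(self, small_phantom):
        _, labels = small_phantom
        rm = RegionMasks.from_labels(labels)
        assert np.all(rm.whole[rm.core])
        assert np.all(rm.core[rm.enhancing])


class TestMulticlassDiceLoss:
    def test_perfect_agreement_is_minus_one(self):
        truth = np.zeros((10, 3))
        truth[np.arange(10), np.arange(10) % 3] = 1.0
        loss = multiclass_dice_loss(DiceInputs(soft_pred=truth, one_hot_truth=truth))
        assert loss == pytest.approx(-1.0, abs=1e-12)

    def test_complete_disagreement_is_zero(self):
        pred = np.zeros((4, 2))
        truth = np.zeros((4, 2))
        pred[:, 0] = 1.0
        truth[:, 1] = 1.0
        assert multiclass_dice_loss(DiceInputs(pred, truth)) == 0.0

    def test_uniform_prediction_toy(self):
        # K=2, 4 voxels, l=0.5 everywhere, 2 truth voxels per class:
        # each class term = 1/(2+2) ... = 1/4, loss = -(2/2)(1/4+1/4) = -0.5
        pred = np.full((4, 2), 0.5)
        truth = np.zeros((4, 2))
        truth[:2, 0] = 1.0
        truth[2:, 1] = 1.0
        assert multiclass_dice_loss(DiceInputs(pred, truth)) == pytest.approx(-0.5, abs=1e-12)

    def test_binary_prediction_term_halves_set_dice(self, rng):
        # with hard one-hot predictions, each class term equals dice/2
        pred_lbl = rng.integers(0, 2, 50)
        true_lbl = rng.integers(0, 2, 50)
        pred = np.eye(2)[pred_lbl]
        truth = np.eye(2)[true_lbl]
        loss = multiclass_dice_loss(DiceInputs(pred, truth))
        dices = []
        for k in (0, 1):
            dices.append(dice_score((pred_lbl == k).reshape(5, 5, 2), (true_lbl == k).reshape(5, 5, 2)))
        assert loss == pytest.approx(-np.mean(dices), abs=1e-12)

    def test_bounded_for_random_soft_inputs(self, rng):
        for _ in range(20):
            raw = rng.random((30, 3))
            pred = raw / raw.sum(axis=1, keepdims=True)
            truth = np.eye(3)[rng.integers(0, 3, 30)]
            loss = multiclass_dice_loss(DiceInputs(pred, truth))
            assert -1.0 <= loss <= 0.0

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            DiceInputs(np.full((4, 2), 0.3), np.eye(2)[[0, 1, 0, 1]])  # rows don't sum to 1
        with pytest.raises(ValueError):
            DiceInputs(np.full((4, 2), 0.5), np.full((4, 2), 0.5))  # truth not one-hot
        with pytest.raises(ValueError):
            DiceInputs(np.full((4, 2), 0.5), np.eye(2)[[0, 1, 0]])  # shape mismatch


class TestImageQuality:
    def test_identity_and_constant_offset(self, small_phantom):
        vol, _ = small_phantom
        rmse, psnr, ratio = image_quality(vol, vol)
        assert rmse == 0.0 and psnr == float("inf") and ratio == 1.0
        off = vol.with_data(vol.data + 3.0)
        rmse, _, _ = image_quality(off, vol)
        assert rmse == pytest.approx(3.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        a = Volume3D(rng.random((6, 6, 6)) + 0.5)
        b = Volume3D(rng.random((6, 6, 6)) + 0.5)
        mask = rng.random((6, 6, 6)) > 0.3
        rmse, psnr, ratio = image_quality(a, b, mask)
        sq = 0.0
        sa = sb = 0.0
        n = 0
        bvals = []
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    if mask[i, j, k]:
                        d = a.data[i, j, k] - b.data[i, j, k]
                        sq += d * d
                        sa += a.data[i, j, k]
                        sb += b.data[i, j, k]
                        bvals.append(b.data[i, j, k])
                        n += 1
        exp_rmse = np.sqrt(sq / n)
        assert abs(rmse - exp_rmse) < 1e-10
        assert abs(ratio - (sa / n) / (sb / n)) < 1e-10
        assert abs(psnr - 20 * np.log10((max(bvals) - min(bvals)) / exp_rmse)) < 1e-10

    def test_shape_mismatch_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValueError):
            image_quality(vol, Volume3D(np.ones((2, 2, 2))))
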