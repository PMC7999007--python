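import itertools

import numpy as np
import pytest

from craniomsp.metrics import (
    ConfusionCounts,
    confusion_from_labels,
    confusion_rates,
    dice,
    full_report,
    hausdorff,
    quality_indices,
    svd,
)
from craniomsp.volume_io import Volume

from conftest import random_mask


def brute_force_hausdorff(a, b, spacing=(1.0, 1.0, 1.0)):
    """O(n^2) max-min oracle over boundary voxels."""
    from scipy import ndimage

    def boundary(m):
        return np.argwhere(m & ~ndimage.binary_erosion(m)) * np.asarray(spacing)

    pa, pb = boundary(a), boundary(b)
    h_ab = max(min(np.linalg.norm(p - q) for q in pb) for p in pa)
    h_ba = max(min(np.linalg.norm(p - q) for q in pa) for p in pb)
    return max(h_ab, h_ba)


class TestDice:
    def test_identical_masks(self, small_phantom):
        assert dice(small_phantom, small_phantom) == 1.0
        assert svd(small_phantom, small_phantom) == 0.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        a[0], b[2] = 1, 1
        assert dice(Volume(a), Volume(b)) == 0.0
        assert svd(Volume(a), Volume(b)) == 1.0

    def test_hand_computed_counts(self):
        # TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1) = 2/3
        a = np.zeros((1, 1, 4), np.uint8)
        b = np.zeros((1, 1, 4), np.uint8)
        a[0, 0, :3] = 1  # truth: 3 voxels
        b[0, 0, 1:4] = 1  # pred: voxels 1,2 overlap, 3 extra
        got = dice(Volume(a), Volume(b))
        assert got == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))
        assert svd(Volume(a), Volume(b)) == pytest.approx(1 / 3)

    def test_both_empty_is_perfect_agreement(self):
        z = Volume(np.zeros((3, 3, 3), np.uint8))
        assert dice(z, z) == 1.0

    def test_symmetry_property(self, rng):
        a = random_mask(rng, (8, 8, 8))
        b = random_mask(rng, (8, 8, 8))
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            dice(Volume(np.zeros((2, 2, 2))), Volume(np.zeros((3, 3, 3))))


class TestHausdorff:
    def test_identical_masks_zero(self, small_phantom):
        assert hausdorff(small_phantom, small_phantom) == 0.0

    def test_two_single_voxels(self):
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[1, 1, 1] = 1
        b[4, 1, 1] = 1
        assert hausdorff(Volume(a), Volume(b)) == 3.0

    def test_spacing_applied_in_mm(self):
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[1, 1, 1], b[4, 1, 1] = 1, 1
        sp = (0.5, 1.0, 1.0)
        assert hausdorff(Volume(a, sp), Volume(b, sp)) == 1.5
        assert hausdorff(Volume(a, sp), Volume(b, sp), units="voxels") == 3.0

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(5):
            a = random_mask(rng, (12, 12, 12), 0.4)
            b = random_mask(rng, (12, 12, 12), 0.4)
            got = hausdorff(a, b)
            want = brute_force_hausdorff(a.mask_array(), b.mask_array())
            assert got == pytest.approx(want)

    def test_symmetric_and_triangle_inequality(self, rng):
        masks = [random_mask(rng, (8, 8, 8), 0.3) for _ in range(3)]
        for a, b in itertools.permutations(masks, 2):
            assert hausdorff(a, b) == hausdorff(b, a)
        d = {
            (i, j): hausdorff(masks[i], masks[j])
            for i, j in itertools.combinations(range(3), 2)
        }
        assert d[(0, 2)] <= d[(0, 1)] + d[(1, 2)] + 1e-9

    def test_empty_mask_errors(self, small_phantom):
        with pytest.raises(ValueError, match="empty"):
            hausdorff(small_phantom,
                      Volume(np.zeros(small_phantom.shape, np.uint8)))


class TestConfusionRates:
    def test_perfect_sensitivity(self):
        r = confusion_rates(ConfusionCounts(tp=5, fp=0, fn=0, tn=0))
        assert r.sensitivity == 1.0

    def test_hand_arithmetic(self):
        r = confusion_rates(ConfusionCounts(tp=3, fp=2, fn=1, tn=8))
        assert r.sensitivity == pytest.approx(3 / 4)
        assert r.specificity == pytest.approx(8 / 10)
        assert r.ppv == pytest.approx(3 / 5)
        assert r.npv == pytest.approx(8 / 9)

    def test_zero_denominator_is_none_not_nan(self):
        r = confusion_rates(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert r.sensitivity is None
        assert r.specificity == 1.0

    def test_multiclass_macro_average_against_direct_reduction(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        rep = confusion_from_labels(y_true, y_pred, 4)
        sens = []
        for c in range(4):
            tp = int(((y_true == c) & (y_pred == c)).sum())
            fn = int(((y_true == c) & (y_pred != c)).sum())
            if tp + fn:
                sens.append(tp / (tp + fn))
        assert rep.sensitivity == pytest.approx(np.mean(sens))


class TestQualityIndices:
    IDEAL = dict(ad=0, iqi=1, lmse=0, md=0, mse=0, nae=0, nk=1, sc=1, ssim=1)

    def test_identical_volumes_give_exact_ideal_values(self, small_phantom):
        rep = quality_indices(small_phantom, small_phantom)
        for key, want in self.IDEAL.items():
            assert getattr(rep, key) == want, key

    def test_constant_shift(self, rng):
        ref = Volume(rng.random((8, 8, 8)) * 10)
        test = Volume(ref.data + 2.0)
        rep = quality_indices(ref, test)
        assert rep.ad == pytest.approx(-2.0)
        assert rep.md == pytest.approx(2.0)
        assert rep.mse == pytest.approx(4.0)

    def test_direct_formula_oracle_on_random_pair(self, rng):
        r = rng.random((16, 16, 16))
        t = rng.random((16, 16, 16))
        rep = quality_indices(Volume(r), Volume(t))
        d = r - t
        assert rep.ad == pytest.approx(d.mean())
        assert rep.md == pytest.approx(np.abs(d).max())
        assert rep.mse == pytest.approx((d**2).mean())
        assert rep.nae == pytest.approx(np.abs(d).sum() / np.abs(r).sum())
        assert rep.nk == pytest.approx((r * t).sum() / (r**2).sum())
        assert rep.sc == pytest.approx((r**2).sum() / (t**2).sum())
        # Laplacian MSE oracle: explicit 6-neighbor stencil on interior
        def lap(f):
            out = np.zeros((14, 14, 14))
            for i in range(1, 15):
                for j in range(1, 15):
                    for k in range(1, 15):
                        out[i - 1, j - 1, k - 1] = (
                            f[i - 1, j, k] + f[i + 1, j, k] + f[i, j - 1, k]
                            + f[i, j + 1, k] + f[i, j, k - 1] + f[i, j, k + 1]
                            - 6 * f[i, j, k]
                        )
            return out

        lr_, lt_ = lap(r), lap(t)
        assert rep.lmse == pytest.approx(
            ((lr_ - lt_) ** 2).sum() / (lr_**2).sum()
        )
        # universal quality index, global window
        mr, mt = r.mean(), t.mean()
        num = 4 * ((r - mr) * (t - mt)).mean() * mr * mt
        den = (r.var() + t.var()) * (mr**2 + mt**2)
        assert rep.iqi == pytest.approx(num / den)
        assert -1 <= rep.ssim <= 1

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            quality_indices(Volume(np.ones((2, 2, 2))),
                            Volume(np.ones((3, 3, 3))))


class TestFullReport:
    def test_report_on_identical_masks(self, small_phantom):
        rep = full_report(small_phantom, small_phantom)
        assert rep.dsc == 1.0 and rep.svd == 0.0 and rep.hd_mm == 0.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.ssim == 1

    def test_json_round_trip_keys(self, small_phantom):
        import json

        rep = full_report(small_phantom, small_phantom)
        d = json.loads(rep.to_json())
        assert set(d) == set(rep.to_dict())
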