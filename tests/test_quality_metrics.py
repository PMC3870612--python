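"""MSR/CNR/CIR/PSNR against hand computations and brute-force oracles,
plus observer-score aggregation."""
import math

import numpy as np
import pytest

from waveclear import (
    ImageGrid,
    RegionSpec,
    ScoreTable,
    aggregate_preference_scores,
    cir,
    cnr,
    msr,
    psnr,
)
from waveclear.datasets import CHEST_PREFERENCE_SCORES, MAMMOGRAM_PREFERENCE_SCORES
from waveclear.errors import DegenerateRegionError, InputShapeError, ValidationError

from _oracles import cir_oracle, cnr_oracle, msr_oracle, psnr_oracle


def _checkerboard(rows, cols, lo, hi):
    out = np.full((rows, cols), lo, dtype=float)
    out[(np.indices((rows, cols)).sum(axis=0) % 2) == 1] = hi
    return out


class TestMSR:
    def test_alternating_region_hand_value(self):
        img = _checkerboard(8, 8, 90.0, 110.0)
        assert msr(img, RegionSpec(0, 0, 8, 8)) == pytest.approx(10.0)

    def test_constant_region_raises(self):
        with pytest.raises(DegenerateRegionError):
            msr(np.full((8, 8), 50.0), RegionSpec(0, 0, 4, 4))

    def test_scale_invariance(self, rng):
        img = rng.uniform(10, 200, size=(16, 16))
        roi = RegionSpec(2, 3, 12, 13)
        assert msr(img, roi) == pytest.approx(msr(3.7 * img, roi), rel=1e-12)

    def test_matches_brute_force(self, rng):
        img = rng.uniform(0, 255, size=(32, 32))
        roi = RegionSpec(4, 6, 20, 30)
        expected = msr_oracle(img[4:20, 6:30])
        assert msr(img, roi) == pytest.approx(expected, rel=1e-10)

    def test_region_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            msr(np.zeros((8, 8)), RegionSpec(0, 0, 9, 4))


class TestCNR:
    def test_hand_value(self):
        img = np.zeros((8, 16))
        img[:, :8] = _checkerboard(8, 8, 90.0, 110.0)
        img[:, 8:] = _checkerboard(8, 8, 40.0, 60.0)
        droi = RegionSpec(0, 0, 8, 8)
        uroi = RegionSpec(0, 8, 8, 16)
        assert cnr(img, droi, uroi) == pytest.approx(5.0)

    def test_identical_statistics_give_zero(self, rng):
        block = rng.uniform(0, 100, size=(8, 8))
        img = np.hstack([block, block])
        assert cnr(img, RegionSpec(0, 0, 8, 8), RegionSpec(0, 8, 8, 16)) == 0.0

    def test_symmetric_in_regions(self, rng):
        img = rng.uniform(0, 255, size=(16, 16))
        droi = RegionSpec(0, 0, 8, 8)
        uroi = RegionSpec(8, 8, 16, 16)
        assert cnr(img, droi, uroi) == pytest.approx(cnr(img, uroi, droi))

    def test_offset_invariance(self, rng):
        img = rng.uniform(0, 200, size=(16, 16))
        droi = RegionSpec(0, 0, 8, 8)
        uroi = RegionSpec(8, 0, 16, 8)
        assert cnr(img + 31.0, droi, uroi) == pytest.approx(
            cnr(img, droi, uroi), rel=1e-12
        )

    def test_matches_brute_force(self, rng):
        img = rng.uniform(0, 255, size=(32, 32))
        droi = RegionSpec(1, 2, 15, 17)
        uroi = RegionSpec(16, 3, 30, 29)
        expected = cnr_oracle(img[1:15, 2:17], img[16:30, 3:29])
        assert cnr(img, droi, uroi) == pytest.approx(expected, rel=1e-10)

    def test_both_regions_constant_raises(self):
        img = np.full((8, 8), 7.0)
        with pytest.raises(DegenerateRegionError):
            cnr(img, RegionSpec(0, 0, 4, 4), RegionSpec(4, 4, 8, 8))


class TestCIR:
    def test_identical_images_give_zero(self, rng):
        img = rng.uniform(0, 255, size=(16, 16))
        assert cir(img, img.copy()) == 0.0

    def test_constant_original_raises(self, rng):
        with pytest.raises(DegenerateRegionError):
            cir(np.full((16, 16), 9.0), rng.uniform(0, 255, size=(16, 16)))

    def test_matches_sliding_window_oracle(self, rng):
        orig = rng.uniform(0, 255, size=(9, 9))
        enh = rng.uniform(0, 255, size=(9, 9))
        assert cir(orig, enh) == pytest.approx(cir_oracle(orig, enh), rel=1e-10)

    def test_matches_oracle_32x32(self, rng):
        orig = rng.uniform(0, 255, size=(32, 32))
        enh = orig * 1.2 + rng.normal(size=(32, 32))
        assert cir(orig, enh) == pytest.approx(cir_oracle(orig, enh), rel=1e-10)

    def test_nonnegative(self, rng):
        orig = rng.uniform(0, 255, size=(16, 16))
        enh = rng.uniform(0, 255, size=(16, 16))
        assert cir(orig, enh) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputShapeError):
            cir(np.zeros((16, 16)), np.zeros((16, 18)))


class TestPSNR:
    def test_identical_images_give_infinity(self, rng):
        img = ImageGrid(rng.uniform(0, 255, size=(8, 8)))
        assert psnr(img, ImageGrid(img.pixels.copy())) == math.inf

    def test_single_pixel_closed_form(self):
        ref = np.zeros((16, 16))
        proc = ref.copy()
        proc[4, 7] = 255.0
        expected = 10 * math.log10(256 * 255**2 / 255**2)  # = 10 log10(256)
        assert psnr(ImageGrid(ref), ImageGrid(proc)) == pytest.approx(expected)
        assert expected == pytest.approx(24.0824, abs=1e-4)

    def test_symmetric(self, rng):
        a = ImageGrid(rng.uniform(0, 255, size=(16, 16)))
        b = ImageGrid(rng.uniform(0, 255, size=(16, 16)))
        assert psnr(a, b) == pytest.approx(psnr(b, a))

    def test_matches_brute_force(self, rng):
        a = rng.uniform(0, 255, size=(32, 32))
        b = rng.uniform(0, 255, size=(32, 32))
        expected = psnr_oracle(a, b, 8)
        assert psnr(ImageGrid(a), ImageGrid(b)) == pytest.approx(expected, rel=1e-10)

    def test_monotonically_decreasing_in_noise(self):
        rng = np.random.default_rng(0)
        ref = ImageGrid(rng.uniform(50, 200, size=(64, 64)))
        means = []
        for sigma in (0.005, 0.01, 0.02):
            vals = [
                psnr(
                    ref,
                    ImageGrid(
                        ref.pixels
                        + np.random.default_rng(seed).normal(0, sigma * 255, (64, 64))
                    ),
                )
                for seed in range(10)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_bit_depth_mismatch_rejected(self, rng):
        a = ImageGrid(rng.uniform(0, 255, size=(8, 8)), bit_depth=8)
        b = ImageGrid(a.pixels + 1, bit_depth=12)
        with pytest.raises(InputShapeError):
            psnr(a, b)


class TestScoreAggregation:
    def test_mammogram_table_sums(self):
        sums, _ = aggregate_preference_scores(MAMMOGRAM_PREFERENCE_SCORES)
        assert sums[("sigmoid", "udwt")] == pytest.approx(-4.37)
        assert sums[("sigmoid", "combined")] == pytest.approx(-7.71)
        assert sums[("udwt", "combined")] == pytest.approx(-6.87)

    def test_chest_table_sums(self):
        sums, _ = aggregate_preference_scores(CHEST_PREFERENCE_SCORES)
        assert sums[("sigmoid", "udwt")] == pytest.approx(-3.7)
        assert sums[("sigmoid", "combined")] == pytest.approx(-7.5)
        assert sums[("udwt", "combined")] == pytest.approx(-7.3)

    def test_preference_degrees_sum_to_zero(self):
        # main effects of a complete paired comparison balance out
        for table in (MAMMOGRAM_PREFERENCE_SCORES, CHEST_PREFERENCE_SCORES):
            _, degrees = aggregate_preference_scores(table)
            assert sum(degrees.values()) == pytest.approx(0.0, abs=1e-12)
            assert degrees["combined"] == max(degrees.values())

    def test_all_zero_scores(self):
        table = ScoreTable(
            combinations=[("a", "b"), ("a", "c")],
            scores=[[0.0, 0.0], [0.0, 0.0]],
        )
        sums, degrees = aggregate_preference_scores(table)
        assert all(v == 0.0 for v in sums.values())
        assert all(v == 0.0 for v in degrees.values())

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValidationError):
            ScoreTable(combinations=[("a", "b")], scores=[[2.5]])

    def test_inconsistent_observer_count_rejected(self):
        with pytest.raises(ValidationError):
            ScoreTable(
                combinations=[("a", "b"), ("a", "c")],
                scores=[[1.0, 0.0], [1.0]],
            )
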