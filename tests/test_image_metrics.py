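"""Unit and property tests for the per-image scalar measurements."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import punctatrack as pt
from punctatrack.errors import (
    DegenerateBaselineError,
    DegenerateInputError,
    InsufficientRoiError,
    InvalidParamsError,
    UndefinedCorrelationError,
)

from conftest import brute_median_ratio


class TestMedianRatio:
    def test_constant_image_gives_unit_ratio(self):
        img = pt.FluorescenceImage(np.full((20, 20), 7.0))
        ratio = pt.median_ratio_image(img, window=5)
        assert np.allclose(ratio.data, 1.0)

    @pytest.mark.parametrize("c", [0.1, 3.0, 10.0])
    def test_scale_factor_cancels(self, c, rng):
        data = rng.uniform(5, 50, size=(24, 24))
        r1 = pt.median_ratio_image(pt.FluorescenceImage(data), 5).data
        r2 = pt.median_ratio_image(pt.FluorescenceImage(data * c), 5).data
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_center_spike_on_constant_background(self):
        # one hot pixel over a flat field: the 3x3 median everywhere is the
        # background, so the ratio is value/background at the spike and 1 off it
        data = np.full((9, 9), 10.0)
        data[4, 4] = 100.0
        ratio = pt.median_ratio_image(pt.FluorescenceImage(data), 3).data
        assert ratio[4, 4] == pytest.approx(10.0)
        off = np.ones_like(data, dtype=bool)
        off[4, 4] = False
        assert np.allclose(ratio[off], 1.0)

    @pytest.mark.parametrize("window", [3, 4, 5, 10])
    def test_matches_bruteforce_oracle(self, window, rng):
        data = rng.uniform(1, 100, size=(27, 31))
        got = pt.median_ratio_image(pt.FluorescenceImage(data), window).data
        np.testing.assert_array_equal(got, brute_median_ratio(data, window))

    def test_all_zero_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            pt.median_ratio_image(pt.FluorescenceImage(np.zeros((20, 20))), 5)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(InvalidParamsError):
            pt.median_ratio_image(pt.FluorescenceImage(np.ones((8, 8))), 9)


class TestPunctaIndex:
    def test_constant_image_sd_zero(self):
        img = pt.FluorescenceImage(np.full((30, 30), 42.0))
        mask = pt.RoiMask(np.ones((30, 30), bool))
        assert pt.puncta_index(img, mask, variant="sd").value == pytest.approx(0.0)

    def test_symmetric_ratio_skewness_zero(self):
        # two isolated excursions, one up one down by the same relative
        # amount, leave the masked ratio distribution symmetric
        data = np.full((40, 40), 10.0)
        data[10, 10] = 12.0
        data[30, 30] = 8.0
        img = pt.FluorescenceImage(data)
        mask = pt.RoiMask(np.ones((40, 40), bool))
        res = pt.puncta_index(img, mask, window=3, variant="skewness")
        assert res.value == pytest.approx(0.0, abs=1e-10)

    def test_matches_straight_line_oracle(self):
        params = pt.ImageSimParams(seed=11, n_puncta=50, puncta_amplitude=500.0,
                                   shape=(128, 128), radius=50)
        img, mask, _ = pt.simulate_cell_image(params)
        res = pt.puncta_index(img, mask, window=5, variant="sd")
        vals = brute_median_ratio(img.data, 5)[mask.data]
        expect = np.sqrt(((vals - vals.mean()) ** 2).sum() / (len(vals) - 1))
        assert res.value == pytest.approx(expect, rel=1e-12)
        assert res.n_pixels == mask.n_pixels

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_property(self, c):
        rng = np.random.default_rng(7)
        data = rng.uniform(5, 50, size=(24, 24))
        mask = pt.RoiMask(np.ones((24, 24), bool))
        v1 = pt.puncta_index(pt.FluorescenceImage(data), mask).value
        v2 = pt.puncta_index(pt.FluorescenceImage(data * c), mask).value
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_translation_covariance(self, rng):
        # shift image+mask together by (3, 5); interior ROI keeps the shifted
        # pixels clear of the border band so the metric is unchanged
        data = rng.uniform(5, 50, size=(40, 40))
        inner = np.zeros((40, 40), bool)
        inner[10:25, 10:25] = True
        big = np.pad(data, ((3, 0), (5, 0)), mode="symmetric")[:40, :40]
        big[3:, 5:] = data[:37, :35]
        shifted_mask = np.zeros((40, 40), bool)
        shifted_mask[13:28, 15:30] = True
        v1 = pt.puncta_index(pt.FluorescenceImage(data), pt.RoiMask(inner)).value
        v2 = pt.puncta_index(pt.FluorescenceImage(big), pt.RoiMask(shifted_mask)).value
        assert v2 == pytest.approx(v1, rel=1e-12)

    def test_monotone_in_amplitude(self):
        amps = [50.0, 150.0, 300.0, 600.0, 1200.0]
        for seed in range(10):
            vals = []
            for a in amps:
                img, mask, _ = pt.simulate_cell_image(
                    pt.ImageSimParams(seed=seed, puncta_amplitude=a,
                                      shape=(128, 128), radius=50)
                )
                vals.append(pt.puncta_index(img, mask).value)
            assert all(b >= a for a, b in zip(vals, vals[1:])), (seed, vals)

    def test_small_roi_rejected(self):
        img = pt.FluorescenceImage(np.random.default_rng(0).uniform(1, 2, (30, 30)))
        mask = np.zeros((30, 30), bool)
        mask[10:14, 10:14] = True  # 16 px <= 5*5
        with pytest.raises(InsufficientRoiError):
            pt.puncta_index(img, pt.RoiMask(mask), window=5)


class TestPearson:
    def test_identity_and_negation(self, small_image):
        img, mask = small_image
        assert pt.pearson_colocalization(img, img, mask) == pytest.approx(1.0)
        neg = pt.FluorescenceImage(img.data.max() - img.data)
        assert pt.pearson_colocalization(img, neg, mask) == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        # 100 seeds, 1e4 masked pixels each: |r| stays small
        mask = pt.RoiMask(np.ones((100, 100), bool))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = pt.FluorescenceImage(rng.uniform(0, 100, (100, 100)))
            b = pt.FluorescenceImage(rng.uniform(0, 100, (100, 100)))
            assert abs(pt.pearson_colocalization(a, b, mask)) < 0.05

    def test_two_pixel_closed_form(self):
        # with exactly two masked pixels r is +-1 by the two-point formula
        mask = np.zeros((16, 16), bool)
        mask[0, 0] = mask[8, 8] = True
        a = np.ones((16, 16))
        b = np.ones((16, 16))
        a[0, 0], a[8, 8] = 1.0, 5.0
        b[0, 0], b[8, 8] = 2.0, 9.0
        r = pt.pearson_colocalization(
            pt.FluorescenceImage(a), pt.FluorescenceImage(b), pt.RoiMask(mask)
        )
        assert r == pytest.approx(1.0)
        b[0, 0], b[8, 8] = 9.0, 2.0
        r = pt.pearson_colocalization(
            pt.FluorescenceImage(a), pt.FluorescenceImage(b), pt.RoiMask(mask)
        )
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self, small_image):
        img, mask = small_image
        flat = pt.FluorescenceImage(np.full(img.shape, 3.0))
        with pytest.raises(UndefinedCorrelationError):
            pt.pearson_colocalization(img, flat, mask)


class TestCoRecruitment:
    def test_constant_prey_gives_unit_ci(self):
        t = np.arange(10.0)
        s = pt.RecruitmentSeries(t, np.linspace(100, 200, 10), np.full(10, 50.0), 5)
        assert pt.co_recruitment_index(s).ci == pytest.approx(1.0)

    def test_bait_gate_excludes_weak_recruitment(self):
        cells, _ = pt.simulate_recruitment_series(
            bait_fold=1.2, prey_fold=2.0, noise_sigma=0.0, n_cells=1, seed=0
        )
        res = pt.co_recruitment_index(cells[0])
        assert not res.included
        assert res.bait_fold == pytest.approx(1.2)

    def test_noise_free_fold_recovered_exactly(self):
        cells, _ = pt.simulate_recruitment_series(
            bait_fold=2.0, prey_fold=1.23, noise_sigma=0.0, n_cells=1, seed=0,
            frames_post=20, rise_time=5.0,
        )
        res = pt.co_recruitment_index(cells[0])
        assert res.ci == 1.23
        assert res.included

    def test_gate_boundary_is_inclusive(self):
        # a bait fold of exactly 1.30 satisfies "at least 30% increase"
        t = np.arange(4.0)
        s = pt.RecruitmentSeries(t, [1.0, 1.0, 1.3, 1.3], [1.0, 1.0, 1.0, 1.0], 2)
        res = pt.co_recruitment_index(s, response_frames=1)
        assert res.bait_fold == 1.3
        assert res.included

    def test_degenerate_baseline_rejected(self):
        t = np.arange(6.0)
        s = pt.RecruitmentSeries(t, np.zeros(6), np.ones(6), 3)
        with pytest.raises(DegenerateBaselineError):
            pt.co_recruitment_index(s)

    def test_background_subtraction_applied(self):
        t = np.arange(4.0)
        s = pt.RecruitmentSeries(t, [20.0, 20.0, 30.0, 30.0], [15.0, 15.0, 25.0, 25.0],
                                 2, background=(10.0, 5.0))
        res = pt.co_recruitment_index(s, response_frames=2)
        assert res.bait_fold == pytest.approx(2.0)
        assert res.ci == pytest.approx(2.0)


class TestTranslocationAndFriends:
    def test_translocation_examples(self):
        assert pt.translocation_index([10, 10, 10, 10], 2) == pytest.approx(0.0)
        assert pt.translocation_index([10, 10, 5, 5], 2) == pytest.approx(0.5)
        with pytest.warns(UserWarning):
            assert pt.translocation_index([10, 10, 20, 20], 2) == 0.0
        with pytest.raises(DegenerateBaselineError):
            pt.translocation_index([0.0, 0.0, 1.0], 2)

    def test_fa_enrichment_arithmetic(self):
        data = np.ones((20, 20))
        fa = np.zeros((20, 20), bool)
        cyt = np.zeros((20, 20), bool)
        fa[2:5, 2:5] = True
        cyt[10:15, 10:15] = True
        img = pt.FluorescenceImage(data)
        assert pt.fa_enrichment(img, pt.RoiMask(fa, "focal_adhesion"),
                                pt.RoiMask(cyt, "cytosol")) == pytest.approx(1.0)
        data2 = data.copy()
        data2[fa] = 2.0
        assert pt.fa_enrichment(pt.FluorescenceImage(data2),
                                pt.RoiMask(fa, "focal_adhesion"),
                                pt.RoiMask(cyt, "cytosol")) == pytest.approx(2.0)

    def test_fa_enrichment_overlap_rejected(self):
        m = np.zeros((20, 20), bool)
        m[5:10, 5:10] = True
        img = pt.FluorescenceImage(np.ones((20, 20)))
        with pytest.raises(InvalidParamsError):
            pt.fa_enrichment(img, pt.RoiMask(m, "focal_adhesion"), pt.RoiMask(m, "cytosol"))

    def test_timecourse_normalize(self):
        v = np.array([4.0, 8.0, 2.0])
        out = pt.timecourse_normalize(v, 0)
        assert out[0] == 1.0
        np.testing.assert_allclose(out, [1.0, 2.0, 0.5])
        np.testing.assert_allclose(pt.timecourse_normalize(2 * v, 0), out)
        np.testing.assert_allclose(pt.timecourse_normalize(np.full(5, 3.0)), np.ones(5))
        with pytest.raises(DegenerateBaselineError):
            pt.timecourse_normalize([0.0, 1.0], 0)

    def test_cytosolic_uptake(self):
        img = pt.FluorescenceImage(np.full((20, 20), 100.0))
        mask = pt.RoiMask(np.ones((20, 20), bool), "cell")
        assert pt.cytosolic_uptake(img, mask, background=20.0) == pytest.approx(80.0)
        assert pt.cytosolic_uptake(img, mask, background=150.0) == 0.0

    def test_cytosolic_uptake_locality(self, rng):
        data = rng.uniform(10, 50, (30, 30))
        img = pt.FluorescenceImage(data)
        m1 = np.zeros((30, 30), bool)
        m2 = np.zeros((30, 30), bool)
        m1[2:10, 2:10] = True
        m2[20:28, 20:28] = True
        v1 = pt.cytosolic_uptake(img, pt.RoiMask(m1, "cell"))
        v2 = pt.cytosolic_uptake(img, pt.RoiMask(m2, "cell"))
        assert v1 == pytest.approx(data[m1].mean())
        assert v2 == pytest.approx(data[m2].mean())
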