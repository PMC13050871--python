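"""Unit and oracle tests for the 2D-STED cluster-segmentation routine."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from ribbonquant.core import DegenerateInputError, Frame2D, InsufficientDataError
from ribbonquant.sted2d import (
    AreaPair,
    analyze_pair,
    correlate_pairs,
    filter_and_fit,
    gaussian_blur,
    kapur_threshold,
    max_entropy_threshold,
    segment_frame,
    watershed_split,
)
from ribbonquant.synthetic import make_sted_pair_frames


def kapur_bruteforce(values, n_bins=256):
    """Independent enumeration oracle: evaluate the Kapur objective at every
    interior bin edge by direct probability sums."""
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    p = counts / counts.sum()
    best, best_t = -np.inf, None
    for t in range(n_bins - 1):  # threshold after bin t
        p0, p1 = p[: t + 1], p[t + 1 :]
        w0, w1 = p0.sum(), p1.sum()
        if w0 == 0 or w1 == 0:
            continue
        q0 = p0[p0 > 0] / w0
        q1 = p1[p1 > 0] / w1
        h = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
        if h > best:
            best, best_t = h, t
    return float(edges[best_t + 1])


class TestGaussianBlur:
    def test_constant_frame_unchanged(self):
        f = Frame2D(np.full((32, 32), 7.0))
        out = gaussian_blur(f, 1.0)
        np.testing.assert_allclose(out.intensity, 7.0, rtol=1e-12)

    def test_impulse_matches_dense_convolution(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = gaussian_blur(Frame2D(img), 1.0).intensity
        # dense separable-kernel oracle, sampled at sigma = 1 px with the
        # filter's documented 4-sigma support
        k1 = np.exp(-np.arange(-4, 5) ** 2 / 2.0)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        np.testing.assert_allclose(out[16:25, 16:25], kernel, rtol=1e-6, atol=1e-15)

    def test_total_intensity_conserved(self):
        img = np.zeros((51, 51))
        img[25, 25] = 3.0
        out = gaussian_blur(Frame2D(img), 1.0).intensity
        assert abs(out.sum() - 3.0) < 1e-9 * 3.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_blur(Frame2D(np.ones((4, 4))), 0.0)


class TestMaxEntropyThreshold:
    def test_two_level_frame_separates_populations(self):
        rng = np.random.default_rng(0)
        img = np.full((50, 50), 10.0)
        bright = rng.choice(2500, size=250, replace=False)
        img.ravel()[bright] = 200.0
        f = Frame2D(img)
        t = max_entropy_threshold(f)
        assert 10.0 <= t < 200.0
        assert (img > t).sum() == 250

    @pytest.mark.parametrize("seed", [42, 7, 99])
    def test_equals_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(64, 64)).astype(float)
        assert max_entropy_threshold(Frame2D(img)) == pytest.approx(
            kapur_bruteforce(img), abs=0
        )

    def test_constant_frame_raises(self):
        with pytest.raises(DegenerateInputError):
            max_entropy_threshold(Frame2D(np.full((8, 8), 3.0)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_threshold_within_value_range(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.gamma(2.0, 10.0, size=(32, 32))
        t = kapur_threshold(img)
        assert img.min() <= t <= img.max()
        assert (img > t).any() and (img <= t).any()


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestWatershedSplit:
    def test_single_disc_one_label(self):
        labels = watershed_split(disc_mask((40, 40), 20, 20, 10))
        assert labels.max() == 1

    def test_two_overlapping_discs_split(self):
        mask = disc_mask((50, 60), 25, 22, 10) | disc_mask((50, 60), 25, 38, 10)
        # distance-transform oracle confirms two seed maxima
        import scipy.ndimage as ndi

        dist = ndi.distance_transform_edt(mask)
        assert dist[25, 22] >= 9 and dist[25, 38] >= 9
        labels = watershed_split(mask)
        assert labels.max() == 2
        assert labels[25, 22] != labels[25, 38]
        assert labels[25, 22] != 0 and labels[25, 38] != 0

    def test_empty_mask(self):
        labels = watershed_split(np.zeros((10, 10), dtype=bool))
        assert labels.max() == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_labels_partition_mask(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) > 0.6
        labels = watershed_split(mask)
        assert ((labels > 0) == mask).all()


class TestFilterAndFit:
    def test_strict_size_filter(self):
        labels = np.zeros((40, 80), dtype=int)
        labels[0:5, 0:10] = 1  # exactly 50 px
        labels[10:15, 0:10] = 2
        labels[10, 10] = 2  # 51 px
        frame = Frame2D(np.ones((40, 80)))
        regions = filter_and_fit(labels, frame, min_px=50)
        assert [r.label for r in regions] == [2]
        assert regions[0].pixel_count == 51

    def test_disc_fit_matches_analytic(self):
        r = 20
        mask = disc_mask((64, 64), 32, 32, r)
        labels = mask.astype(int)
        frame = Frame2D(np.ones((64, 64)), pixel_size_um=0.015)
        (region,) = filter_and_fit(labels, frame)
        assert region.area_um2 == pytest.approx(np.pi * r**2 * 0.015**2, rel=0.02)
        assert region.major_um / region.minor_um == pytest.approx(1.0, abs=0.05)
        assert region.major_um >= region.minor_um

    def test_empty_label_map(self):
        assert filter_and_fit(np.zeros((8, 8), dtype=int), Frame2D(np.ones((8, 8)))) == []


class TestCorrelatePairs:
    def _pairs(self, x, y):
        return [AreaPair(a, b, i) for i, (a, b) in enumerate(zip(x, y))]

    def test_identical_rank_order(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate_pairs(self._pairs(x, [2.0, 4.0, 5.0, 9.0]))
        assert res["spearman_rho"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate_pairs(self._pairs(x, [9.0, 5.0, 4.0, 2.0]))
        assert res["spearman_rho"] == pytest.approx(-1.0)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            correlate_pairs(self._pairs([1.0, 2.0], [1.0, 2.0]))

    def test_regression_matches_scipy(self, rng):
        x = rng.lognormal(0, 0.3, 30)
        y = 0.5 * x + rng.normal(0, 0.05, 30)
        res = correlate_pairs(self._pairs(x, y))
        fit = scipy.stats.linregress(x, y)
        assert res["slope"] == pytest.approx(fit.slope)
        assert res["slope_ci95"][0] < fit.slope < res["slope_ci95"][1]


class TestEndToEnd:
    def test_pair_count_and_area_recovery(self):
        """All generated cluster pairs are recovered and recovered areas
        preserve the true size ranking (default imaging noise)."""
        pairs, man = make_sted_pair_frames(40, 0.35, seed=5)
        true_a = [r**2 * np.pi for ch, c, r, i in man.puncta_true if ch == "ctbp2"]
        rec = [analyze_pair(a, b, frame_id=i) for i, (a, b) in enumerate(pairs)]
        assert all(r is not None for r in rec)
        rho = scipy.stats.spearmanr(true_a, [r.ribbon_area_um2 for r in rec]).statistic
        assert rho >= 0.95

    def test_noise_free_pair_count(self):
        """Noise-free: every frame whose blob exceeds the 51-px filter
        yields exactly one recovered object per channel."""
        pairs, man = make_sted_pair_frames(25, 0.0, seed=9, noise_sd=0.0)
        for a, b in pairs:
            for f in (a, b):
                regions = segment_frame(f)
                assert len(regions) == 1
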