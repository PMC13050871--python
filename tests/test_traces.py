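"""Tests for GCaMP and voltage trace analysis."""

import numpy as np
import pytest

from ribbonquant.core import DegenerateInputError, Trace
from ribbonquant.synthetic import make_gcamp_trace, make_voltage_trace
from ribbonquant.traces import (
    baseline_correct,
    detect_events,
    extract_trace,
    peak_frequency,
    roi_mask_from_movie,
)


def make_movie(n_frames=20, shape=(40, 40), blob=None, seed=0):
    rng = np.random.default_rng(seed)
    movie = rng.normal(10, 1, size=(n_frames,) + shape).clip(0)
    if blob is not None:
        cy, cx, r = blob
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        movie[n_frames // 2][disc] += 200.0
    return movie


class TestRoiMask:
    def test_flashing_blob_footprint(self):
        movie = np.zeros((10, 40, 40))
        yy, xx = np.mgrid[:40, :40]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 8**2
        movie[4][disc] = 100.0
        mask = roi_mask_from_movie(movie)
        assert (mask == disc).all()

    def test_min_size_monotone(self):
        movie = make_movie(blob=(20, 20, 8))
        areas = [roi_mask_from_movie(movie, min_size_px=m).sum() for m in (1, 20, 100, 10_000)]
        assert areas == sorted(areas, reverse=True)

    def test_threshold_matches_enumeration(self):
        from test_sted2d import kapur_bruteforce

        from ribbonquant.sted2d import kapur_threshold

        movie = make_movie(blob=(20, 20, 8), seed=3)
        mip = movie.max(axis=0)
        assert kapur_threshold(mip) == pytest.approx(kapur_bruteforce(mip), abs=0)

    def test_constant_movie_raises(self):
        with pytest.raises(DegenerateInputError):
            roi_mask_from_movie(np.full((5, 8, 8), 3.0))


class TestExtractTrace:
    def test_constant_movie(self):
        movie = np.full((6, 8, 8), 4.0)
        mask = np.ones((8, 8), bool)
        tr = extract_trace(movie, mask)
        assert np.allclose(tr.value, 4.0)

    def test_single_pixel_mask(self):
        movie = make_movie()
        mask = np.zeros((40, 40), bool)
        mask[3, 7] = True
        tr = extract_trace(movie, mask)
        np.testing.assert_allclose(tr.value, movie[:, 3, 7])

    def test_linearity(self):
        movie = make_movie()
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True
        np.testing.assert_allclose(
            extract_trace(3.0 * movie, mask).value, 3.0 * extract_trace(movie, mask).value
        )

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_trace(make_movie(), np.zeros((40, 40), bool))


class TestBaselineCorrect:
    def test_constant_trace_zeroed(self):
        tr = Trace(np.arange(10) * 0.78, np.full(10, 5.0))
        for mode in ("percentile", "initial"):
            assert np.allclose(baseline_correct(tr, mode).value, 0.0)

    def test_percentile_recovers_baseline(self):
        tr = make_gcamp_trace(600, list(np.arange(50, 600, 50.0)), noise_sd=0.02,
                              seed=8, baseline=2.0)
        corrected = baseline_correct(tr)
        # transients occupy a minority of samples: corrected baseline near 0
        assert abs(np.median(corrected.value)) < 0.1

    def test_invalid_mode(self):
        tr = Trace(np.arange(4) * 1.0, np.arange(4) * 1.0)
        with pytest.raises(ValueError):
            baseline_correct(tr, "bogus")


class TestPeakFrequency:
    def test_flat_trace(self):
        tr = Trace(np.arange(100) * 0.78, np.zeros(100))
        ps = peak_frequency(tr)
        assert ps.count == 0 and ps.frequency_per_min == 0.0

    def test_noise_free_count_and_frequency(self):
        dt = 0.78
        times = [round(t / dt) * dt for t in np.linspace(20, 580, 12)]
        tr = make_gcamp_trace(600, times, noise_sd=0.0)
        ps = peak_frequency(baseline_correct(tr))
        assert ps.count == 12
        assert ps.frequency_per_min == pytest.approx(12 / (tr.duration_s / 60.0))
        assert ps.frequency_per_min == pytest.approx(1.2, abs=0.01)

    def test_unresolvable_twin_peaks_merge(self):
        dt = 0.78
        tr = make_gcamp_trace(60, [30.0, 30.0 + 0.5 * dt], noise_sd=0.0)
        ps = peak_frequency(baseline_correct(tr))
        assert ps.count == 1

    def test_offset_invariance(self):
        dt = 0.78
        times = [round(t / dt) * dt for t in np.linspace(10, 110, 5)]
        tr = make_gcamp_trace(120, times, noise_sd=0.05, seed=2)
        c = baseline_correct(tr)
        shifted = Trace(c.time_s, c.value + 100.0)
        assert peak_frequency(baseline_correct(shifted)).count == peak_frequency(c).count


class TestDetectEvents:
    def test_never_above_threshold(self):
        tr = make_voltage_trace(5, [1.0, 2.0], rmp_mV=-70, spike_peak_mV=-50, noise_sd_mV=0.0)
        assert detect_events(tr).count == 0

    def test_rectangle_auc(self):
        dt = 0.001
        t = np.arange(0, 1, dt)
        v = np.full_like(t, -70.0)
        v[200:301] = -20.0  # plateau spans exactly 0.1 s of trapezoids
        ev = detect_events(Trace(t, v, kind="voltage"))
        assert ev.count == 1
        assert ev.aucs_mVs[0] == pytest.approx(5.0, rel=1e-9)

    def test_spike_train_count_and_auc(self):
        spikes = [1.0, 3.0, 5.0, 7.0]
        tr = make_voltage_trace(9, spikes, noise_sd_mV=0.0)
        ev = detect_events(tr)
        assert ev.count == len(spikes)
        true_auc = tr.meta["spike_integral_true_mVs"]
        np.testing.assert_allclose(ev.aucs_mVs, true_auc, rtol=0.05)

    def test_auc_scales_with_amplitude(self):
        a1 = detect_events(make_voltage_trace(5, [2.0], rmp_mV=-70, spike_peak_mV=-20,
                                              noise_sd_mV=0.0), threshold_mV=-50).aucs_mVs[0]
        a2 = detect_events(make_voltage_trace(5, [2.0], rmp_mV=-70, spike_peak_mV=-45,
                                              noise_sd_mV=0.0), threshold_mV=-50).aucs_mVs[0]
        assert a1 / a2 == pytest.approx(50.0 / 25.0, rel=0.02)

    def test_event_count_monotone_in_threshold(self):
        # clean trace: run-based detection has no near-threshold chatter
        tr = make_voltage_trace(20, list(np.arange(1.0, 19.0, 1.5)), noise_sd_mV=0.0)
        counts = [detect_events(tr, threshold_mV=thr).count for thr in (-45, -35, -25, -16, -10)]
        assert counts == sorted(counts, reverse=True)

    def test_offset_invariance_after_baseline(self):
        tr = make_voltage_trace(10, [2.0, 6.0], noise_sd_mV=0.0)
        ev = detect_events(tr)
        shifted = Trace(tr.time_s, tr.value + 7.0, kind="voltage")
        ev2 = detect_events(shifted, threshold_mV=-35 + 7.0)
        assert ev2.count == ev.count
        np.testing.assert_allclose(ev2.aucs_mVs, ev.aucs_mVs, rtol=1e-9)
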