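"""Activity-trace analysis.

GCaMP side: build a region-of-interest mask from a time-lapse movie
(temporal maximum-intensity projection → maximum-entropy threshold →
small-object removal), extract the mean fluorescence over the mask,
baseline-correct (ΔF − F0) and count transient peaks, reported as a
frequency in events·min⁻¹.

Voltage side: detect supra-threshold depolarisation events in a
current-clamp trace (default threshold V_m = −35 mV), with each event's
area under the curve (spike integral) taken relative to the resting
baseline, in mV·s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.signal
from skimage.morphology import remove_small_objects

from .core import DegenerateInputError, Trace
from .sted2d import kapur_threshold

__all__ = [
    "PeakSet",
    "EventSet",
    "AP_THRESHOLD_MV",
    "roi_mask_from_movie",
    "extract_trace",
    "baseline_correct",
    "peak_frequency",
    "detect_events",
]

#: Action-potential detection threshold for IHC voltage traces (mV).
AP_THRESHOLD_MV = -35.0


@dataclass(frozen=True)
class PeakSet:
    """Detected fluorescence transients of one trace."""

    peak_times_s: tuple
    frequency_per_min: float

    @property
    def count(self) -> int:
        return len(self.peak_times_s)


@dataclass(frozen=True)
class EventSet:
    """Supra-threshold voltage events.

    Each event is ``(onset_s, offset_s, peak_mV, auc_mVs)``; AUC is the
    trapezoidal integral of (V − baseline) over the event window extended
    to the surrounding baseline crossings.
    """

    events: tuple
    rate_per_s: float
    threshold_mV: float
    baseline_mV: float

    @property
    def count(self) -> int:
        return len(self.events)

    @property
    def aucs_mVs(self) -> np.ndarray:
        return np.array([e[3] for e in self.events])


def roi_mask_from_movie(movie: np.ndarray, min_size_px: int = 20, n_bins: int = 256) -> np.ndarray:
    """ROI mask from a (t, y, x) movie: temporal maximum projection,
    maximum-entropy threshold, then removal of connected components
    smaller than ``min_size_px``."""
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be a (t, y, x) array with >= 2 frames")
    mip = movie.max(axis=0)
    if mip.min() == mip.max():
        raise DegenerateInputError("constant movie: no ROI can be derived")
    t = kapur_threshold(mip, n_bins=n_bins)
    mask = mip > t
    return remove_small_objects(mask, max_size=min_size_px - 1)


def extract_trace(movie: np.ndarray, mask: np.ndarray, dt_s: float = 0.78) -> Trace:
    """Mean intensity over the mask, per frame."""
    movie = np.asarray(movie, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    value = movie[:, mask].mean(axis=1)
    return Trace(np.arange(movie.shape[0]) * dt_s, value, kind="fluorescence")


def baseline_correct(trace: Trace, f0_mode: str = "percentile", percentile: float = 10.0,
                     k_initial: int = 10) -> Trace:
    """ΔF − F0 baseline correction.

    ``f0_mode="percentile"`` (default): F0 is the given percentile
    (10th) of the trace.  ``f0_mode="initial"``: F0 is the mean of the
    first ``k_initial`` samples.  The mode and F0 used are recorded in
    ``Trace.meta``.
    """
    if trace.value.size == 0:
        raise ValueError("trace is empty")
    if f0_mode == "percentile":
        f0 = float(np.percentile(trace.value, percentile))
    elif f0_mode == "initial":
        f0 = float(trace.value[: max(1, k_initial)].mean())
    else:
        raise ValueError(f"unknown f0_mode: {f0_mode!r}")
    meta = dict(trace.meta)
    meta.update({"f0_mode": f0_mode, "f0": f0})
    return Trace(trace.time_s, trace.value - f0, kind=trace.kind, meta=meta)


def peak_frequency(
    trace: Trace,
    min_prominence: float | None = None,
    smooth_sigma_samples: float = 1.5,
) -> PeakSet:
    """Count fluorescence transients and report events·min⁻¹.

    The trace is lightly smoothed (Gaussian, default σ = 1.5 samples)
    and local maxima with prominence ≥ ``min_prominence`` are counted.
    The default prominence is 5 robust standard deviations
    (5 × 1.4826 × MAD) of the smoothed trace — scale-free, and strict
    enough that white noise almost never produces a qualifying peak over
    a 10-min recording.  Closely spaced transients (within about one
    sampling interval) merge into a single peak; that resolution limit
    is inherent to the sampling.
    """
    v = trace.value
    if smooth_sigma_samples > 0 and v.size > 1:
        v = ndi.gaussian_filter1d(v, smooth_sigma_samples, mode="nearest")
    if min_prominence is None:
        mad = float(np.median(np.abs(v - np.median(v))))
        min_prominence = 5.0 * 1.4826 * mad if mad > 0 else np.finfo(float).eps
    idx, _ = scipy.signal.find_peaks(v, prominence=min_prominence)
    duration_min = trace.duration_s / 60.0 if v.size >= 2 else 0.0
    freq = len(idx) / duration_min if duration_min > 0 else 0.0
    return PeakSet(tuple(trace.time_s[idx]), freq)


def detect_events(
    vtrace: Trace,
    threshold_mV: float = AP_THRESHOLD_MV,
    baseline_mode: str = "rmp",
    hysteresis_mV: float = 2.0,
) -> EventSet:
    """Supra-threshold event detection on a voltage trace.

    Events are maximal contiguous runs with V > threshold; two runs are
    merged when the voltage between them never falls below
    threshold − ``hysteresis_mV`` (guards against noise chatter while a
    slow repolarisation crosses the threshold).  For the AUC
    each run is extended outward to where V falls back to the baseline
    (or to the trace edge / the midpoint toward a neighbouring event),
    and the trapezoidal integral of (V − baseline) is taken over that
    window.  Baseline: ``"rmp"`` (default) = median of sub-threshold
    samples; ``"median"`` = median of the whole trace.
    """
    v = np.asarray(vtrace.value)
    t = np.asarray(vtrace.time_s)
    if v.size < 2:
        return EventSet((), 0.0, threshold_mV, float(np.median(v)) if v.size else 0.0)
    if baseline_mode == "rmp":
        sub = v[v <= threshold_mV]
        baseline = float(np.median(sub)) if sub.size else float(np.median(v))
    elif baseline_mode == "median":
        baseline = float(np.median(v))
    else:
        raise ValueError(f"unknown baseline_mode: {baseline_mode!r}")

    above = v > threshold_mV
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1))
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        stops = stops + [v.size - 1]

    # hysteresis merge: a dip that stays above (threshold - hysteresis)
    # does not end the event
    if hysteresis_mV > 0 and len(starts) > 1:
        m_starts, m_stops = [starts[0]], [stops[0]]
        for s, e in zip(starts[1:], stops[1:]):
            if v[m_stops[-1] : s + 1].min() > threshold_mV - hysteresis_mV:
                m_stops[-1] = e
            else:
                m_starts.append(s)
                m_stops.append(e)
        starts, stops = m_starts, m_stops

    events = []
    n = len(starts)
    for k, (s, e) in enumerate(zip(starts, stops)):
        lo_bound = 0 if k == 0 else (stops[k - 1] + starts[k]) // 2
        hi_bound = v.size - 1 if k == n - 1 else (stops[k] + starts[k + 1]) // 2
        lo = s
        while lo > lo_bound and v[lo - 1] > baseline:
            lo -= 1
        hi = e
        while hi < hi_bound and v[hi + 1] > baseline:
            hi += 1
        auc = float(np.trapezoid(v[lo : hi + 1] - baseline, t[lo : hi + 1]))
        events.append((float(t[lo]), float(t[hi]), float(v[s : e + 1].max()), auc))

    duration = vtrace.duration_s
    rate = len(events) / duration if duration > 0 else 0.0
    return EventSet(tuple(events), rate, threshold_mV, baseline)
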