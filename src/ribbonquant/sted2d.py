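"""2D-STED cluster-area analysis.

Re-implements the cluster-segmentation routine used for paired CtBP2
(ribbon) and Ca_v1.3 (calcium-channel) clusters in super-resolution
optical sections: Gaussian blur (σ = 1 px) → maximum-entropy dark
thresholding → watershed separation of touching objects → size filter
(objects larger than 50 px) → moment-matched ellipse fit and calibrated
area measurement → paired-area correlation (Spearman rank correlation
plus ordinary least-squares regression with a 95% confidence interval).

The maximum-entropy threshold is the Kapur–Sahoo–Wong criterion: over a
256-bin histogram, pick the cut maximising the summed Shannon entropies
of the background (≤ threshold) and foreground (> threshold) intensity
distributions.  "Dark" refers to the background: objects are bright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.stats
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed as _watershed

from .core import DegenerateInputError, Frame2D, InsufficientDataError

__all__ = [
    "EllipseRegion",
    "AreaPair",
    "gaussian_blur",
    "max_entropy_threshold",
    "kapur_threshold",
    "watershed_split",
    "filter_and_fit",
    "correlate_pairs",
    "segment_frame",
    "analyze_pair",
]


@dataclass(frozen=True)
class EllipseRegion:
    """One segmented 2D cluster that survived the size filter.

    ``area_um2`` is the calibrated mask area (pixel count × pixel area);
    the ellipse axes/orientation are shape descriptors from the region's
    second-order image moments.
    """

    label: int
    pixel_count: int
    area_um2: float
    centroid_um: tuple[float, float]  # (y, x)
    major_um: float
    minor_um: float
    orientation_rad: float

    def __post_init__(self):
        if self.pixel_count <= 0 or self.area_um2 <= 0:
            raise ValueError("region must have positive pixel count and area")
        if self.major_um < self.minor_um:
            raise ValueError("major axis must be >= minor axis")


@dataclass(frozen=True)
class AreaPair:
    """Calibrated areas of one CtBP2/Ca_v1.3 cluster pair (μm²)."""

    ribbon_area_um2: float
    channel2_area_um2: float
    frame_id: int = 0

    def __post_init__(self):
        if self.ribbon_area_um2 <= 0 or self.channel2_area_um2 <= 0:
            raise ValueError("areas must be positive")


def gaussian_blur(frame: Frame2D, sigma_px: float = 1.0) -> Frame2D:
    """Low-pass filter a frame with a Gaussian kernel (reflective boundary)."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    blurred = ndi.gaussian_filter(np.asarray(frame.intensity, dtype=float), sigma_px, mode="reflect")
    # tiny negative round-off would violate the Frame2D invariant
    return Frame2D(np.clip(blurred, 0, None), frame.pixel_size_um, frame.channel)


def kapur_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Kapur maximum-entropy threshold of an intensity sample.

    Histogram: ``n_bins`` equal-width bins over [min, max].  Candidate
    thresholds are the interior bin edges; the returned edge maximises
    H_background + H_foreground where each term is the Shannon entropy of
    the class-conditional bin distribution.  Foreground is *strictly
    above* the threshold.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateInputError("cannot threshold a constant image")
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    p = counts / counts.sum()
    # cumulative class probabilities: background = bins 0..t, foreground = rest
    w0 = np.cumsum(p)
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])
    s0 = np.cumsum(plogp)
    s_total = s0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(w0) - s0 / w0
        w1 = 1.0 - w0
        h1 = np.log(w1) - (s_total - s0) / w1
    obj = h0 + h1
    # a valid cut needs mass on both sides
    valid = (w0 > 0) & (w0 < 1)
    obj = np.where(valid, obj, -np.inf)
    t_bin = int(np.argmax(obj[:-1]))  # last edge would leave empty foreground
    return float(edges[t_bin + 1])


def max_entropy_threshold(frame: Frame2D, n_bins: int = 256) -> float:
    """Maximum-entropy (Kapur) dark threshold of a frame.

    Raises :class:`DegenerateInputError` on a constant frame.
    """
    return kapur_threshold(frame.intensity, n_bins=n_bins)


def watershed_split(mask: np.ndarray, min_seed_separation_px: int = 3) -> np.ndarray:
    """Split touching objects in a binary mask with a distance-transform
    seeded watershed.

    Seeds are local maxima of the Euclidean distance transform at least
    ``min_seed_separation_px`` apart; the returned label map partitions
    exactly the input mask (0 outside).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    seed_coords = peak_local_max(
        dist, min_distance=int(min_seed_separation_px), labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, c in enumerate(seed_coords, start=1):
        markers[tuple(c)] = i
    if markers.max() == 0:  # pathological: no maxima found, fall back to components
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    labels = _watershed(-dist, markers, mask=mask).astype(np.int32)
    # components whose only maximum was suppressed by a neighbour's seed
    # would stay unlabeled; give each its own label so the labels
    # partition the mask exactly
    missing = mask & (labels == 0)
    if missing.any():
        extra, n_extra = ndi.label(missing)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0).astype(np.int32)
    return labels


def filter_and_fit(labels: np.ndarray, frame: Frame2D, min_px: int = 50) -> list[EllipseRegion]:
    """Discard labels with ≤ ``min_px`` pixels (strict "larger than") and
    fit a moment-matched ellipse to each survivor.

    Area is the calibrated mask area; axes are the full lengths of the
    equal-second-moment ellipse, converted to μm.
    """
    labels = np.asarray(labels)
    if labels.shape != frame.intensity.shape:
        raise ValueError("label map and frame must be congruent")
    px = frame.pixel_size_um
    out: list[EllipseRegion] = []
    for rp in regionprops(labels):
        if rp.num_pixels <= min_px:
            continue
        cy, cx = rp.centroid
        out.append(
            EllipseRegion(
                label=int(rp.label),
                pixel_count=int(rp.num_pixels),
                area_um2=rp.num_pixels * frame.pixel_area_um2,
                centroid_um=(cy * px, cx * px),
                major_um=rp.axis_major_length * px,
                minor_um=rp.axis_minor_length * px,
                orientation_rad=float(rp.orientation),
            )
        )
    return out


def segment_frame(
    frame: Frame2D, sigma_px: float = 1.0, min_px: int = 50, n_bins: int = 256
) -> list[EllipseRegion]:
    """Full single-frame routine: blur → threshold → watershed → fit."""
    blurred = gaussian_blur(frame, sigma_px)
    t = max_entropy_threshold(blurred, n_bins=n_bins)
    mask = blurred.intensity > t
    labels = watershed_split(mask)
    return filter_and_fit(labels, frame, min_px=min_px)


def analyze_pair(
    ribbon_frame: Frame2D,
    channel2_frame: Frame2D,
    frame_id: int = 0,
    **kwargs,
) -> AreaPair | None:
    """Segment both channels of one cropped synapse frame and pair the
    largest surviving object of each (multi-object frames are paired
    largest-to-largest).  Returns ``None`` when either channel yields no
    object.
    """
    r = segment_frame(ribbon_frame, **kwargs)
    c = segment_frame(channel2_frame, **kwargs)
    if not r or not c:
        return None
    r_best = max(r, key=lambda e: e.pixel_count)
    c_best = max(c, key=lambda e: e.pixel_count)
    return AreaPair(r_best.area_um2, c_best.area_um2, frame_id=frame_id)


def correlate_pairs(pairs: list[AreaPair]) -> dict:
    """Spearman correlation and OLS regression of paired cluster areas.

    Regresses channel-2 (Ca_v1.3) area on ribbon (CtBP2) area.  Returns a
    dict with ``spearman_rho``, ``spearman_p``, ``slope``, ``intercept``,
    ``slope_ci95`` and ``intercept_ci95`` (95% confidence intervals), and
    ``n``.
    """
    if len(pairs) < 3:
        raise InsufficientDataError("need at least 3 pairs to correlate")
    x = np.array([p.ribbon_area_um2 for p in pairs])
    y = np.array([p.channel2_area_um2 for p in pairs])
    rho, p = scipy.stats.spearmanr(x, y)
    fit = scipy.stats.linregress(x, y)
    tcrit = scipy.stats.t.ppf(0.975, len(pairs) - 2)
    return {
        "n": len(pairs),
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_ci95": (float(fit.slope - tcrit * fit.stderr), float(fit.slope + tcrit * fit.stderr)),
        "intercept_ci95": (
            float(fit.intercept - tcrit * fit.intercept_stderr),
            float(fit.intercept + tcrit * fit.intercept_stderr),
        ),
    }
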