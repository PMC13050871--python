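"""Synthetic-data generation with ground truth.

Every input the downstream pipeline consumes can be generated here with
a known answer: three-channel confocal stacks of ribbon/PSD puncta pairs
(with a controllable engaged fraction under the 0.5 μm surface-distance
rule), paired 2D-STED frames whose true cluster areas follow a Gaussian
copula with a target Spearman correlation, GCaMP-like fluorescence
traces with known transient times, and IHC-like voltage traces with
stereotyped spikes.

The generator states a world; its defaults mirror the acquisition
geometry of the study this pipeline quantifies (80 × 80 × 200 nm
confocal voxels, 15 nm STED pixels, 0.78 s time-lapse interval) and
plausible object statistics where the study reports none (log-normal
radii and intensities).  It does not attempt optical realism.

Determinism: identical (config, seed) give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .core import (
    CONFOCAL_VOXEL_UM,
    GCAMP_INTERVAL_S,
    STED_PIXEL_UM,
    Frame2D,
    ImageStack,
    PlacementError,
    Trace,
)
from .engagement import ENGAGEMENT_CUTOFF_UM, surface_distance
from .puncta3d import Punctum

__all__ = [
    "SynthConfig",
    "GroundTruthManifest",
    "make_confocal_stack",
    "render_label_volumes",
    "make_sted_pair_frames",
    "sample_paired_areas",
    "make_gcamp_trace",
    "make_voltage_trace",
]

_MAX_PLACEMENT_ATTEMPTS = 10_000


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthConfig:
    """World description for the confocal-stack generator.

    Lengths in μm, axis order (z, y, x).  ``n_pairs`` ribbon/PSD pairs
    are placed; a fraction ``engaged_fraction`` of them with a surface
    gap drawn below the 0.5 μm engagement rule, the rest well above it.
    Noise model: Poisson shot noise (``poisson_scale`` photons per a.u.;
    0 disables) plus additive Gaussian read noise.
    """

    shape_zyx: tuple[int, int, int] = (32, 128, 128)
    voxel_size_um: tuple[float, float, float] = CONFOCAL_VOXEL_UM
    n_pairs: int = 20
    engaged_fraction: float = 0.8
    ribbon_radius_median_um: float = 0.15
    psd_radius_median_um: float = 0.20
    radius_sigma_log: float = 0.25
    intensity_median: float = 2000.0
    intensity_sigma_log: float = 0.3
    background: float = 50.0
    poisson_scale: float = 1.0
    read_noise_sd: float = 5.0
    psf_sigma_um: tuple[float, float, float] = (0.25, 0.08, 0.08)
    min_separation_um: float = 0.6
    cross_separation_um: float = 1.3
    engaged_gap_um: tuple[float, float] = (0.05, 0.25)
    floating_gap_um: tuple[float, float] = (1.0, 1.8)
    n_ihc: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not 0.0 <= self.engaged_fraction <= 1.0:
            raise ValueError("engaged_fraction must lie in [0, 1]")
        for name in (
            "ribbon_radius_median_um",
            "psd_radius_median_um",
            "intensity_median",
            "min_separation_um",
            "cross_separation_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("radius_sigma_log", "intensity_sigma_log", "background",
                     "poisson_scale", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v <= 0 for v in self.voxel_size_um) or any(s <= 0 for s in self.shape_zyx):
            raise ValueError("shape and voxel size must be positive")
        if self.n_ihc < 1:
            raise ValueError("n_ihc must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruthManifest:
    """Ground truth of one generated dataset.

    ``puncta_true`` rows: (channel, center_um (z, y, x), radius_um,
    peak_intensity).  ``pairs_true`` rows: (ribbon_index, psd_index,
    center_distance_um, engaged).  The engaged flag is the generator's
    own surface-distance audit of the rendered pre-noise label volumes
    against the 0.5 μm rule, not the intended placement.
    """

    puncta_true: list = field(default_factory=list)
    pairs_true: list = field(default_factory=list)
    n_ihc: int = 1
    spike_times_true: list = field(default_factory=list)
    rho_true: float | None = None
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "puncta_true": [
                        [ch, list(map(float, c)), float(r), float(i)]
                        for ch, c, r, i in self.puncta_true
                    ],
                    "pairs_true": [
                        [int(a), int(b), float(d), bool(e)] for a, b, d, e in self.pairs_true
                    ],
                    "n_ihc": int(self.n_ihc),
                    "spike_times_true": [float(t) for t in self.spike_times_true],
                    "rho_true": None if self.rho_true is None else float(self.rho_true),
                    "seed": int(self.seed),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            puncta_true=[(ch, tuple(c), r, i) for ch, c, r, i in d["puncta_true"]],
            pairs_true=[(a, b, d_, e) for a, b, d_, e in d["pairs_true"]],
            n_ihc=d["n_ihc"],
            spike_times_true=list(d["spike_times_true"]),
            rho_true=d["rho_true"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# confocal stack generation
# ---------------------------------------------------------------------------


def _volume_extent_um(config: SynthConfig) -> np.ndarray:
    return np.array(config.shape_zyx) * np.array(config.voxel_size_um)


def _place_point(rng, lo, hi, existing, min_dists):
    """Rejection-sample a point in [lo, hi] at least min_dists[i] from
    existing[i] (grouped constraint lists)."""
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        p = lo + rng.random(3) * (hi - lo)
        ok = True
        for pts, dmin in zip(existing, min_dists):
            for q in pts:
                if np.linalg.norm(p - q) < dmin:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return p
    raise PlacementError(
        "could not place object after {} attempts; volume too small for the "
        "requested counts and separations".format(_MAX_PLACEMENT_ATTEMPTS)
    )


def _generate_geometry(config: SynthConfig):
    """Deterministic object placement; shared by the intensity and label
    renderers so both see the same world."""
    rng = np.random.default_rng(config.seed)
    extent = _volume_extent_um(config)
    n = config.n_pairs

    r_rib = config.ribbon_radius_median_um * np.exp(
        rng.normal(0, config.radius_sigma_log, n)
    )
    r_psd = config.psd_radius_median_um * np.exp(rng.normal(0, config.radius_sigma_log, n))
    i_rib = config.intensity_median * np.exp(rng.normal(0, config.intensity_sigma_log, n))
    i_psd = config.intensity_median * np.exp(rng.normal(0, config.intensity_sigma_log, n))

    n_engaged = int(round(config.engaged_fraction * n))
    engaged_intent = np.zeros(n, dtype=bool)
    engaged_intent[:n_engaged] = True

    rib_centers: list[np.ndarray] = []
    psd_centers: list[np.ndarray] = []
    margin = 0.4  # keep whole objects inside the volume
    for i in range(n):
        lo = np.full(3, margin) + r_rib[i]
        hi = extent - margin - r_rib[i]
        if np.any(hi <= lo):
            raise PlacementError("volume too small for the requested object sizes")
        c = _place_point(
            rng,
            lo,
            hi,
            [rib_centers, psd_centers],
            [config.min_separation_um, config.cross_separation_um],
        )
        # partner PSD on a random direction at the intended surface gap
        glo, ghi = config.engaged_gap_um if engaged_intent[i] else config.floating_gap_um
        placed = False
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            gap = glo + rng.random() * (ghi - glo)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            p = c + u * (r_rib[i] + r_psd[i] + gap)
            if np.any(p < margin + r_psd[i]) or np.any(p > extent - margin - r_psd[i]):
                continue
            # rib_centers does not yet contain this pair's ribbon, so the
            # cross-channel constraint automatically exempts the partner
            ok = all(
                np.linalg.norm(p - q) >= config.min_separation_um for q in psd_centers
            ) and all(
                np.linalg.norm(p - q) >= config.cross_separation_um for q in rib_centers
            )
            if ok:
                placed = True
                break
        if not placed:
            raise PlacementError("could not place partner PSD")
        rib_centers.append(c)
        psd_centers.append(p)

    return {
        "rib_centers": np.array(rib_centers).reshape(n, 3),
        "psd_centers": np.array(psd_centers).reshape(n, 3),
        "r_rib": r_rib,
        "r_psd": r_psd,
        "i_rib": i_rib,
        "i_psd": i_psd,
        "rng_state_rng": rng,  # carries on for noise so seed covers everything
    }


def _sphere_voxels(center_um, radius_um, shape, voxel_size_um) -> np.ndarray:
    """(n, 3) indices of voxels whose centers lie within radius of center;
    never empty (falls back to the voxel nearest the center)."""
    vs = np.asarray(voxel_size_um)
    lo = np.maximum(0, np.floor((center_um - radius_um) / vs - 1).astype(int))
    hi = np.minimum(np.asarray(shape), np.ceil((center_um + radius_um) / vs + 1).astype(int))
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    pos = (idx + 0.5) * vs
    d = np.linalg.norm(pos - center_um, axis=1)
    inside = idx[d <= radius_um]
    if len(inside) == 0:
        nearest = np.clip(np.round(center_um / vs - 0.5).astype(int), 0, np.asarray(shape) - 1)
        inside = nearest.reshape(1, 3)
    return inside


def _render_channel(centers, radii, intensities, config: SynthConfig) -> np.ndarray:
    """Additive Gaussian spots (σ_xy = radius/2, σ_z = max(radius/2, dz/2))."""
    img = np.zeros(config.shape_zyx, dtype=float)
    vs = np.asarray(config.voxel_size_um)
    for c, r, amp in zip(centers, radii, intensities):
        sig = np.array([max(r / 2.0, vs[0] / 2.0), r / 2.0, r / 2.0])
        lo = np.maximum(0, np.floor((c - 4 * sig) / vs).astype(int))
        hi = np.minimum(np.array(config.shape_zyx), np.ceil((c + 4 * sig) / vs).astype(int) + 1)
        if np.any(hi <= lo):
            continue
        zz = ((np.arange(lo[0], hi[0]) + 0.5) * vs[0] - c[0]) / sig[0]
        yy = ((np.arange(lo[1], hi[1]) + 0.5) * vs[1] - c[1]) / sig[1]
        xx = ((np.arange(lo[2], hi[2]) + 0.5) * vs[2] - c[2]) / sig[2]
        g = np.exp(
            -0.5
            * (
                zz[:, None, None] ** 2
                + yy[None, :, None] ** 2
                + xx[None, None, :] ** 2
            )
        )
        img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amp * g
    return img


def render_label_volumes(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pre-noise ground-truth label volumes (ribbon, PSD); label i+1 marks
    the sphere of pair i.  Regenerated deterministically from the config."""
    geom = _generate_geometry(config)
    rib = np.zeros(config.shape_zyx, dtype=np.int32)
    psd = np.zeros(config.shape_zyx, dtype=np.int32)
    for i in range(config.n_pairs):
        for vol, centers, radii in ((rib, geom["rib_centers"], geom["r_rib"]),
                                    (psd, geom["psd_centers"], geom["r_psd"])):
            vox = _sphere_voxels(centers[i], radii[i], config.shape_zyx, config.voxel_size_um)
            vol[vox[:, 0], vox[:, 1], vox[:, 2]] = i + 1
    return rib, psd


def _label_punctum(label_vol: np.ndarray, lab: int, voxel_size_um) -> Punctum:
    vox = np.argwhere(label_vol == lab)
    vs = np.asarray(voxel_size_um)
    centroid = tuple(float(v) for v in (vox.mean(axis=0) + 0.5) * vs)
    return Punctum(lab, vox, centroid, len(vox) * float(np.prod(vs)), 0.0, 0.0)


def audit_engagement(config: SynthConfig) -> list[tuple[int, int, float, bool]]:
    """The generator's own engagement audit: for each ribbon, the nearest
    PSD by voxel surface distance on the pre-noise label volumes and the
    strict <0.5 μm flag."""
    rib_lab, psd_lab = render_label_volumes(config)
    geom = _generate_geometry(config)
    out = []
    psds = [_label_punctum(psd_lab, j + 1, config.voxel_size_um) for j in range(config.n_pairs)]
    for i in range(config.n_pairs):
        r = _label_punctum(rib_lab, i + 1, config.voxel_size_um)
        dists = [surface_distance(r, p, config.voxel_size_um) for p in psds]
        j = int(np.argmin(dists))
        center_d = float(
            np.linalg.norm(geom["rib_centers"][i] - geom["psd_centers"][j])
        )
        out.append((i, j, center_d, bool(dists[j] < ENGAGEMENT_CUTOFF_UM)))
    return out


def make_confocal_stack(config: SynthConfig) -> tuple[dict[str, ImageStack], GroundTruthManifest]:
    """Generate a three-channel confocal stack (ribbon, PSD, cell context)
    plus its ground-truth manifest.

    Channels are returned as a dict of :class:`ImageStack`; the context
    channel is a smooth uninformative background (IHC count is carried in
    the manifest, mirroring manual cell counting).
    """
    geom = _generate_geometry(config)
    rng = geom["rng_state_rng"]
    vs = np.asarray(config.voxel_size_um)
    psf_sig_vox = np.asarray(config.psf_sigma_um) / vs

    stacks: dict[str, ImageStack] = {}
    for name, centers, radii, amps in (
        ("ribbon", geom["rib_centers"], geom["r_rib"], geom["i_rib"]),
        ("psd", geom["psd_centers"], geom["r_psd"], geom["i_psd"]),
    ):
        img = _render_channel(centers, radii, amps, config)
        img = ndi.gaussian_filter(img, psf_sig_vox, mode="reflect")
        img += config.background
        if config.poisson_scale > 0:
            img = rng.poisson(img * config.poisson_scale) / config.poisson_scale
        if config.read_noise_sd > 0:
            img = img + rng.normal(0, config.read_noise_sd, img.shape)
        stacks[name] = ImageStack(np.clip(img, 0, None), config.voxel_size_um, channel=name)

    # context: smooth low-frequency field, no object information
    ctx = ndi.gaussian_filter(rng.random(config.shape_zyx), 8.0) * config.background
    stacks["context"] = ImageStack(ctx, config.voxel_size_um, channel="context")

    manifest = GroundTruthManifest(
        puncta_true=(
            [
                ("ribbon", tuple(geom["rib_centers"][i]), float(geom["r_rib"][i]), float(geom["i_rib"][i]))
                for i in range(config.n_pairs)
            ]
            + [
                ("psd", tuple(geom["psd_centers"][i]), float(geom["r_psd"][i]), float(geom["i_psd"][i]))
                for i in range(config.n_pairs)
            ]
        ),
        pairs_true=audit_engagement(config),
        n_ihc=config.n_ihc,
        seed=config.seed,
    )
    return stacks, manifest


# ---------------------------------------------------------------------------
# paired 2D-STED frames
# ---------------------------------------------------------------------------


def sample_paired_areas(
    n_pairs: int,
    rho: float,
    rng: np.random.Generator,
    median_um2: float = 0.03,
    sigma_log: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired (CtBP2, Ca_v1.3) true areas from a Gaussian copula with
    target *Spearman* correlation ``rho`` and log-normal marginals.

    The latent Pearson correlation is 2 sin(πρ/6), the exact inverse of
    the Spearman-of-bivariate-normal relation, so the population Spearman
    of the output equals ``rho``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2 for a defined correlation")
    r_pearson = 2.0 * np.sin(np.pi * rho / 6.0)
    cov = np.array([[1.0, r_pearson], [r_pearson, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_pairs, method="cholesky")
    a = median_um2 * np.exp(sigma_log * z[:, 0])
    b = median_um2 * np.exp(sigma_log * z[:, 1])
    return a, b


def make_sted_pair_frames(
    n_pairs: int,
    rho: float,
    seed: int,
    frame_um: float = 1.0,
    pixel_size_um: float = STED_PIXEL_UM,
    peak_intensity: float = 150.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    edge_sigma_px: float = 1.0,
) -> tuple[list[tuple[Frame2D, Frame2D]], GroundTruthManifest]:
    """Paired 1 × 1 μm 2D-STED crops, one CtBP2 and one Ca_v1.3 blob each.

    True blob areas follow the Gaussian copula of
    :func:`sample_paired_areas`; each blob is rendered as a soft-edged
    disc of the matching area.  ``noise_sd = 0`` disables noise.
    """
    rng = np.random.default_rng(seed)
    areas_a, areas_b = sample_paired_areas(n_pairs, rho, rng)
    npx = int(round(frame_um / pixel_size_um))
    yy, xx = np.mgrid[0:npx, 0:npx]
    pairs: list[tuple[Frame2D, Frame2D]] = []
    puncta_true = []
    for i in range(n_pairs):
        frames = []
        for ch, area in (("ctbp2", areas_a[i]), ("cav13", areas_b[i])):
            r_um = float(np.sqrt(area / np.pi))
            r_px = r_um / pixel_size_um
            c = npx / 2.0 + rng.uniform(-0.1, 0.1, size=2) * npx  # slight jitter
            disc = ((yy - c[0]) ** 2 + (xx - c[1]) ** 2) <= r_px**2
            img = np.where(disc, peak_intensity, 0.0)
            if edge_sigma_px > 0:
                img = ndi.gaussian_filter(img, edge_sigma_px)
            img += background
            if noise_sd > 0:
                img = img + rng.normal(0, noise_sd, img.shape)
            frames.append(Frame2D(np.clip(img, 0, None), pixel_size_um, channel=ch))
            puncta_true.append(
                (ch, (0.0, c[0] * pixel_size_um, c[1] * pixel_size_um), r_um, peak_intensity)
            )
        pairs.append((frames[0], frames[1]))
    manifest = GroundTruthManifest(puncta_true=puncta_true, rho_true=rho, seed=seed)
    return pairs, manifest


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def make_gcamp_trace(
    duration_s: float,
    peak_times: list[float],
    drift_per_s: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_s: float = GCAMP_INTERVAL_S,
    baseline: float = 1.0,
    amplitude: float = 1.0,
    tau_decay_s: float = 2.0,
) -> Trace:
    """GCaMP6-like ΔF trace: baseline + linear drift + fast-rise
    exponential-decay transients at the given times + Gaussian noise.

    Ground truth (peak times, amplitude, decay constant) is recorded in
    ``Trace.meta``.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    peak_times = sorted(float(t) for t in peak_times)
    if peak_times and (peak_times[0] < 0 or peak_times[-1] > duration_s):
        raise ValueError("peak times must lie within [0, duration]")
    t = np.arange(0.0, duration_s, dt_s)
    v = baseline + drift_per_s * t
    for t0 in peak_times:
        onset = t >= t0
        v = v + np.where(onset, amplitude * np.exp(-(t - t0) / tau_decay_s), 0.0)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0, noise_sd, t.shape)
    return Trace(
        t,
        v,
        kind="fluorescence",
        meta={
            "peak_times_true": peak_times,
            "amplitude": amplitude,
            "tau_decay_s": tau_decay_s,
            "baseline": baseline,
            "drift_per_s": drift_per_s,
            "seed": seed,
        },
    )


def _spike_shape(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> tuple[np.ndarray, float]:
    """Unit-peak double-exponential spike and its analytic time integral."""
    tp = np.where(t >= 0, t, 0.0)  # clamp to avoid overflow in exp for t < 0
    s = np.where(t >= 0, np.exp(-tp / tau_decay_s) - np.exp(-tp / tau_rise_s), 0.0)
    t_peak = np.log(tau_decay_s / tau_rise_s) * tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
    m = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    integral = (tau_decay_s - tau_rise_s) / m  # of the unit-peak shape
    return s / m, integral


def make_voltage_trace(
    duration_s: float,
    spike_times: list[float],
    rmp_mV: float = -60.0,
    spike_peak_mV: float = -15.0,
    seed: int = 0,
    fs_hz: float = 10_000.0,
    noise_sd_mV: float = 0.3,
    tau_rise_s: float = 0.002,
    tau_decay_s: float = 0.010,
) -> Trace:
    """IHC-like current-clamp voltage trace with stereotyped Ca²⁺ spikes.

    Each spike is a double-exponential (2 ms rise, 10 ms decay by
    default) peaking at ``spike_peak_mV`` above the resting membrane
    potential ``rmp_mV``.  The analytic per-spike integral above RMP is
    recorded in ``Trace.meta["spike_integral_true_mVs"]``.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    if spike_peak_mV <= rmp_mV:
        raise ValueError("spike peak must exceed the resting potential")
    spike_times = sorted(float(t) for t in spike_times)
    if spike_times and (spike_times[0] < 0 or spike_times[-1] > duration_s):
        raise ValueError("spike times must lie within [0, duration]")
    t = np.arange(0.0, duration_s, 1.0 / fs_hz)
    v = np.full_like(t, rmp_mV)
    amp = spike_peak_mV - rmp_mV
    _, unit_integral = _spike_shape(np.array([0.0]), tau_rise_s, tau_decay_s)
    for t0 in spike_times:
        shape, _ = _spike_shape(t - t0, tau_rise_s, tau_decay_s)
        v = v + amp * shape
    if noise_sd_mV > 0:
        v = v + np.random.default_rng(seed).normal(0, noise_sd_mV, t.shape)
    return Trace(
        t,
        v,
        kind="voltage",
        meta={
            "spike_times_true": spike_times,
            "rmp_mV": rmp_mV,
            "spike_peak_mV": spike_peak_mV,
            "spike_integral_true_mVs": amp * unit_integral,
            "seed": seed,
        },
    )
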