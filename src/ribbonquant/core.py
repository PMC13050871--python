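"""Core data containers shared across the pipeline.

All physical quantities are in micrometres (μm), seconds (s), millivolts
(mV) or arbitrary fluorescence units (a.u.).  Array axes follow the
``z, y, x`` convention throughout; voxel/pixel sizes are stored in the
same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "Frame2D",
    "Trace",
    "DegenerateInputError",
    "InsufficientDataError",
    "PlacementError",
]

#: Confocal voxel size (z, y, x) in μm: 200 nm steps, 80 × 80 nm pixels.
CONFOCAL_VOXEL_UM = (0.2, 0.08, 0.08)

#: 2D-STED pixel size in μm (15 × 15 nm).
STED_PIXEL_UM = 0.015

#: Default sampling interval of the GCaMP6 time-lapse protocol (s).
GCAMP_INTERVAL_S = 0.78


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable information (e.g. a constant
    image offered for thresholding)."""


class InsufficientDataError(ValueError):
    """Raised when a statistical operation receives too few observations."""


class PlacementError(RuntimeError):
    """Raised when the synthetic generator cannot place the requested
    objects without violating the minimum-separation constraint."""


@dataclass
class ImageStack:
    """A single-channel 3D intensity stack with physical voxel size.

    Parameters
    ----------
    intensity
        3D array, axis order ``(z, y, x)``, arbitrary units, non-negative.
    voxel_size_um
        Physical voxel edge lengths ``(dz, dy, dx)`` in μm.  Default is the
        confocal acquisition geometry (0.2, 0.08, 0.08).
    channel
        Free-form channel label (e.g. ``"ribbon"``, ``"psd"``).
    """

    intensity: np.ndarray
    voxel_size_um: tuple[float, float, float] = CONFOCAL_VOXEL_UM
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3 or self.intensity.size == 0:
            raise ValueError("intensity must be a non-empty 3D array (z, y, x)")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive lengths (dz, dy, dx)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensity.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    def with_intensity(self, intensity: np.ndarray) -> "ImageStack":
        return replace(self, intensity=np.asarray(intensity))

    def to_tiff(self, path) -> None:
        """Write the stack as a plain TIFF, planes along z."""
        tifffile.imwrite(path, np.asarray(self.intensity), metadata=None)

    @classmethod
    def from_tiff(cls, path, voxel_size_um=CONFOCAL_VOXEL_UM, channel="") -> "ImageStack":
        return cls(tifffile.imread(path), voxel_size_um=voxel_size_um, channel=channel)


@dataclass
class Frame2D:
    """A single-channel 2D frame (one STED optical section).

    ``pixel_size_um`` defaults to the 2D-STED pixel pitch of 15 nm.
    """

    intensity: np.ndarray
    pixel_size_um: float = STED_PIXEL_UM
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2 or self.intensity.size == 0:
            raise ValueError("intensity must be a non-empty 2D array")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, np.asarray(self.intensity), metadata=None)

    @classmethod
    def from_tiff(cls, path, pixel_size_um=STED_PIXEL_UM, channel="") -> "Frame2D":
        return cls(tifffile.imread(path), pixel_size_um=pixel_size_um, channel=channel)


@dataclass
class Trace:
    """A uniformly sampled time series (fluorescence or membrane voltage).

    ``kind`` is ``"fluorescence"`` (a.u.) or ``"voltage"`` (mV).  ``meta``
    carries provenance such as the baseline mode applied.
    """

    time_s: np.ndarray
    value: np.ndarray
    kind: str = "fluorescence"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_s.shape != self.value.shape or self.time_s.ndim != 1:
            raise ValueError("time_s and value must be 1D arrays of equal length")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
                raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        if self.time_s.size < 2:
            raise ValueError("dt undefined for traces with fewer than 2 samples")
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        if self.time_s.size == 0:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0]) + (self.dt if self.time_s.size >= 2 else 0.0)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "value": self.value}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind="fluorescence") -> "Trace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["value"].to_numpy(), kind=kind)
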