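"""Shared in-memory containers for the quantification pipeline.

Conventions fixed across all modules:

* Image axis order is ``(t, z, c, y, x)``; singleton axes are retained;
  indices are 0-based and y increases downward.
* Continuous image coordinates put the center of pixel ``(i, j)`` at the
  integer point ``(i, j)``; the pixel occupies the half-open box
  ``[i - 0.5, i + 0.5) x [j - 0.5, j + 0.5)``.
* Time is carried in seconds in acquisition metadata and in minutes on
  every reported time axis, anchored at agonist addition (t = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger("acquant")


class ConfigurationError(ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


class CalibrationError(ValueError):
    """Required physical calibration is missing or invalid."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of an image stack.

    Parameters
    ----------
    pixel_size_um:
        Lateral pixel size in micrometers per pixel. Must be positive.
    frame_interval_s:
        Time between frames in seconds; required whenever the t-axis has
        more than one frame.
    agonist_frame:
        Index of the first frame at/after agonist addition (t = 0).
    fsk_frames:
        Optional ``(start, stop)`` frame-index range (half-open) of the
        terminal forskolin/IBMX saturation epoch.
    z_step_um:
        Optional axial step between z-planes in micrometers.
    """

    pixel_size_um: float
    frame_interval_s: float | None = None
    agonist_frame: int | None = None
    fsk_frames: tuple[int, int] | None = None
    z_step_um: float | None = None

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise CalibrationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.frame_interval_s is not None and not (self.frame_interval_s > 0):
            raise CalibrationError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")

    def time_axis_min(self, n_frames: int) -> np.ndarray:
        """Frame times in minutes relative to agonist addition."""
        if n_frames > 1 and self.frame_interval_s is None:
            raise CalibrationError("frame_interval_s required for a multi-frame time axis")
        interval = self.frame_interval_s or 0.0
        t0 = self.agonist_frame if self.agonist_frame is not None else 0
        if not (0 <= t0 < max(n_frames, 1)):
            raise CalibrationError(f"agonist_frame {t0} outside [0, {n_frames})")
        return (np.arange(n_frames) - t0) * interval / 60.0


@dataclass
class ImageStack:
    """Multi-dimensional fluorescence image with calibration.

    ``pixels`` always has exactly five axes ``(t, z, c, y, x)`` with
    finite, non-negative intensities.
    """

    pixels: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(f"expected (t, z, c, y, x) pixels, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[3], self.pixels.shape[4]

    def times_min(self) -> np.ndarray:
        return self.calibration.time_axis_min(self.n_frames)


@dataclass
class RegionMask:
    """Binary pixel set over one (y, x) frame with provenance.

    ``provenance`` is the ordered list of operations that produced the
    mask (e.g. ``["threshold>12.0", "close(r=1,square)"]``) so that every
    derived measurement can be audited.
    """

    pixels: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("RegionMask pixels must be 2-D (y, x)")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def derived(self, step: str, pixels: np.ndarray) -> "RegionMask":
        """New mask produced from this one by ``step``."""
        return RegionMask(pixels, provenance=[*self.provenance, step])


@dataclass(frozen=True)
class Punctum:
    """One labeled connected component."""

    label: int
    area_px: int
    centroid: tuple[float, float]  # (y, x), mean of member pixel centers


@dataclass
class PunctaSet:
    """Connected components of a binary mask (the computational puncta)."""

    labels: np.ndarray  # int label image, 0 = background
    components: list[Punctum]

    @property
    def n_puncta(self) -> int:
        return len(self.components)

    def areas(self) -> np.ndarray:
        return np.array([c.area_px for c in self.components], dtype=int)


#: Legal normalization states, in the only order they may advance.
NORMALIZATION_ORDER = ("raw", "F/F0", "dF/F0", "fsk")


@dataclass
class TimeSeries:
    """Per-frame scalar fluorescence trace anchored at agonist addition.

    ``values`` may contain NaN for frames where the measurement mask was
    empty; such frames are interpolated only inside area-under-curve
    computations, never stored interpolated.
    """

    times_min: np.ndarray
    values: np.ndarray
    normalization: str = "raw"
    mask_area_px: np.ndarray | None = None
    fsk_frames: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times_min.size >= 2 and not np.all(np.diff(self.times_min) > 0):
            raise ValueError("times must be strictly increasing")
        if self.normalization not in NORMALIZATION_ORDER:
            raise ValueError(f"unknown normalization state {self.normalization!r}")

    def with_values(self, values: np.ndarray, normalization: str) -> "TimeSeries":
        """Copy with new values and a normalization state moved forward."""
        old = NORMALIZATION_ORDER.index(self.normalization)
        new = NORMALIZATION_ORDER.index(normalization)
        if new < old:
            raise ValueError(
                f"normalization may only advance ({self.normalization!r} -> {normalization!r})"
            )
        return TimeSeries(
            self.times_min.copy(),
            np.asarray(values, dtype=float),
            normalization=normalization,
            mask_area_px=None if self.mask_area_px is None else self.mask_area_px.copy(),
            fsk_frames=self.fsk_frames,
        )

    def window(self, t_start: float, t_end: float, *, include_start: bool = False,
               include_end: bool = True) -> np.ndarray:
        """Boolean selector for samples inside a time window in minutes."""
        lo = self.times_min >= t_start if include_start else self.times_min > t_start
        hi = self.times_min <= t_end if include_end else self.times_min < t_end
        return lo & hi


def as_mask(mask: "RegionMask | np.ndarray | Sequence") -> RegionMask:
    """Coerce an array-like into a RegionMask (no-op on RegionMask)."""
    if isinstance(mask, RegionMask):
        return mask
    return RegionMask(np.asarray(mask, dtype=bool))
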