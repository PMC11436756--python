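"""Live-cell receptor accumulation at marker-defined endosomes.

Re-implements the puncta-quantification pipeline for trafficking movies:
a cell ROI (refined by thresholding the maximal temporal projection and
smoothing), a per-frame endosome mask from the marker channel (strict
threshold, exclusion of regions smaller than 3 pixels, 1-pixel dilation
then 1-pixel erosion), mean receptor fluorescence inside the mask,
background subtraction, and normalization to the pre-agonist baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ImageStack, RegionMask, TimeSeries, as_mask
from .enrichment import estimate_background
from .segmentation import (
    auto_threshold,
    connected_components,
    max_project_t,
    max_project_z,
    size_filter,
    smooth_mask,
    threshold_mask,
)

logger = logging.getLogger("acquant")

__all__ = ["PunctiConfig", "puncti_accumulation_trace", "normalize_baseline", "refine_cell_mask"]


@dataclass
class PunctiConfig:
    """Parameters of the endosomal-accumulation measurement.

    ``marker_threshold`` and ``cell_threshold`` may be numeric (the
    "set manually" convention) or ``"otsu"`` for the reproducible
    automatic default. ``mask_mode`` selects whether the endosome mask
    is recomputed per frame (default) or fixed from the temporal maximum
    projection of the marker channel; for a stationary marker the two
    are nearly identical.
    """

    marker_channel: int = 0
    receptor_channel: int = 1
    marker_threshold: float | str = "otsu"
    cell_threshold: float | str = "otsu"
    min_area_px: int = 3
    closing_element: str = "square"
    mask_mode: str = "per-frame"  # or "fixed"
    measure: str = "mean"  # or "integrated"
    background_method: str = "exterior"

    def validate(self) -> None:
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.mask_mode not in ("per-frame", "fixed"):
            raise ValueError("mask_mode must be 'per-frame' or 'fixed'")
        if self.measure not in ("mean", "integrated"):
            raise ValueError("measure must be 'mean' or 'integrated'")


def refine_cell_mask(
    movie: ImageStack,
    cfg: PunctiConfig,
    initial_roi: RegionMask | np.ndarray | None = None,
) -> RegionMask:
    """Cell ROI refined by thresholding a maximal temporal projection.

    The receptor channel's temporal maximum (over t after z-projection)
    is thresholded and smoothed with the same 1-px closing used for the
    endosome mask; an initial manual ROI, when given, bounds the result.
    """
    tmax = max_project_t(movie, channel=cfg.receptor_channel)
    restrict = as_mask(initial_roi) if initial_roi is not None else None
    thr = (
        auto_threshold(tmax, restrict_to=restrict)
        if cfg.cell_threshold == "otsu"
        else float(cfg.cell_threshold)
    )
    mask = threshold_mask(tmax, thr, restrict_to=restrict)
    return smooth_mask(mask, element=cfg.closing_element)


def _endosome_mask(
    marker: np.ndarray, cell: RegionMask, threshold: float, cfg: PunctiConfig
) -> RegionMask:
    mask = threshold_mask(marker, threshold, restrict_to=cell)
    puncta = size_filter(connected_components(mask), cfg.min_area_px)
    filtered = mask.derived(f"size>={cfg.min_area_px}", puncta.labels > 0)
    return smooth_mask(filtered, element=cfg.closing_element)


def puncti_accumulation_trace(
    movie: ImageStack,
    cfg: PunctiConfig | None = None,
    cell_roi: RegionMask | np.ndarray | None = None,
    normalize: bool = True,
) -> TimeSeries:
    """Receptor fluorescence at marker objects over time, baseline-normalized.

    Per frame: build the endosome mask from the marker channel inside
    the refined cell ROI, measure the mean receptor fluorescence inside
    it, subtract the exterior background, then normalize the whole trace
    to the mean over pre-agonist frames (F/F0). Frames whose endosome
    mask is empty are recorded as NaN with a warning, never as zero.
    """
    cfg = cfg or PunctiConfig()
    cfg.validate()
    cal = movie.calibration
    if movie.n_frames < 2:
        raise ValueError("a trafficking movie needs a time axis")
    if cal.agonist_frame is None:
        raise ValueError("calibration must define agonist_frame")

    cell = refine_cell_mask(movie, cfg, initial_roi=cell_roi)

    marker_frames = [max_project_z(movie, cfg.marker_channel, t) for t in range(movie.n_frames)]
    receptor_frames = [
        max_project_z(movie, cfg.receptor_channel, t) for t in range(movie.n_frames)
    ]

    if cfg.marker_threshold == "otsu":
        # threshold chosen once, on the temporal max, as one manual choice would be
        tmax = max_project_t(movie, channel=cfg.marker_channel)
        thr = auto_threshold(tmax, restrict_to=cell)
    else:
        thr = float(cfg.marker_threshold)

    fixed_mask: RegionMask | None = None
    if cfg.mask_mode == "fixed":
        tmax = max_project_t(movie, channel=cfg.marker_channel)
        fixed_mask = _endosome_mask(tmax, cell, thr, cfg)

    values = np.empty(movie.n_frames, dtype=float)
    areas = np.zeros(movie.n_frames, dtype=float)
    for t in range(movie.n_frames):
        mask = fixed_mask if fixed_mask is not None else _endosome_mask(
            marker_frames[t], cell, thr, cfg
        )
        areas[t] = mask.area_px
        if mask.area_px == 0:
            logger.warning("frame %d: empty endosome mask, value recorded as missing", t)
            values[t] = np.nan
            continue
        frame = receptor_frames[t]
        bg = estimate_background(frame, cell, method=cfg.background_method)
        inside = frame[mask.pixels] - bg
        values[t] = inside.mean() if cfg.measure == "mean" else inside.sum()

    raw = TimeSeries(
        movie.times_min(), values, normalization="raw", mask_area_px=areas,
        fsk_frames=cal.fsk_frames,
    )
    if not normalize:
        return raw
    normalized = normalize_baseline(raw, mode="F/F0")
    normalized.mask_area_px = areas.copy()
    return normalized


def normalize_baseline(trace: TimeSeries, mode: str = "F/F0") -> TimeSeries:
    """Normalize a trace to its pre-agonist baseline mean F0.

    ``F/F0`` divides by F0; ``dF/F0`` is ``(F - F0) / F0``. F0 is the
    mean over frames with t < 0; it must be positive for either mode.
    """
    baseline = trace.times_min < 0.0
    if not baseline.any():
        raise ValueError("no pre-agonist baseline frames (t < 0)")
    f0 = np.nanmean(trace.values[baseline])
    if not np.isfinite(f0) or f0 <= 0:
        raise ValueError(f"baseline mean F0 must be positive, got {f0}")
    if mode == "F/F0":
        return trace.with_values(trace.values / f0, "F/F0")
    if mode == "dF/F0":
        return trace.with_values((trace.values - f0) / f0, "dF/F0")
    raise ValueError(f"unknown normalization mode {mode!r}")
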