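"""Biosensor (cAMP / PKA activity) time-course summarization.

Traces are per-cell mean-fluorescence time series, background-subtracted
and expressed as dF/F0 relative to the pre-agonist baseline. Whole-cell
cAMP (cADDis) and non-targeted PKA sensor traces are additionally
divided by their mean during the terminal forskolin/IBMX saturation
epoch, putting them on a fraction-of-maximum scale.

Each trace is summarized by:

* two-phase area under the curve — the early phase over (0, 5] min and
  the late phase over (5, 30] min of agonist treatment (trapezoidal
  rule, phase boundaries hit exactly by linear interpolation);
* the peak — maximum sampled value in (0, 30] min;
* the plateau — mean over [20, 30] min (inclusive).

Summaries can be normalized across conditions by dividing each statistic
by its mean in a designated reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ImageStack, RegionMask, TimeSeries, as_mask
from .enrichment import estimate_background
from .segmentation import max_project_z
from .trafficking import normalize_baseline

__all__ = [
    "PhaseSummary",
    "fskibmx_normalize",
    "integrate_phase",
    "peak_value",
    "peak_time",
    "plateau_value",
    "summarize_phases",
    "normalize_to_condition",
    "roi_trace",
]

EARLY_PHASE = (0.0, 5.0)
LATE_PHASE = (5.0, 30.0)
PEAK_WINDOW = (0.0, 30.0)
PLATEAU_WINDOW = (20.0, 30.0)


@dataclass
class PhaseSummary:
    """Per-cell response summary in dF/F0 (or fraction-of-maximum) units."""

    cell_id: str
    condition: str
    auc_early: float
    auc_late: float
    auc_total: float
    peak: float
    plateau: float
    reference_condition_mean: float | None = None


def fskibmx_normalize(trace: TimeSeries, fsk_frames: tuple[int, int] | None = None) -> TimeSeries:
    """Divide a trace by its mean over the Fsk/IBMX saturation epoch.

    ``fsk_frames`` is a half-open frame-index range; when omitted the
    trace's own recorded epoch is used.
    """
    frames = fsk_frames if fsk_frames is not None else trace.fsk_frames
    if frames is None:
        raise ValueError("no Fsk/IBMX frames recorded or provided")
    lo, hi = frames
    if not (0 <= lo < hi <= trace.values.size):
        raise ValueError(f"fsk_frames {frames} outside the trace")
    sat = np.nanmean(trace.values[lo:hi])
    if not np.isfinite(sat) or sat <= 0:
        raise ValueError(f"Fsk/IBMX epoch mean must be positive, got {sat}")
    return trace.with_values(trace.values / sat, "fsk")


def integrate_phase(trace: TimeSeries, t_start: float, t_end: float) -> float:
    """Trapezoidal area under the trace over [t_start, t_end] minutes.

    Phase boundaries are hit exactly via linear interpolation, so that
    the areas over (0, 5] and (5, 30] sum exactly to the area over
    (0, 30]. Missing (NaN) samples are linearly interpolated for the
    integral only.
    """
    if not (t_start < t_end):
        raise ValueError("t_start must be < t_end")
    t = trace.times_min
    v = trace.values
    ok = np.isfinite(v)
    if not ok.all():
        if ok.sum() < 2:
            raise ValueError("too few finite samples to integrate")
        t, v = t[ok], v[ok]
    # tolerate float slop at the trace ends (one part in 1e9 of the span)
    slack = 1e-9 * max(abs(t[0]), abs(t[-1]), 1.0)
    if t_start < t[0] - slack or t_end > t[-1] + slack:
        raise ValueError(
            f"window [{t_start}, {t_end}] min outside trace span [{t[0]}, {t[-1]}]"
        )
    t_start = max(t_start, t[0])
    t_end = min(t_end, t[-1])
    interior = t[(t > t_start) & (t < t_end)]
    grid = np.concatenate([[t_start], interior, [t_end]])
    vals = np.interp(grid, t, v)
    return float(np.trapezoid(vals, grid))


def peak_value(trace: TimeSeries, window: tuple[float, float] = PEAK_WINDOW) -> float:
    """Maximum sampled value in the (open-start, closed-end) window."""
    sel = trace.window(*window)
    vals = trace.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no finite samples in window {window}")
    return float(vals.max())


def peak_time(trace: TimeSeries, window: tuple[float, float] = PEAK_WINDOW) -> float:
    """Time (min) of the peak; ties resolve to the earliest sample."""
    sel = trace.window(*window)
    t = trace.times_min[sel]
    v = trace.values[sel]
    finite = np.isfinite(v)
    t, v = t[finite], v[finite]
    if v.size == 0:
        raise ValueError(f"no finite samples in window {window}")
    return float(t[np.argmax(v)])  # argmax returns the first maximum


def plateau_value(trace: TimeSeries, window: tuple[float, float] = PLATEAU_WINDOW) -> float:
    """Mean of samples with time in the closed window [20, 30] min."""
    sel = trace.window(*window, include_start=True, include_end=True)
    vals = trace.values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no finite samples in window {window}")
    return float(vals.mean())


def summarize_phases(
    trace: TimeSeries, cell_id: str = "cell", condition: str = ""
) -> PhaseSummary:
    """Two-phase AUC, peak and plateau of one trace."""
    auc_early = integrate_phase(trace, *EARLY_PHASE)
    auc_late = integrate_phase(trace, *LATE_PHASE)
    return PhaseSummary(
        cell_id=cell_id,
        condition=condition,
        auc_early=auc_early,
        auc_late=auc_late,
        auc_total=integrate_phase(trace, EARLY_PHASE[0], LATE_PHASE[1]),
        peak=peak_value(trace),
        plateau=plateau_value(trace),
    )


_STATS = ("auc_early", "auc_late", "auc_total", "peak", "plateau")


def normalize_to_condition(
    summaries: list[PhaseSummary] | pd.DataFrame,
    reference_condition: str,
) -> pd.DataFrame:
    """Divide each statistic by its mean in the reference condition.

    The reference condition's own mean maps to exactly 1.0 for every
    statistic. Returns a DataFrame with the same rows, normalized.
    """
    if isinstance(summaries, pd.DataFrame):
        frame = summaries.copy()
    else:
        frame = pd.DataFrame(
            [
                {
                    "cell_id": s.cell_id,
                    "condition": s.condition,
                    **{k: getattr(s, k) for k in _STATS},
                }
                for s in summaries
            ]
        )
    ref = frame[frame["condition"] == reference_condition]
    if ref.empty:
        raise ValueError(f"reference condition {reference_condition!r} has no cells")
    for stat in _STATS:
        if stat not in frame.columns:
            continue
        ref_mean = ref[stat].mean()
        if ref_mean == 0:
            raise ValueError(f"reference mean of {stat!r} is zero")
        frame[stat] = frame[stat] / ref_mean
        frame[f"{stat}_reference_mean"] = ref_mean
    return frame


def roi_trace(
    movie: ImageStack,
    roi_mask: RegionMask | np.ndarray,
    channel: int = 0,
    background: float | np.ndarray | None = None,
    mode: str = "dF/F0",
) -> TimeSeries:
    """Mean-fluorescence trace of one ROI, background-subtracted, dF/F0.

    Used identically for whole-cell, nuclear, cytoplasmic and
    endosome-targeted sensor movies — only the ROI changes. Background
    may be a scalar, a per-frame array, or None (estimated per frame
    from outside the ROI).
    """
    if mode not in ("raw", "F/F0", "dF/F0"):
        raise ValueError(f"unknown roi_trace mode {mode!r}")
    roi = as_mask(roi_mask)
    if roi.area_px == 0:
        raise ValueError("ROI is empty")
    n = movie.n_frames
    if background is None:
        bg = np.array(
            [
                estimate_background(max_project_z(movie, channel, t), roi)
                for t in range(n)
            ]
        )
    else:
        bg = np.broadcast_to(np.asarray(background, dtype=float), (n,))
    values = np.array(
        [max_project_z(movie, channel, t)[roi.pixels].mean() - bg[t] for t in range(n)]
    )
    raw = TimeSeries(
        movie.times_min(), values, normalization="raw",
        fsk_frames=movie.calibration.fsk_frames,
    )
    if mode == "raw":
        return raw
    return normalize_baseline(raw, mode=mode)
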