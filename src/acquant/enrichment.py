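"""Per-cell compartment localization statistics.

The two headline quantities are the *cilia enrichment index* and the
*endosome enrichment index*: the AC channel's background-subtracted
fluorescence inside a compartment mask divided by its fluorescence over
the whole cell. Two conventions are supported and always recorded:

* ``mean-ratio`` (default): mean compartment intensity / mean cell
  intensity — a concentration enrichment, independent of compartment
  area, equal to 1 for a uniformly fluorescent cell.
* ``integrated-ratio``: summed compartment intensity / summed cell
  intensity — the fraction of total cell fluorescence inside the
  compartment.

Puncta-based classification counts thresholded internal particles after
a minimum-size filter; a cell with 10 or more puncta is "positive"
(endosome-localized AC), and populations are summarized as the
percentage of positive cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ImageStack, RegionMask, as_mask
from .imaging_io import RoiSpec, rasterize_roi
from .segmentation import (
    connected_components,
    max_project_z,
    size_filter,
    threshold_mask,
)

logger = logging.getLogger("acquant")

__all__ = [
    "EnrichmentResult",
    "CellClassification",
    "estimate_background",
    "enrichment_index",
    "endosome_mask_from_marker",
    "count_internal_puncta",
    "fraction_positive",
    "cilia_enrichment",
]

CONVENTIONS = ("mean-ratio", "integrated-ratio")


@dataclass
class EnrichmentResult:
    """Enrichment of a channel in one compartment of one cell."""

    cell_id: str
    compartment: str
    index: float
    compartment_fluorescence: float
    cell_fluorescence: float
    background: float
    convention: str
    empty_compartment: bool = False
    provenance: tuple[str, ...] = ()


@dataclass
class CellClassification:
    """Puncta count and positivity call for one cell."""

    cell_id: str
    n_puncta: int
    positive: bool
    threshold_puncta: int = 10


def estimate_background(
    image: np.ndarray,
    cell_mask: RegionMask | np.ndarray,
    method: str = "exterior",
    background_roi: RegionMask | np.ndarray | None = None,
    percentile: float = 5.0,
) -> float:
    """Estimate the per-pixel background level of a frame.

    ``exterior`` (default) averages pixels outside the cell mask,
    optionally restricted to an explicit background ROI; ``percentile``
    takes the p-th percentile of the whole frame.
    """
    image = np.asarray(image, dtype=float)
    cell = as_mask(cell_mask)
    if method == "exterior":
        if background_roi is not None:
            region = as_mask(background_roi).pixels & ~cell.pixels
        else:
            region = ~cell.pixels
        if not region.any():
            raise ValueError("no exterior pixels available for background estimation")
        return float(image[region].mean())
    if method == "percentile":
        return float(np.percentile(image, percentile))
    raise ValueError(f"unknown background method {method!r}")


def enrichment_index(
    image: np.ndarray,
    compartment_mask: RegionMask | np.ndarray,
    cell_mask: RegionMask | np.ndarray,
    background: float = 0.0,
    convention: str = "mean-ratio",
    cell_id: str = "cell",
    compartment: str = "compartment",
) -> EnrichmentResult:
    """Compartment-to-cell fluorescence ratio after background subtraction.

    The compartment mask is intersected with the cell mask (and the
    intersection logged) so the compartment is always a sub-region of
    the cell. Background-subtracted pixel values are clipped at zero
    before the ratio. An empty compartment yields index 0 with the
    ``empty_compartment`` flag set; a cell with zero fluorescence after
    subtraction is an error, since the ratio is undefined.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    image = np.asarray(image, dtype=float)
    cell = as_mask(cell_mask)
    comp = as_mask(compartment_mask)
    if cell.area_px == 0:
        raise ValueError("cell mask is empty")
    inter = comp.pixels & cell.pixels
    if inter.sum() != comp.area_px:
        logger.info(
            "compartment mask clipped to cell: %d -> %d px", comp.area_px, int(inter.sum())
        )
    vals = np.clip(image - background, 0.0, None)

    cell_vals = vals[cell.pixels]
    if not inter.any():
        logger.warning("empty compartment mask for %s/%s: index set to 0", cell_id, compartment)
        return EnrichmentResult(
            cell_id, compartment, 0.0, 0.0, float(cell_vals.sum()), background,
            convention, empty_compartment=True,
            provenance=tuple(comp.provenance),
        )
    comp_vals = vals[inter]
    if cell_vals.sum() <= 0:
        raise ValueError("cell fluorescence is zero after background subtraction")
    if convention == "mean-ratio":
        index = comp_vals.mean() / cell_vals.mean()
    else:
        index = comp_vals.sum() / cell_vals.sum()
    return EnrichmentResult(
        cell_id=cell_id,
        compartment=compartment,
        index=float(index),
        compartment_fluorescence=float(comp_vals.sum()),
        cell_fluorescence=float(cell_vals.sum()),
        background=background,
        convention=convention,
        provenance=tuple(comp.provenance),
    )


def endosome_mask_from_marker(
    marker_image: np.ndarray,
    cell_mask: RegionMask | np.ndarray,
    threshold: float,
) -> RegionMask:
    """Endosome mask: marker pixels above threshold, inside the cell ROI.

    The resulting mask is applied to the AC channel by
    :func:`enrichment_index` to measure endosomal enrichment.
    """
    return threshold_mask(marker_image, threshold, restrict_to=as_mask(cell_mask))


def count_internal_puncta(
    ac_image: np.ndarray,
    cell_mask: RegionMask | np.ndarray,
    threshold: float,
    min_area_px: int = 3,
    positivity_threshold: int = 10,
    connectivity: int = 8,
    cell_id: str = "cell",
) -> CellClassification:
    """Count thresholded internal particles and call positivity.

    Pipeline: strict threshold inside the cell ROI, connected-component
    labeling, minimum-size filter; positive iff the count reaches
    ``positivity_threshold`` (default 10, inclusive).
    """
    mask = threshold_mask(ac_image, threshold, restrict_to=as_mask(cell_mask))
    puncta = size_filter(connected_components(mask, connectivity=connectivity), min_area_px)
    n = puncta.n_puncta
    return CellClassification(
        cell_id=cell_id,
        n_puncta=n,
        positive=n >= positivity_threshold,
        threshold_puncta=positivity_threshold,
    )


def fraction_positive(
    classifications: Sequence[CellClassification],
) -> tuple[float, int, int]:
    """Percentage of positive cells: ``(percent, n_positive, n_total)``."""
    if len(classifications) == 0:
        raise ValueError("need at least one cell")
    n_pos = sum(1 for c in classifications if c.positive)
    n_tot = len(classifications)
    return 100.0 * n_pos / n_tot, n_pos, n_tot


def cilia_enrichment(
    stack: ImageStack,
    cilium_roi: RoiSpec | RegionMask | np.ndarray,
    cell_roi: RoiSpec | RegionMask | np.ndarray,
    ac_channel: int = 1,
    t: int = 0,
    background: float | None = None,
    convention: str = "mean-ratio",
    cell_id: str = "cell",
) -> EnrichmentResult:
    """Cilia enrichment index on an (unprocessed) maximum z-projection.

    ROIs are drawn on the cilium-marker channel and applied to the AC
    channel: z-max-project the AC channel, rasterize the ROIs, estimate
    background outside the cell when not given, then form the ratio.
    """
    ac = max_project_z(stack, channel=ac_channel, t=t)

    def _to_mask(roi) -> RegionMask:
        if isinstance(roi, RoiSpec):
            return rasterize_roi(roi, ac.shape)
        return as_mask(roi)

    cilium = _to_mask(cilium_roi)
    cell = _to_mask(cell_roi)
    if background is None:
        background = estimate_background(ac, cell)
    return enrichment_index(
        ac, cilium, cell, background=background, convention=convention,
        cell_id=cell_id, compartment="cilium",
    )
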