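"""Reading and writing the formats the pipeline touches.

TIFF stacks (with calibration metadata), polygon/label-image ROIs, and
CSV tables. Axis order is normalized to ``(t, z, c, y, x)`` on read; a
stack whose axis semantics cannot be determined from metadata must be
read with an explicit ``axes`` override — there is no silent default.

ROI JSON schema (defined by this package)::

    {"rois": [{"id": "cell1", "kind": "polygon",
               "vertices": [[y, x], ...], "channel": 0}]}

Polygon vertices are in continuous image coordinates with pixel centers
at integer points; rasterization uses the even-odd fill rule and
includes a pixel iff its center lies inside the polygon.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import Calibration, CalibrationError, ImageStack, RegionMask

__all__ = [
    "RoiSpec",
    "read_stack",
    "write_stack",
    "read_rois",
    "write_rois",
    "rasterize_roi",
    "write_table",
    "read_table",
    "write_mask",
    "read_mask",
]

_AXES = "TZCYX"


@dataclass(frozen=True)
class RoiSpec:
    """A region-of-interest definition.

    ``kind`` is ``"polygon"`` (vertices in (y, x)) or ``"label"``
    (a label value in an external label image). ``channel`` records the
    channel the ROI was drawn on (e.g. the cilium marker channel).
    """

    roi_id: str
    kind: str = "polygon"
    vertices: tuple[tuple[float, float], ...] | None = None
    label_value: int | None = None
    channel: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError(f"polygon ROI {self.roi_id!r} needs >= 3 vertices")
        elif self.kind == "label":
            if self.label_value is None:
                raise ValueError(f"label ROI {self.roi_id!r} needs a label value")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")


# ---------------------------------------------------------------------------
# TIFF stacks


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF with calibration in the metadata."""
    cal = stack.calibration
    meta: dict[str, Any] = {"axes": _AXES, "pixel_size_um": cal.pixel_size_um}
    if cal.frame_interval_s is not None:
        meta["frame_interval_s"] = cal.frame_interval_s
    if cal.agonist_frame is not None:
        meta["agonist_frame"] = cal.agonist_frame
    if cal.fsk_frames is not None:
        meta["fsk_frames"] = list(cal.fsk_frames)
    if cal.z_step_um is not None:
        meta["z_step_um"] = cal.z_step_um
    tifffile.imwrite(path, stack.pixels, metadata=meta, photometric="minisblack")


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with named axes into (t, z, c, y, x)."""
    axes = axes.upper()
    # tifffile uses Q/S for unknown/sample axes; a trailing unknown pair is YX
    if len(axes) != data.ndim:
        raise CalibrationError(f"axes {axes!r} do not match data ndim {data.ndim}")
    if "Y" not in axes or "X" not in axes:
        raise CalibrationError(f"axes {axes!r} lack Y/X")
    for ax in axes:
        if ax not in _AXES:
            raise CalibrationError(f"unsupported axis {ax!r} in {axes!r}")
    if len(set(axes)) != len(axes):
        raise CalibrationError(f"duplicate axes in {axes!r}")
    out = data
    order = [axes.index(ax) for ax in _AXES if ax in axes]
    out = np.transpose(out, order)
    present = [ax for ax in _AXES if ax in axes]
    for i, ax in enumerate(_AXES):
        if ax not in present:
            out = np.expand_dims(out, i)
    return out


def read_stack(
    path: str | Path,
    calibration_override: Mapping[str, Any] | Calibration | None = None,
    axes: str | None = None,
) -> tuple[ImageStack, Calibration]:
    """Read a TIFF stack, normalizing axes to (t, z, c, y, x).

    Calibration is taken from the file metadata; fields given in
    ``calibration_override`` (a mapping or a full :class:`Calibration`)
    take precedence. Missing pixel size with no override is an error —
    never a silent default. ``axes`` overrides ambiguous axis metadata.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        meta: dict[str, Any] = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
        file_axes = meta.get("axes", series.axes)

    if axes is not None:
        file_axes = axes
    elif data.ndim == 2:
        file_axes = "YX"
    if any(ax not in _AXES for ax in file_axes.upper()):
        raise CalibrationError(
            f"ambiguous axis metadata {file_axes!r} in {path.name}; pass axes=..."
        )
    pixels = _normalize_axes(data, file_axes)

    fields: dict[str, Any] = {
        "pixel_size_um": meta.get("pixel_size_um"),
        "frame_interval_s": meta.get("frame_interval_s"),
        "agonist_frame": meta.get("agonist_frame"),
        "fsk_frames": tuple(meta["fsk_frames"]) if meta.get("fsk_frames") else None,
        "z_step_um": meta.get("z_step_um"),
    }
    if isinstance(calibration_override, Calibration):
        override = {
            "pixel_size_um": calibration_override.pixel_size_um,
            "frame_interval_s": calibration_override.frame_interval_s,
            "agonist_frame": calibration_override.agonist_frame,
            "fsk_frames": calibration_override.fsk_frames,
            "z_step_um": calibration_override.z_step_um,
        }
    else:
        override = dict(calibration_override or {})
    for key, value in override.items():
        if key not in fields:
            raise CalibrationError(f"unknown calibration field {key!r}")
        if value is not None:
            fields[key] = value
    if fields["pixel_size_um"] is None:
        raise CalibrationError(
            f"{path.name} carries no pixel size and none was provided; "
            "pass calibration_override={'pixel_size_um': ...}"
        )
    if pixels.shape[0] > 1 and fields["frame_interval_s"] is None:
        raise CalibrationError(
            f"{path.name} is a time series but carries no frame interval"
        )
    cal = Calibration(**fields)
    return ImageStack(pixels, cal), cal


def write_mask(path: str | Path, mask: RegionMask | np.ndarray) -> None:
    """Write a binary or label mask as uint8/uint16 TIFF."""
    arr = mask.pixels if isinstance(mask, RegionMask) else np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(path, arr)


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# ROIs


def write_rois(path: str | Path, rois: Sequence[RoiSpec]) -> None:
    records = []
    for roi in rois:
        rec: dict[str, Any] = {"id": roi.roi_id, "kind": roi.kind}
        if roi.kind == "polygon":
            rec["vertices"] = [list(v) for v in roi.vertices]
        else:
            rec["label_value"] = roi.label_value
        if roi.channel is not None:
            rec["channel"] = roi.channel
        records.append(rec)
    Path(path).write_text(json.dumps({"rois": records}, indent=1))


def read_rois(path: str | Path) -> list[RoiSpec]:
    payload = json.loads(Path(path).read_text())
    rois = []
    for rec in payload["rois"]:
        rois.append(
            RoiSpec(
                roi_id=str(rec["id"]),
                kind=rec.get("kind", "polygon"),
                vertices=tuple(tuple(map(float, v)) for v in rec["vertices"])
                if "vertices" in rec
                else None,
                label_value=rec.get("label_value"),
                channel=rec.get("channel"),
            )
        )
    return rois


def rasterize_roi(
    roi: RoiSpec,
    image_shape: tuple[int, int],
    label_image: np.ndarray | None = None,
) -> RegionMask:
    """Rasterize an ROI to a binary mask.

    Polygons are filled with the even-odd rule; a pixel belongs to the
    mask iff its center (integer coordinates) lies inside. Label ROIs
    select equal-valued pixels of ``label_image``.
    """
    ny, nx = image_shape
    if roi.kind == "label":
        if label_image is None:
            raise ValueError("label ROI requires a label image")
        return RegionMask(
            np.asarray(label_image) == roi.label_value,
            provenance=[f"label=={roi.label_value}"],
        )

    verts = np.asarray(roi.vertices, dtype=float)
    if np.any(verts[:, 0] < -0.5) or np.any(verts[:, 0] > ny - 0.5) or np.any(
        verts[:, 1] < -0.5
    ) or np.any(verts[:, 1] > nx - 0.5):
        raise ValueError(f"ROI {roi.roi_id!r} has vertices outside the image bounds")

    mask = _fill_polygon_even_odd(verts, image_shape)
    if not mask.any():
        warnings.warn(f"ROI {roi.roi_id!r} rasterized to an empty mask", stacklevel=2)
    return RegionMask(mask, provenance=[f"roi:{roi.roi_id}"])


def _fill_polygon_even_odd(verts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd ray casting over the grid of pixel centers.

    For each pixel center a horizontal ray toward -x counts crossings of
    polygon edges; odd count means inside. Edges are taken half-open in y
    (``y1 <= py < y2``) so shared vertices are counted once.
    """
    ny, nx = shape
    py = np.arange(ny, dtype=float)[:, None]  # pixel centers
    px = np.arange(nx, dtype=float)[None, :]
    inside = np.zeros(shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        y1, x1 = verts[k]
        y2, x2 = verts[(k + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crosses a horizontal ray transversally
        straddles = (y1 > py) != (y2 > py)
        with np.errstate(invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (px < x_at)
    return inside


# ---------------------------------------------------------------------------
# Tables


def write_table(records: Iterable[Mapping[str, Any]] | pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None) -> None:
    """Write records as UTF-8 CSV with header and stable column order.

    Floats are serialized with 12 significant digits so a roundtrip
    preserves values to well below 1e-9 relative error.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        frame = pd.DataFrame.from_records(records)
        if columns is None and records:
            columns = list(records[0].keys())
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    frame.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
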