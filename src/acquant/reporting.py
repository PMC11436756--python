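"""Group statistics and the configured pipeline runner.

Statistics follow the study design the pipeline serves: the unit of
replication is an independent culture/dish, so cells are averaged
within replicate first and summary statistics (mean +/- s.e.m.) are
computed over replicate means. Significance uses the classical Student
two-sample t-test (pooled variance) or its paired variant, two-tailed.

:func:`run_pipeline` executes a declarative stage list and writes every
output table plus a ``manifest.json`` recording the package version, the
seed, and every numeric parameter and convention each stage consumed, so
reruns are auditable and bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from . import __version__
from .biosensor import fskibmx_normalize, normalize_to_condition, summarize_phases
from .core import TimeSeries
from .colocalization import classify_colocalized, detect_spots
from .enrichment import (
    count_internal_puncta,
    endosome_mask_from_marker,
    enrichment_index,
    estimate_background,
    fraction_positive,
)
from .imaging_io import read_mask, read_stack, read_table, write_mask, write_stack, write_table
from .segmentation import auto_threshold, max_project_z, threshold_mask
from .synthetic import (
    KineticConfig,
    SceneConfig,
    simulate_biosensor_trace,
    simulate_static_scene,
    simulate_trafficking_movie,
)
from .trafficking import PunctiConfig, normalize_baseline, puncti_accumulation_trace

logger = logging.getLogger("acquant")

__all__ = ["GroupSummary", "TTestResult", "summarize_group", "two_sample_t_test", "run_pipeline"]


@dataclass
class GroupSummary:
    """Replicate-level summary of one condition."""

    condition: str
    n_replicates: int
    n_cells_total: int
    mean: float
    sem: float  # sample sd of replicate means / sqrt(n_replicates); NaN for n = 1
    replicate_means: tuple[float, ...] = ()


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    paired: bool


def summarize_group(
    values_per_replicate: Sequence[Sequence[float]] | Sequence[float],
    condition: str = "",
    cell_level: bool = False,
) -> GroupSummary:
    """Mean +/- s.e.m. over replicate means (cells averaged first).

    ``values_per_replicate`` is either a sequence of per-replicate cell
    values, or a flat sequence already at replicate level. With
    ``cell_level=True`` all cells are pooled into one flat sample
    instead (reported explicitly, never the default).
    """
    if len(values_per_replicate) == 0:
        raise ValueError("need at least one replicate")
    if np.ndim(values_per_replicate[0]) == 0:
        groups = [[float(v)] for v in values_per_replicate]
    else:
        groups = [list(map(float, g)) for g in values_per_replicate]
    if any(len(g) == 0 for g in groups):
        raise ValueError("each replicate needs at least one cell")
    n_cells = sum(len(g) for g in groups)
    if cell_level:
        pooled = np.concatenate([np.asarray(g) for g in groups])
        means = pooled
    else:
        means = np.array([np.mean(g) for g in groups])
    n = means.size
    sem = float(np.std(means, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    if n == 1:
        logger.warning("single replicate: s.e.m. reported as missing")
    return GroupSummary(
        condition=condition,
        n_replicates=len(groups),
        n_cells_total=n_cells,
        mean=float(np.mean(means)),
        sem=sem,
        replicate_means=tuple(float(m) for m in means),
    )


def two_sample_t_test(
    group_a: Sequence[float], group_b: Sequence[float], paired: bool = False
) -> TTestResult:
    """Two-tailed Student t-test (pooled variance), or paired t-test.

    Degenerate case: zero variance in both groups with equal means gives
    t = 0, p = 1 by convention (logged) rather than a division error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        if a.size < 2:
            raise ValueError("paired test requires n >= 2")
        d = a - b
        n = d.size
        sd = d.std(ddof=1)
        df = n - 1
        if sd == 0:
            logger.info("all paired differences equal: t = 0, p = 1 by convention")
            t_stat = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        else:
            t_stat = d.mean() / (sd / np.sqrt(n))
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("unpaired test requires n >= 2 per group")
        na, nb = a.size, b.size
        df = na + nb - 2
        pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        if pooled_var == 0:
            if a.mean() == b.mean():
                logger.info("zero variance, equal means: t = 0, p = 1 by convention")
                t_stat = 0.0
            else:
                t_stat = np.inf * np.sign(a.mean() - b.mean())
        else:
            t_stat = (a.mean() - b.mean()) / np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    if np.isinf(t_stat):
        p = 0.0
    else:
        p = float(2.0 * sstats.t.sf(abs(t_stat), df))
    return TTestResult(t=float(t_stat), df=int(df), p=p, paired=paired)


# ---------------------------------------------------------------------------
# pipeline runner

_STAGES = (
    "simulate-scene",
    "simulate-movie",
    "simulate-trace",
    "enrich",
    "puncta",
    "traffick",
    "biosensor",
    "coloc",
    "report",
)


class ConfigSchemaError(ValueError):
    """Pipeline configuration does not match the expected schema."""


def _build_dataclass(cls, params: Mapping[str, Any], context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    bad = sorted(set(params) - known)
    if bad:
        raise ConfigSchemaError(f"{context}: unknown keys {bad}")
    obj = cls(**{k: _tuplify(v) for k, v in params.items()})
    if hasattr(obj, "validate"):
        obj.validate()
    return obj


def _tuplify(value):
    return tuple(value) if isinstance(value, list) else value


def _resolve_cell_mask(stage: Mapping[str, Any], ac_image, out: dict) -> np.ndarray:
    if "cell_mask" in stage:
        mask = read_mask(stage["cell_mask"]).astype(bool)
        out["cell_mask"] = str(stage["cell_mask"])
        return mask
    thr = stage.get("cell_threshold", "otsu")
    thr = auto_threshold(ac_image) if thr == "otsu" else float(thr)
    out["cell_threshold"] = thr
    return threshold_mask(ac_image, thr).pixels


def run_pipeline(
    config: Mapping[str, Any], out_dir: str | Path, seed: int = 0
) -> Path:
    """Execute the configured stages and write outputs plus a manifest.

    ``config`` is ``{"stages": [{"stage": <name>, ...params}, ...]}``.
    A schema-invalid config raises :class:`ConfigSchemaError` listing
    the offending keys. Returns the output directory.
    """
    if not isinstance(config, Mapping) or "stages" not in config:
        raise ConfigSchemaError("config must be a mapping with a 'stages' list")
    stages = config["stages"]
    if not isinstance(stages, (list, tuple)):
        raise ConfigSchemaError("'stages' must be a list")
    bad = [s.get("stage") for s in stages if s.get("stage") not in _STAGES]
    if bad:
        raise ConfigSchemaError(f"unknown stages {bad}; known: {list(_STAGES)}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "acquant",
        "version": __version__,
        "seed": seed,
        "stages": [],
    }
    for i, stage in enumerate(stages):
        name = stage["stage"]
        record = _run_stage(name, stage, out_dir, seed, i)
        manifest["stages"].append({"stage": name, **record})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out_dir


def _run_stage(name: str, stage: Mapping[str, Any], out_dir: Path, seed: int,
               index: int) -> dict[str, Any]:
    prefix = stage.get("prefix", f"{index:02d}_{name.replace('-', '_')}")
    record: dict[str, Any] = {"prefix": prefix}

    if name == "simulate-scene":
        cfg = _build_dataclass(SceneConfig, {"seed": seed, **stage.get("scene", {})},
                               "simulate-scene.scene")
        stack, truth = simulate_static_scene(cfg)
        write_stack(out_dir / f"{prefix}.tif", stack)
        for comp in ("cell", "cilium", "endosomes"):
            write_mask(out_dir / f"{prefix}_mask_{comp}.tif", truth.masks[comp])
        (out_dir / f"{prefix}.truth.json").write_text(
            json.dumps({"true_enrichment": truth.true_enrichment, "params": truth.params},
                       indent=1, default=str)
        )
        record["scene"] = dataclasses.asdict(cfg)

    elif name == "simulate-movie":
        scene = _build_dataclass(SceneConfig, {"seed": seed, **stage.get("scene", {})},
                                 "simulate-movie.scene")
        kin = _build_dataclass(KineticConfig, {"seed": seed, **stage.get("kinetics", {})},
                               "simulate-movie.kinetics")
        stack, truth = simulate_trafficking_movie(scene, kin)
        write_stack(out_dir / f"{prefix}.tif", stack)
        (out_dir / f"{prefix}.truth.json").write_text(
            json.dumps(
                {
                    "times_min": truth.times_min.tolist(),
                    "internalized_fraction": truth.internalized_fraction.tolist(),
                    "expected_trace": truth.expected_trace.tolist(),
                    "params": truth.params,
                },
                indent=1, default=str,
            )
        )
        record["scene"] = dataclasses.asdict(scene)
        record["kinetics"] = dataclasses.asdict(kin)

    elif name == "simulate-trace":
        kin = _build_dataclass(KineticConfig, {"seed": seed, **stage.get("kinetics", {})},
                               "simulate-trace.kinetics")
        trace, truth = simulate_biosensor_trace(kin)
        write_table(
            [{"time_min": t, "value": v} for t, v in zip(trace.times_min, trace.values)],
            out_dir / f"{prefix}.csv",
        )
        (out_dir / f"{prefix}.truth.json").write_text(
            json.dumps({"trace_params": truth.trace_params, "params": truth.params},
                       indent=1, default=str)
        )
        record["kinetics"] = dataclasses.asdict(kin)

    elif name == "enrich":
        stack, _ = read_stack(stage["stack"],
                              calibration_override=stage.get("calibration"))
        marker_c = int(stage.get("marker_channel", 0))
        ac_c = int(stage.get("ac_channel", 1))
        convention = stage.get("convention", "mean-ratio")
        ac = max_project_z(stack, channel=ac_c)
        marker = max_project_z(stack, channel=marker_c)
        cell = _resolve_cell_mask(stage, ac, record)
        thr = stage.get("marker_threshold", "otsu")
        thr = auto_threshold(marker, restrict_to=cell) if thr == "otsu" else float(thr)
        background = stage.get("background")
        background = (estimate_background(ac, cell) if background is None
                      else float(background))
        endo = endosome_mask_from_marker(marker, cell, thr)
        result = enrichment_index(ac, endo, cell, background=background,
                                  convention=convention,
                                  cell_id=stage.get("cell_id", "cell"),
                                  compartment="endosome")
        write_table([dataclasses.asdict(result)], out_dir / f"{prefix}.csv")
        record.update(
            marker_threshold=thr, background=background, convention=convention,
            marker_channel=marker_c, ac_channel=ac_c, index=result.index,
        )

    elif name == "puncta":
        stack, _ = read_stack(stage["stack"],
                              calibration_override=stage.get("calibration"))
        ac_c = int(stage.get("ac_channel", 1))
        ac = max_project_z(stack, channel=ac_c)
        cell = _resolve_cell_mask(stage, ac, record)
        thr = stage.get("threshold", "otsu")
        thr = auto_threshold(ac, restrict_to=cell) if thr == "otsu" else float(thr)
        min_area = int(stage.get("min_area_px", 3))
        pos_thr = int(stage.get("positivity_threshold", 10))
        cls = count_internal_puncta(ac, cell, thr, min_area_px=min_area,
                                    positivity_threshold=pos_thr,
                                    cell_id=stage.get("cell_id", "cell"))
        write_table([dataclasses.asdict(cls)], out_dir / f"{prefix}.csv")
        record.update(threshold=thr, min_area_px=min_area,
                      positivity_threshold=pos_thr, n_puncta=cls.n_puncta)

    elif name == "traffick":
        stack, _ = read_stack(stage["stack"],
                              calibration_override=stage.get("calibration"))
        cfg = _build_dataclass(PunctiConfig, stage.get("puncti", {}), "traffick.puncti")
        raw = puncti_accumulation_trace(stack, cfg, normalize=False)
        normalized = normalize_baseline(raw, mode="F/F0")
        write_table(
            [
                {"time_min": t, "raw": r, "normalized": v, "mask_area_px": a}
                for t, r, v, a in zip(raw.times_min, raw.values, normalized.values,
                                      raw.mask_area_px)
            ],
            out_dir / f"{prefix}.csv",
        )
        record["puncti"] = dataclasses.asdict(cfg)

    elif name == "biosensor":
        frame = read_table(stage["traces"])
        fsk_window = stage.get("fsk_window_min")  # [start, end] in minutes
        condition_col = "condition" if "condition" in frame.columns else None
        cell_col = "cell_id" if "cell_id" in frame.columns else None
        summaries = []
        keys = frame[cell_col].unique() if cell_col else ["cell"]
        for cell_id in keys:
            sub = frame[frame[cell_col] == cell_id] if cell_col else frame
            trace = TimeSeries(sub["time_min"].to_numpy(), sub["value"].to_numpy(),
                               normalization="dF/F0")
            if fsk_window is not None:
                lo, hi = fsk_window
                sel = (trace.times_min >= lo) & (trace.times_min <= hi)
                idx = np.nonzero(sel)[0]
                trace = fskibmx_normalize(trace, (int(idx[0]), int(idx[-1]) + 1))
            condition = str(sub[condition_col].iloc[0]) if condition_col else ""
            summaries.append(summarize_phases(trace, cell_id=str(cell_id),
                                              condition=condition))
        rows = [dataclasses.asdict(s) for s in summaries]
        write_table(rows, out_dir / f"{prefix}.csv")
        reference = stage.get("reference_condition")
        if reference is not None:
            write_table(normalize_to_condition(summaries, reference),
                        out_dir / f"{prefix}_normalized.csv")
            record["reference_condition"] = reference
        record.update(fsk_window_min=fsk_window, n_cells=len(summaries))

    elif name == "coloc":
        stack, cal = read_stack(stage["stack"],
                                calibration_override=stage.get("calibration"))
        spot_c = int(stage.get("spot_channel", 1))
        ref_c = int(stage.get("reference_channel", 0))
        spot_img = max_project_z(stack, channel=spot_c)
        ref_img = max_project_z(stack, channel=ref_c)
        spot_thr = stage.get("spot_threshold", "otsu")
        spot_thr = auto_threshold(spot_img) if spot_thr == "otsu" else float(spot_thr)
        ref_thr = stage.get("reference_threshold", "otsu")
        ref_thr = auto_threshold(ref_img) if ref_thr == "otsu" else float(ref_thr)
        min_sep = int(stage.get("min_separation_px", 3))
        max_dist = float(stage.get("max_distance_um", 1.0))
        spots = detect_spots(spot_img, intensity_threshold=spot_thr,
                             min_separation_px=min_sep)
        reference = threshold_mask(ref_img, ref_thr)
        result = classify_colocalized(spots, reference, cal.pixel_size_um,
                                      max_distance_um=max_dist)
        write_table(
            [
                {"spot_id": s.spot_id, "y": s.centroid[0], "x": s.centroid[1],
                 "distance_um": d, "colocalized": bool(c)}
                for s, d, c in zip(spots.spots, result.distances_um, result.colocalized)
            ],
            out_dir / f"{prefix}.csv",
            columns=["spot_id", "y", "x", "distance_um", "colocalized"],
        )
        write_table(
            [{"n_spots_total": result.n_spots_total,
              "n_colocalized": result.n_colocalized,
              "max_distance_um": result.max_distance_um}],
            out_dir / f"{prefix}_summary.csv",
        )
        record.update(spot_threshold=spot_thr, reference_threshold=ref_thr,
                      min_separation_px=min_sep, max_distance_um=max_dist)

    elif name == "report":
        frame = read_table(stage["values"])
        required = {"condition", "replicate", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigSchemaError(f"report.values: missing columns {sorted(missing)}")
        summaries = []
        for condition, sub in frame.groupby("condition", sort=True):
            groups = [g["value"].tolist() for _, g in sub.groupby("replicate", sort=True)]
            summary = summarize_group(groups, condition=str(condition))
            summaries.append(summary)
        write_table(
            [
                {k: v for k, v in dataclasses.asdict(s).items() if k != "replicate_means"}
                for s in summaries
            ],
            out_dir / f"{prefix}.csv",
        )
        paired = bool(stage.get("paired", False))
        if len(summaries) == 2:
            test = two_sample_t_test(summaries[0].replicate_means,
                                     summaries[1].replicate_means, paired=paired)
            (out_dir / f"{prefix}_ttest.json").write_text(
                json.dumps(dataclasses.asdict(test), indent=1)
            )
            record["t_test"] = dataclasses.asdict(test)
        record.update(paired=paired, n_conditions=len(summaries))

    else:  # pragma: no cover - guarded by schema validation
        raise ConfigSchemaError(f"unknown stage {name!r}")
    return record
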