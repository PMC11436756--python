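"""Synthetic fluorescence-microscopy generator with known ground truth.

Emulates the three kinds of data the quantification pipeline consumes:

* **Static neuron scenes** — a medium-spiny-neuron-like cell (elliptical
  soma, radial processes, a thin primary cilium abutting the soma, and
  punctate endosomes) rendered into a two-channel image: a compartment
  *marker* channel (cilium/endosome marker, e.g. Arl13b or EEA1) and an
  *AC* channel whose compartment enrichment is configurable.
* **Trafficking movies** — a surface-labeled receptor redistributing to
  stationary endosomes after agonist addition at t = 0 with first-order
  kinetics, alongside a stable endosome-marker channel.
* **Biosensor traces** — cAMP/PKA activity time courses with a fast
  rise, partial decay to a sustained plateau, and a terminal
  forskolin/IBMX saturation epoch.

Camera noise is Poisson on (signal + background) followed by additive
Gaussian read noise, clipped at zero. Every simulator is bit-identical
for identical (config, seed).

Compartments are painted as exact pixel sets (pixel-center containment)
so the stored ground-truth masks are the same set objects a perfect
segmentation would recover, and the true enrichment index is an exact
pixel statistic of the pre-noise image.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from dataclasses import replace as dataclass_replace
from typing import Any

import numpy as np
from scipy import ndimage as ndi

from .core import Calibration, ConfigurationError, ImageStack, TimeSeries

__all__ = [
    "SceneConfig",
    "KineticConfig",
    "GroundTruth",
    "simulate_static_scene",
    "simulate_trafficking_movie",
    "simulate_biosensor_trace",
    "matched_peak_variant",
    "biosensor_response",
    "internalized_fraction",
]

MARKER_CHANNEL = 0
AC_CHANNEL = 1  # also the receptor channel in trafficking movies


@dataclass
class SceneConfig:
    """Geometry and photometry of a static two-channel neuron scene.

    Intensities are mean photon counts per pixel. Compartment factors
    multiply ``base_cell`` *inside* the compartment (replacement, not
    addition), so a factor of 1 paints a uniform cell.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    n_z: int = 1
    soma_center: tuple[float, float] | None = None  # default: image center
    soma_radii: tuple[float, float] = (55.0, 65.0)  # px, (y, x)
    n_processes: int = 4
    process_length_px: float = 55.0
    process_width_px: float = 5.0
    cilium_length_px: float = 40.0
    cilium_width_px: float = 4.0
    n_endosomes: int = 12
    endosome_radius_px: tuple[float, float] = (3.0, 5.0)
    membrane_width_px: int = 2
    base_cell: float = 50.0
    cilium_factor: float = 5.0
    endosome_factor: float = 4.0
    plasma_membrane_factor: float = 1.5
    marker_base: float = 10.0
    marker_level: float = 200.0
    marker_target: str = "endosomes"  # "endosomes", "cilium", or "both"
    background: float = 10.0
    poisson_on: bool = True
    gaussian_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        ny, nx = self.image_shape
        cy, cx = self.center
        ry, rx = self.soma_radii
        if not (self.pixel_size_um > 0):
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.n_z < 1:
            raise ConfigurationError("n_z must be >= 1")
        for name in ("base_cell", "marker_base", "marker_level", "background", "gaussian_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("cilium_factor", "endosome_factor", "plasma_membrane_factor"):
            if not (getattr(self, name) > 0):
                raise ConfigurationError(f"{name} must be > 0")
        if self.marker_target not in ("endosomes", "cilium", "both"):
            raise ConfigurationError("marker_target must be 'endosomes', 'cilium' or 'both'")
        reach = max(self.process_length_px, 0.0)
        if cy - ry - self.cilium_length_px < 0:
            raise ConfigurationError(
                "cilium_length_px: cilium extends above the image bounds"
            )
        if cy + ry + reach > ny - 1 or cx + rx + reach > nx - 1 or cy - ry - reach < 0 \
                or cx - rx - reach < 0:
            raise ConfigurationError(
                "soma_radii/process_length_px: cell geometry exceeds image bounds"
            )
        rmax = max(self.endosome_radius_px)
        if rmax + self.membrane_width_px >= min(ry, rx):
            raise ConfigurationError("endosome_radius_px too large for the soma")

    @property
    def center(self) -> tuple[float, float]:
        if self.soma_center is not None:
            return self.soma_center
        ny, nx = self.image_shape
        return (ny / 2.0, nx / 2.0)


@dataclass
class KineticConfig:
    """Timing and kinetic parameters for live-cell simulations.

    Defaults mirror the acquisition protocol the pipeline is built for:
    20 s frames, a 1 min pre-agonist baseline, a 30 min follow-up, and a
    2 min terminal forskolin/IBMX saturation epoch.

    The biosensor trace model is
    ``r(t) = A (1 - exp(-t/tau_rise)) (p + (1 - p) exp(-t/tau_decay))``
    for t >= 0 (0 before): a saturating rise times a partial exponential
    decay to the sustained fraction ``p`` of the amplitude. Defaults put
    the peak at roughly 3 min after agonist.
    """

    frame_interval_s: float = 20.0
    baseline_duration_s: float = 60.0
    total_duration_s: float = 1800.0
    # receptor internalization (trafficking movies)
    k_internalize_per_min: float = 0.2
    surface_fraction_mobile: float = 0.8
    receptor_surface_level: float = 80.0
    receptor_endosome_baseline: float = 20.0
    # biosensor trace model
    amplitude: float = 0.5  # A, dF/F0 units
    tau_rise_min: float = 1.0
    tau_decay_min: float = 8.0
    plateau_fraction: float = 0.6  # p
    fsk_epoch_duration_s: float = 120.0
    fsk_level: float = 1.0  # saturation S, dF/F0 units
    noise_sd: float = 0.02  # per-frame Gaussian sd on biosensor traces
    seed: int = 0

    def validate(self) -> None:
        if not (self.frame_interval_s > 0):
            raise ConfigurationError("frame_interval_s must be > 0")
        for name in ("baseline_duration_s", "total_duration_s", "fsk_epoch_duration_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name, dur in (
            ("baseline_duration_s", self.baseline_duration_s),
            ("total_duration_s", self.total_duration_s),
            ("fsk_epoch_duration_s", self.fsk_epoch_duration_s),
        ):
            if abs(dur / self.frame_interval_s - round(dur / self.frame_interval_s)) > 1e-9:
                raise ConfigurationError(f"{name} must be a multiple of frame_interval_s")
        if not (self.tau_rise_min > 0 and self.tau_decay_min > 0):
            raise ConfigurationError("tau_rise_min and tau_decay_min must be > 0")
        if not (0.0 <= self.plateau_fraction <= 1.0):
            raise ConfigurationError("plateau_fraction must be in [0, 1]")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if not (0.0 <= self.surface_fraction_mobile <= 1.0):
            raise ConfigurationError("surface_fraction_mobile must be in [0, 1]")
        if self.k_internalize_per_min < 0:
            raise ConfigurationError("k_internalize_per_min must be >= 0")
        if self.receptor_endosome_baseline <= 0:
            raise ConfigurationError("receptor_endosome_baseline must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def time_axis_min(self, include_fsk: bool = False) -> np.ndarray:
        """Frame times in minutes, t = 0 at agonist addition."""
        dt = self.frame_interval_s
        n_base = int(round(self.baseline_duration_s / dt))
        n_post = int(round(self.total_duration_s / dt))
        n_fsk = int(round(self.fsk_epoch_duration_s / dt)) if include_fsk else 0
        frames = np.arange(-n_base, n_post + n_fsk + 1)
        return frames * dt / 60.0

    @property
    def agonist_frame(self) -> int:
        return int(round(self.baseline_duration_s / self.frame_interval_s))


@dataclass
class GroundTruth:
    """The simulator's record of what is true in a synthetic dataset."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)
    true_enrichment: dict[str, float] = field(default_factory=dict)
    times_min: np.ndarray | None = None
    internalized_fraction: np.ndarray | None = None  # f(t)
    expected_trace: np.ndarray | None = None  # noiseless normalized trace
    trace_params: dict[str, float] = field(default_factory=dict)
    noiseless: np.ndarray | None = None  # pre-noise pixel data
    params: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry painting


def _grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    return (
        np.arange(ny, dtype=float)[:, None],
        np.arange(nx, dtype=float)[None, :],
    )


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    yy, xx = _grids(shape)
    cy, cx = center
    ry, rx = radii
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = _grids(shape)
    cy, cx = center
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _capsule_mask(shape, p0, p1, width) -> np.ndarray:
    """Pixels within width/2 of the segment p0-p1 (a thick line)."""
    yy, xx = _grids(shape)
    (y0, x0), (y1, x1) = p0, p1
    dy, dx = y1 - y0, x1 - x0
    norm2 = dy * dy + dx * dx
    if norm2 == 0:
        return _disk_mask(shape, p0, width / 2.0)
    s = ((yy - y0) * dy + (xx - x0) * dx) / norm2
    s = np.clip(s, 0.0, 1.0)
    dist2 = (yy - (y0 + s * dy)) ** 2 + (xx - (x0 + s * dx)) ** 2
    return dist2 <= (width / 2.0) ** 2


def _erode_boundary(mask: np.ndarray, width: int) -> np.ndarray:
    """Interior of a mask: pixels farther than ``width`` from the outside."""
    return ndi.binary_erosion(mask, iterations=width, border_value=0)


def _paint_scene(cfg: SceneConfig) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Paint the geometry masks and the pre-noise marker/AC frames."""
    cfg.validate()
    shape = cfg.image_shape
    cy, cx = cfg.center
    ry, rx = cfg.soma_radii
    rng = np.random.default_rng(cfg.seed)

    soma = _ellipse_mask(shape, (cy, cx), (ry, rx))

    processes = np.zeros(shape, dtype=bool)
    # evenly spaced radial processes, avoiding the cilium direction (up)
    angles = np.linspace(0.0, 2.0 * np.pi, cfg.n_processes, endpoint=False) + np.pi / 5.0
    for theta in angles:
        dy, dx = -np.cos(theta), np.sin(theta)
        # start on the soma boundary, run outward
        r_edge = 1.0 / np.sqrt((dy / ry) ** 2 + (dx / rx) ** 2)
        p0 = (cy + dy * (r_edge - 1.0), cx + dx * (r_edge - 1.0))
        p1 = (cy + dy * (r_edge + cfg.process_length_px), cx + dx * (r_edge + cfg.process_length_px))
        processes |= _capsule_mask(shape, p0, p1, cfg.process_width_px)
    processes &= ~soma

    # cilium: thin capsule pointing straight up from the soma apex
    apex = (cy - ry, cx)
    tip = (cy - ry - cfg.cilium_length_px, cx)
    cilium = _capsule_mask(shape, apex, tip, cfg.cilium_width_px) & ~soma

    body = soma | processes
    membrane = body & ~_erode_boundary(body, cfg.membrane_width_px)

    # endosomes: non-overlapping disks strictly inside the soma interior
    rmin, rmax = cfg.endosome_radius_px
    interior_margin = rmax + cfg.membrane_width_px + 2.0
    endosomes = np.zeros(shape, dtype=bool)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    placed = 0
    attempts = 0
    while placed < cfg.n_endosomes:
        attempts += 1
        if attempts > 200 * max(cfg.n_endosomes, 1):
            raise ConfigurationError(
                "n_endosomes: could not place all endosomes inside the soma"
            )
        r = rng.uniform(rmin, rmax)
        ey = cy + rng.uniform(-1, 1) * (ry - interior_margin)
        ex = cx + rng.uniform(-1, 1) * (rx - interior_margin)
        if ((ey - cy) / (ry - interior_margin)) ** 2 + ((ex - cx) / (rx - interior_margin)) ** 2 > 1:
            continue
        # keep boundary gaps > 2 px so 1-px closing never bridges endosomes
        if any((ey - oy) ** 2 + (ex - ox) ** 2 < (r + orr + 6.0) ** 2
               for (oy, ox), orr in zip(centers, radii)):
            continue
        endosomes |= _disk_mask(shape, (ey, ex), r)
        centers.append((ey, ex))
        radii.append(r)
        placed += 1

    cell = body | cilium

    # AC channel: replacement painting, priority endosome > cilium > membrane
    ac = np.full(shape, cfg.background, dtype=float)
    ac[cell] = cfg.background + cfg.base_cell
    ac[membrane] = cfg.background + cfg.base_cell * cfg.plasma_membrane_factor
    ac[cilium] = cfg.background + cfg.base_cell * cfg.cilium_factor
    ac[endosomes] = cfg.background + cfg.base_cell * cfg.endosome_factor

    marker = np.full(shape, cfg.background, dtype=float)
    marker[cell] = cfg.background + cfg.marker_base
    if cfg.marker_target in ("cilium", "both"):
        marker[cilium] = cfg.background + cfg.marker_level
    if cfg.marker_target in ("endosomes", "both"):
        marker[endosomes] = cfg.background + cfg.marker_level

    masks = {
        "cell": cell,
        "soma": soma,
        "processes": processes,
        "membrane": membrane,
        "cilium": cilium,
        "endosomes": endosomes,
    }
    masks["endosome_centers"] = np.array(centers, dtype=float)
    masks["endosome_radii"] = np.array(radii, dtype=float)
    return masks, marker, ac


def _apply_noise(frames: np.ndarray, cfg_poisson: bool, gaussian_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    out = np.asarray(frames, dtype=float)
    if cfg_poisson:
        out = rng.poisson(out).astype(float)
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _measure_enrichment(image: np.ndarray, comp: np.ndarray, cell: np.ndarray,
                        background: float) -> dict[str, float]:
    vals = np.clip(image - background, 0.0, None)
    if not comp.any():
        return {"mean-ratio": 0.0, "integrated-ratio": 0.0}
    return {
        "mean-ratio": float(vals[comp].mean() / vals[cell].mean()),
        "integrated-ratio": float(vals[comp].sum() / vals[cell].sum()),
    }


def simulate_static_scene(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a fixed-cell two-channel scene with known enrichment.

    Returns a ``(1, n_z, 2, y, x)`` stack (channel 0 = compartment
    marker, channel 1 = AC) and the ground truth: exact compartment
    masks and the enrichment index of the pre-noise AC channel under
    both conventions. With ``n_z > 1`` the cilium is confined to the
    upper z-planes, as for a cilium sitting on top of the soma.
    """
    masks, marker, ac = _paint_scene(config)
    ny, nx = config.image_shape
    noiseless = np.zeros((1, config.n_z, 2, ny, nx), dtype=float)
    cilium_free_ac = ac.copy()
    cilium_free_marker = marker.copy()
    cil = masks["cilium"]
    cilium_free_ac[cil] = config.background
    cilium_free_marker[cil] = config.background
    for z in range(config.n_z):
        in_upper_half = z >= config.n_z // 2
        noiseless[0, z, MARKER_CHANNEL] = marker if in_upper_half else cilium_free_marker
        noiseless[0, z, AC_CHANNEL] = ac if in_upper_half else cilium_free_ac

    rng = np.random.default_rng(config.seed + 1)
    pixels = _apply_noise(noiseless, config.poisson_on, config.gaussian_sd, rng)

    truth = GroundTruth(
        masks=masks,
        noiseless=noiseless,
        params=asdict(config),
    )
    for comp in ("cilium", "endosomes"):
        measured = _measure_enrichment(ac, masks[comp], masks["cell"], config.background)
        for convention, value in measured.items():
            truth.true_enrichment[f"{comp}:{convention}"] = value

    cal = Calibration(pixel_size_um=config.pixel_size_um)
    return ImageStack(pixels, cal), truth


def internalized_fraction(times_min: np.ndarray, k_per_min: float,
                          mobile_fraction: float) -> np.ndarray:
    """First-order internalized fraction f(t); zero before agonist."""
    t = np.asarray(times_min, dtype=float)
    f = mobile_fraction * (1.0 - np.exp(-k_per_min * np.clip(t, 0.0, None)))
    return np.where(t < 0.0, 0.0, f)


def simulate_trafficking_movie(
    scene: SceneConfig, kin: KineticConfig
) -> tuple[ImageStack, GroundTruth]:
    """Simulate agonist-induced receptor redistribution to endosomes.

    Channel 0 carries the stationary endosome marker; channel 1 carries
    the receptor, whose surface pool (plasma membrane) decays and whose
    endosomal pool rises so that total receptor fluorescence is conserved
    frame to frame (pre-noise). The endosomal receptor starts at a small
    constitutive baseline so baseline normalization is well defined.
    """
    kin.validate()
    masks, marker, _ = _paint_scene(scene)
    times = kin.time_axis_min(include_fsk=False)
    f_t = internalized_fraction(times, kin.k_internalize_per_min, kin.surface_fraction_mobile)

    surface = masks["membrane"]
    endo = masks["endosomes"]
    n_surface = int(surface.sum())
    n_endo = int(endo.sum())
    if n_endo == 0:
        raise ConfigurationError("n_endosomes must be > 0 for a trafficking movie")

    gain_per_px = kin.receptor_surface_level * n_surface / n_endo
    ny, nx = scene.image_shape
    noiseless = np.zeros((times.size, 1, 2, ny, nx), dtype=float)
    for i, f in enumerate(f_t):
        rec = np.full((ny, nx), scene.background, dtype=float)
        rec[surface] += kin.receptor_surface_level * (1.0 - f)
        rec[endo] += kin.receptor_endosome_baseline + gain_per_px * f
        noiseless[i, 0, MARKER_CHANNEL] = marker
        noiseless[i, 0, AC_CHANNEL] = rec

    rng = np.random.default_rng(kin.seed + 1)
    pixels = _apply_noise(noiseless, scene.poisson_on, scene.gaussian_sd, rng)

    expected = 1.0 + gain_per_px * f_t / kin.receptor_endosome_baseline
    truth = GroundTruth(
        masks=masks,
        noiseless=noiseless,
        times_min=times,
        internalized_fraction=f_t,
        expected_trace=expected,
        params={"scene": asdict(scene), "kinetics": asdict(kin)},
    )
    cal = Calibration(
        pixel_size_um=scene.pixel_size_um,
        frame_interval_s=kin.frame_interval_s,
        agonist_frame=kin.agonist_frame,
    )
    return ImageStack(pixels, cal), truth


def biosensor_response(times_min: np.ndarray, amplitude: float, tau_rise_min: float,
                       tau_decay_min: float, plateau_fraction: float) -> np.ndarray:
    """Noiseless biosensor response model r(t) in dF/F0 units.

    A saturating rise times a partial exponential decay to a sustained
    plateau: ``A (1 - exp(-t/tau_r)) (p + (1 - p) exp(-t/tau_d))`` for
    t >= 0, exactly zero before agonist.
    """
    t = np.asarray(times_min, dtype=float)
    tc = np.clip(t, 0.0, None)
    rise = 1.0 - np.exp(-tc / tau_rise_min)
    decay = plateau_fraction + (1.0 - plateau_fraction) * np.exp(-tc / tau_decay_min)
    return np.where(t < 0.0, 0.0, amplitude * rise * decay)


def matched_peak_variant(kin: KineticConfig, plateau_ratio: float = 0.5,
                         seed: int | None = None) -> KineticConfig:
    """A second condition with the same peak but a reduced plateau.

    Solves for ``(amplitude, plateau_fraction)`` such that the noiseless
    response sampled on ``kin``'s time grid has exactly the same maximum
    as ``kin``'s and a [20, 30]-min plateau equal to ``plateau_ratio``
    times ``kin``'s. This is the canonical construction for testing that
    the late-phase statistics, and not the early ones, discriminate two
    responses that differ only in their sustained component.
    """
    from scipy.optimize import brentq

    if not (0.0 < plateau_ratio < 1.0):
        raise ConfigurationError("plateau_ratio must be in (0, 1)")
    kin.validate()
    times = kin.time_axis_min()
    in_plateau = (times >= 20.0) & (times <= 30.0)

    def response(amplitude: float, p: float) -> np.ndarray:
        return biosensor_response(times, amplitude, kin.tau_rise_min,
                                  kin.tau_decay_min, p)

    reference = response(kin.amplitude, kin.plateau_fraction)
    ref_peak = reference.max()
    ref_plateau = reference[in_plateau].mean()

    def plateau_ratio_at(p: float) -> float:
        unit = response(1.0, p)
        scaled = unit * (ref_peak / unit.max())
        return scaled[in_plateau].mean() / ref_plateau

    p_b = brentq(lambda p: plateau_ratio_at(p) - plateau_ratio, 1e-9,
                 kin.plateau_fraction)
    unit = response(1.0, p_b)
    amp_b = ref_peak / unit.max()
    return dataclass_replace(
        kin, amplitude=float(amp_b), plateau_fraction=float(p_b),
        seed=kin.seed if seed is None else seed,
    )


def simulate_biosensor_trace(kin: KineticConfig) -> tuple[TimeSeries, GroundTruth]:
    """Simulate one biosensor (cAMP/PKA) time course in dF/F0 units.

    The dopamine response follows :func:`biosensor_response`; a terminal
    Fsk/IBMX epoch at the saturation level ``fsk_level`` is appended.
    Per-frame Gaussian noise of sd ``noise_sd`` is added when nonzero.
    """
    kin.validate()
    times = kin.time_axis_min(include_fsk=True)
    n_fsk = int(round(kin.fsk_epoch_duration_s / kin.frame_interval_s))
    r = biosensor_response(times, kin.amplitude, kin.tau_rise_min,
                           kin.tau_decay_min, kin.plateau_fraction)
    if n_fsk > 0:
        r = r.copy()
        r[-n_fsk:] = kin.fsk_level
        fsk_frames: tuple[int, int] | None = (times.size - n_fsk, times.size)
    else:
        fsk_frames = None

    rng = np.random.default_rng(kin.seed + 1)
    values = r + rng.normal(0.0, kin.noise_sd, size=r.shape) if kin.noise_sd > 0 else r.copy()

    trace = TimeSeries(times, values, normalization="dF/F0", fsk_frames=fsk_frames)
    truth = GroundTruth(
        times_min=times,
        expected_trace=r,
        trace_params={
            "amplitude": kin.amplitude,
            "tau_rise_min": kin.tau_rise_min,
            "tau_decay_min": kin.tau_decay_min,
            "plateau_fraction": kin.plateau_fraction,
            "fsk_level": kin.fsk_level,
        },
        params=asdict(kin),
    )
    return trace, truth
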