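# Methods

This note documents the models, conventions and default parameters
behind `acquant`, and what validation on synthetic data does and does
not establish about real images.

## Conventions fixed across the package

* **Axes.** All stacks are `(t, z, c, y, x)` with singleton axes kept;
  indices are 0-based; y increases downward. The center of pixel
  `(i, j)` is the integer point `(i, j)`; the pixel occupies the
  half-open box `[i-0.5, i+0.5) × [j-0.5, j+0.5)`.
* **Time.** Seconds in acquisition metadata, minutes on every reported
  axis, t = 0 at agonist addition. Default timing is 20 s frames, a
  1 min pre-agonist baseline and a 30 min follow-up, with a terminal
  2 min forskolin/IBMX epoch for biosensor movies.
* **Thresholding.** Strict `>` (upper thresholding, the ImageJ
  convention): a pixel exactly at the threshold is background. Manual
  thresholds are taken verbatim from configuration; the reproducible
  default is Otsu's criterion. Our Otsu is computed exactly over the
  unique pixel values when there are ≤ 256 of them (256-bin histogram
  otherwise), and the returned threshold is placed at the top of the
  background class so that the strict-`>` mask reproduces the Otsu
  split even on few-valued images. (Bin-center thresholds, as returned
  by common implementations, can fall *below* background values that
  share the split bin and silently invert the classes on synthetic
  two-level data.)
* **Connectivity.** 8-connected components in 2-D by default
  (configurable to 4), matching particle-analysis practice.
* **Morphological smoothing.** The 1-px dilate / 1-px erode pair is a
  binary closing. The default structuring element is the 3×3 square —
  the element ImageJ's binary dilate/erode uses and the one under which
  two foreground pixels separated by a 1-px gap are bridged; the 3×3
  cross is available by flag. The image border is treated as background
  beyond the frame (computed on a padded canvas), so closing is
  mathematically extensive: it never removes existing foreground, and
  it is idempotent.
* **Distances.** Euclidean distance transforms in micrometers
  (`pixel_size_um` sampling); colocalization at ≤ 1 μm is inclusive, so
  a spot at exactly the cutoff colocalizes.

## Enrichment indices

Background-subtracted pixel values are clipped at 0 before any ratio
(negative values after subtraction are measurement noise and would
otherwise produce sign pathologies). The compartment mask is
auto-intersected with the cell mask and the clipping logged. Two
conventions are computed and always recorded with the result:

* **mean-ratio** (default): mean compartment intensity over mean
  whole-cell intensity. This is a concentration enrichment — invariant
  to compartment area for a uniformly painted compartment, invariant to
  overall gain and to a correctly estimated uniform background offset,
  and exactly 1 on a uniform cell.
* **integrated-ratio**: summed compartment over summed cell intensity —
  the fraction of total fluorescence in the compartment; scales
  linearly with compartment area fraction.

The wording "compartment fluorescence divided by total cell
fluorescence" is ambiguous between the two; mean-ratio is the default
because a concentration measure is the quantity "enrichment" names, and
neither convention is claimed to be canonical.

Background defaults to the mean intensity outside the cell ROI
(optionally restricted to a user background ROI); the 5th percentile of
the whole frame is available as an alternative for crowded fields.

## Puncta positivity

Threshold inside the cell ROI → 8-connected components → drop
components < 3 px → count. A cell is endosome-positive iff it has
≥ 10 puncta (inclusive; the boundary case of exactly 10 is positive).
Population positivity is `100 · n_positive / n_total`.

## The "Puncti" trafficking pipeline

Per movie: the cell ROI is refined by thresholding the maximal temporal
projection of the receptor channel (so every pixel the receptor ever
visits is inside) and smoothing with the same 1-px closing used for
object masks. The endosome mask is rebuilt per frame by default from
the marker channel (threshold chosen once on the temporal maximum
projection, as a single manual choice would be); a projection-fixed
mask is available, and the two agree to ~1e-6 relative on stationary
markers. Receptor signal is the mean intensity within the mask
(integrated intensity by flag), background-subtracted per frame, and
the whole trace divided by its pre-agonist mean (F/F0). Frames with an
empty mask are recorded as NaN, never as zero, and NaNs are linearly
interpolated only inside AUC integration — stored traces are never
interpolated.

## Biosensor summaries

* ΔF/F0 = (F − F0)/F0 with F0 the pre-agonist mean; traces from
  non-targeted sensors are additionally divided by their mean over the
  Fsk/IBMX epoch (fraction-of-maximum scale).
* AUC by the trapezoidal rule; at 20 s sampling the rule error is
  < 0.3% for exponentials with τ ≥ 2 min. Phase boundaries are hit
  exactly by linear interpolation, and the boundary at 5 min belongs to
  the early phase: phases are (0, 5] and (5, 30], so early + late
  equals total exactly.
* Peak = maximum sampled value in (0, 30] (pre-agonist frames
  excluded; ties resolve to the earliest time). Plateau = mean of
  samples in the closed window [20, 30] min.
* Cross-condition normalization divides each statistic by its mean in a
  designated reference condition, whose own mean maps to exactly 1.

## Synthetic data generator

The generator produces the statistical structure the measurements
assume, not photorealistic microscopy.

**Static scenes.** An elliptical soma (default radii 5.5 × 6.5 μm at
0.1 μm/px), four radial processes, a 4 μm × 0.4 μm cilium capsule
abutting the soma apex, and 12 non-overlapping endosome disks (radius
0.3–0.5 μm) strictly inside the soma. The AC channel paints
`base_cell` (50 photons/px) inside the cell and replaces it with
`base_cell × factor` inside each compartment (membrane ring 1.5×,
cilium 5×, endosomes 4× by default) over a 10 photons/px background;
the marker channel highlights endosomes (EEA1-like), the cilium, or
both. Compartments are exact pixel sets (pixel-center containment)
rather than anti-aliased shapes: this keeps the stored ground-truth
masks identical to what a perfect segmentation recovers, makes the true
enrichment index an exact statistic of the pre-noise image, and lets
threshold-recovery tests assert mask equality rather than approximate
overlap. Endosome placement keeps boundary gaps > 2 px so the 1-px
closing never bridges two endosomes.

**Noise.** Poisson on (signal + background), then additive Gaussian
read noise (sd 2 photons), clipped at 0 — the standard shot +
read-noise camera model. At the default intensities the cell-to-noise
ratio exceeds 5. Identical (config, seed) gives bit-identical output.

**Trafficking movies.** The marker channel is stationary; the receptor
starts on the plasma-membrane ring at 80 photons/px and redistributes
to the endosome set with first-order kinetics,
`f(t) = m (1 − e^{−kt})` for t ≥ 0 (defaults k = 0.2/min, mobile
fraction m = 0.8 — free parameters of the simulation, not biological
claims, since no quantitative internalization rate is asserted).
Total receptor fluorescence is conserved frame to frame pre-noise:
every photon leaving the surface appears in an endosome. Endosomes
carry a constitutive receptor baseline (20 photons/px) so baseline
normalization is well defined.

**Biosensor traces.** The response model is
`r(t) = A (1 − e^{−t/τ_r}) (p + (1 − p) e^{−t/τ_d})` for t ≥ 0 — a
saturating rise times a partial exponential decay to the sustained
fraction `p`. This functional form is a modeling choice (the data it
emulates are described only qualitatively: fast rise within ~2 min,
partial decay over several minutes, sustained plateau); defaults
A = 0.5 ΔF/F0, τ_r = 1 min, τ_d = 8 min, p = 0.6 put the peak at
≈ 3.3 min. A terminal Fsk/IBMX epoch at saturation level S = 1.0 is
appended, and per-frame Gaussian noise (sd 0.02 ΔF/F0) added.
`matched_peak_variant` constructs a second condition with exactly the
same grid peak and a chosen plateau ratio by solving for (A, p) — the
canonical fixture for showing that plateau and late-phase AUC, but not
early-phase AUC, discriminate conditions that differ only in sustained
signaling.

## Statistics

The unit of replication is the independent culture/dish: cells are
averaged within replicate first, and mean ± s.e.m. is computed over
replicate means (sample sd, ddof = 1; a single replicate reports
s.e.m. as missing). Cell-level pooling is available only behind an
explicit flag. The two-sample test is classical Student's t with pooled
variance (df = n_a + n_b − 2) or the paired t on differences,
two-tailed; Welch's correction is deliberately not the default because
the replicate-level design targets the classical test. Zero variance
with equal means returns t = 0, p = 1 by convention (logged) rather
than failing.

## What synthetic validation shows — and does not

Passing recovery tests establishes that the measurement code computes
what it claims on images satisfying its assumptions: uniform
background, stationary cells, compartments brighter than their
surroundings, shot-noise-limited cameras. The generator deliberately
omits point-spread-function blur, photobleaching, cell motion, focal
drift, autofluorescence gradients and segmentation ambiguity from
touching organelles; accuracy on real microscopy therefore also depends
on acquisition quality and threshold choices that no synthetic test can
certify. Reported problem sizes (256² px scenes, 94-frame movies,
9 traces × 100 repetitions for power estimates) were chosen so the full
validation suite characterizes every stage in seconds while keeping all
noise regimes representative.

## Known limitations

* No watershed splitting of touching puncta and no 3-D (z-resolved)
  components — quantification operates on 2-D projections, with an
  optional anisotropic 3-D mode only in the colocalization distance.
* Spot detection reports one local maximum per flat-topped object only
  when the minimum separation exceeds the object extent; it is intended
  for peaked (diffraction-shaped) puncta.
* The exact smoothing the original cell-ROI refinement used is not
  specified anywhere; this package applies the same 1-px closing as for
  object masks and flags it as an assumption.
* ImageJ `.roi` files are not parsed; ROIs enter as label TIFFs or the
  documented polygon JSON.
* No exclusion rule for saturating or bleaching cells is applied by
  default.
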