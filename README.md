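# acquant

Quantification of adenylyl-cyclase (AC) compartment localization and
cAMP/PKA signaling kinetics in fluorescence microscopy of neurons.

Adenylyl cyclase isoforms are differentially sorted in striatal medium
spiny neurons — some concentrate in the primary cilium, one (AC9) in
endosomes — and where cAMP is produced shapes where PKA acts
downstream. Studies of this kind quantify fixed- and live-cell imaging
with a small set of bespoke measurements. `acquant` implements that
measurement suite as a tested, reusable library and command-line tool,
together with a synthetic-microscopy generator with exact ground truth,
so every stage can be validated without any external image data.

## What it computes

**Compartment enrichment index.** For a cell ROI $C$, a compartment
mask $K \subseteq C$ (a manually drawn cilium ROI, or endosomes defined
by thresholding a marker channel such as EEA1/Vps35), and a
background-subtracted AC-channel image $I$:

$$E_{\text{mean}} = \frac{\langle I \rangle_K}{\langle I \rangle_C},
\qquad
E_{\text{int}} = \frac{\sum_K I}{\sum_C I}.$$

The mean-ratio convention (default) measures concentration enrichment —
a uniformly fluorescent cell gives exactly 1 regardless of compartment
size; the integrated-ratio convention measures the fraction of total
cell fluorescence in the compartment. Every result records its
convention.

**Puncta classification.** Internal puncta are pixels above an
intensity threshold inside the cell ROI, labeled as 8-connected
components, with components smaller than 3 px excluded. A cell with
≥ 10 puncta is classified endosome-positive, and populations are
summarized as the percentage of positive cells.

**Receptor trafficking kinetics ("Puncti" pipeline).** For a
two-channel movie (endosome marker + receptor): the cell ROI is refined
by thresholding a maximal temporal projection and smoothing; per frame,
the marker is thresholded inside the ROI, sub-3-px regions removed, and
the mask smoothed by a 1-px dilation followed by a 1-px erosion; mean
receptor fluorescence inside the mask is background-subtracted and the
trace is normalized to the pre-agonist baseline (F/F0).

**Biosensor time-course summaries.** Per-cell ΔF/F0 traces (optionally
divided by their mean during a terminal forskolin/IBMX saturation
epoch) are reduced to: early AUC over (0, 5] min, late AUC over
(5, 30] min (trapezoidal, exact phase boundaries), peak = max over
(0, 30] min, plateau = mean over [20, 30] min, optionally normalized to
a reference condition's means.

**Distance colocalization.** A spot colocalizes with a reference
compartment iff its center lies within 1 μm (inclusive) of the nearest
compartment pixel, via a Euclidean distance transform in physical
units.

**Statistics.** Cells are averaged within biological replicate first;
conditions are reported as mean ± s.e.m. over replicate means and
compared with two-tailed Student's t-tests (pooled variance; paired
variant available).

## Worked example

Simulate an AC9-like neuron (endosome enrichment factor 4, Poisson +
read noise), then measure it blind to the ground truth:

```python
import acquant as aq
from acquant.segmentation import auto_threshold, max_project_z

scene = aq.SceneConfig(endosome_factor=4.0, cilium_factor=1.0, seed=1)
stack, truth = aq.simulate_static_scene(scene)

ac = max_project_z(stack, channel=1)        # AC channel, z-max projection
marker = max_project_z(stack, channel=0)    # endosome marker (EEA1-like)
cell = truth.masks["cell"]                  # stands in for the drawn ROI

marker_thr = auto_threshold(marker, restrict_to=cell)
endosomes = aq.endosome_mask_from_marker(marker, cell, marker_thr)
background = aq.estimate_background(ac, cell)
result = aq.enrichment_index(ac, endosomes, cell, background=background)

cls = aq.count_internal_puncta(ac, cell, auto_threshold(ac, restrict_to=cell))
```

This prints:

```
marker threshold (Otsu): 42.3
background: 10.01 photons/px
endosome enrichment index (mean-ratio): 3.375
true (painted) index: 3.375
internal puncta: 12 -> endosome-positive: True
```

The measured index equals the painted ground truth to three decimals at
the default noise level, and the 12 painted endosomes are all counted,
classifying the cell as endosome-positive (≥ 10 puncta). A trafficking
movie closes the loop on the live-cell side:

```python
kin = aq.KineticConfig(k_internalize_per_min=0.2, surface_fraction_mobile=0.8, seed=1)
movie, movie_truth = aq.simulate_trafficking_movie(aq.SceneConfig(seed=1), kin)
trace = aq.puncti_accumulation_trace(movie)
```

At t = 10 min the recovered endosomal receptor signal is
`F/F0 = 8.28` against a programmed value of 8.19 — the first-order
accumulation curve $f(t) = 0.8\,(1 - e^{-0.2 t})$ read back through the
full segmentation pipeline.

## Command line

Every stage is exposed as a subcommand writing CSV/JSON outputs plus a
`manifest.json` recording the package version, seed, and every
threshold and convention used:

```bash
acquant simulate --what scene --seed 1 --out-dir out/
acquant enrich out/00_simulate_scene.tif --out-dir out/
acquant puncta out/00_simulate_scene.tif --out-dir out/
acquant traffick movie.tif --out-dir out/
acquant biosensor traces.csv --reference-condition AC9 --out-dir out/
acquant coloc stack.tif --max-distance-um 1.0 --out-dir out/
acquant report values.csv --out-dir out/
```

ROIs are accepted as label-image TIFFs or as polygon JSON
(`{"rois": [{"id": "cell1", "kind": "polygon", "vertices": [[y, x], ...]}]}`,
vertices in pixel coordinates, even-odd fill, pixel-center containment).

## Documentation

See `docs/methods.md` for the models behind the synthetic generator,
the default parameters and their rationale, numerical conventions
(threshold strictness, phase boundaries, structuring elements), and
known limitations.
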