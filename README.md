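# pollengerm

Quantitative analysis of pollen germination time-lapse microscopy.

Germinating *Arabidopsis* pollen is a compact model for how a cell breaks
symmetry and establishes polar tip growth: the vegetative cell of the grain
first inflates a roundish bulge at the future germination site, passes a
transition phase in which secretory vesicles pile up at the bulge apex, and
then switches to rapid tip growth of the pollen tube (PT), with the male
germ unit (the two sperm cells plus the vegetative nucleus, MGU) transported
into the tube only after rapid growth is established. `pollengerm` is a
library for people who quantify such movies: it implements the measurement
chain (projection, pooled-histogram thresholding, grain subtraction, shape
descriptors), the growth-kinetics and polarization statistics, and — because
raw microscope data of this kind is rarely shareable — a ground-truthed
synthetic renderer so every detector can be validated end to end.

## What it computes

* **Geometric growth models** (`growth_models`). Two kinematic geometries of
  tube emergence: the *protrusion* model, a constant-width dome-tipped
  cylinder elongating linearly, and the *bulging* model, a circle anchored
  at the germination site that inflates isodiametrically for a fixed number
  of frames before switching to tip growth. Both are held as exact vector
  polygons; `match_net_area` equalizes their net area increase, and
  `classify_trajectory` matches an observed roundness course against both
  templates. The discriminating observables are the *roundness*
  `4·A/(π·major_axis²)` (major axis from the moments-equivalent ellipse) and
  the junction width at the germination site — constant under protrusion,
  widening under bulging.
* **Synthetic microscopy** (`synthetic_microscopy`, `cohorts`). Multi-channel
  T×Z×Y×X stacks (11 optical slices, 3-min frames) with defocus blur and
  confocal-style falloff, Poisson–Gaussian camera noise, and scheduled marker
  behavior: cytoplasmic fill, transient vesicle-marker peaks at the cortex and
  an inverted-cone tip accumulation, a cortical F-actin profile polarized
  opposite the germination site, and a sperm-membrane extension whose tip
  leaves the grain at the scheduled MGU translocation frame. Every rendered
  feature carries a ground-truth record.
* **Segmentation and measurement** (`segmentation`). Max/sum z-projections,
  per-tube stack-histogram thresholds (brightest 70% of above-background
  pixels for shape, 0.5% for intensity peaks), binarization with grain
  subtraction, tube-component extraction, and `RegionMeasurement` descriptors
  (area, fitted-ellipse major axis, roundness, junction width, medial-axis
  tube length).
* **Growth kinetics** (`kinetics`). Germination-aligned tracks (t = 0 at the
  last frame before emergence), QC filtering (≥ 1 h observed, unobstructed),
  the Friedman k = 2 comparison of mean frame-wise area increase over the
  first versus last 10 frames, the through-origin area→length conversion
  factor (≈ 1/tube-width, ~0.18 µm⁻¹ for 5.5-µm tubes), phase annotation
  (bulging / transition / rapid / translocation), and deceleration-event
  detection.
* **Polarization events** (`polarization`). Variable-ROI vesicle-peak series
  (mean gray × ROI size, normalized per tube), peak detection with site
  concordance (≤ 30° from the germination angle), population frequency
  tables, cortical actin polarity profiles (36 angular bins, resultant-length
  index), abnormal-pattern classification (arrest / second tube / branching),
  and MGU translocation timing via the permanently-outside rule.

A thin CLI (`pollengerm simulate / analyze / report`) orchestrates the same
functions over directories of OME-TIFF stacks; `examples/` holds one short
narrative script per capability.

## Worked example

`python examples/03_cohort_kinetics.py` simulates a 12-tube cohort whose
mean cumulative area is calibrated to reach 400.2 µm² one hour after
germination, runs every movie through the full image pipeline, and prints:

```
tubes analyzed: 12
overall growth rate: 385.3 um^2/h (mean cumulative area at 60 min; calibration target 400.2)
first-10 vs last-10 frame increase: 9.5 vs 28.9 um^2/frame
Friedman Q = 12.0 (df=1, n=12), p = 5.32e-04
p << 0.001: early growth is a genuine lag phase, not noise
area->length conversion factor: 0.173 um^-1 (1/tube_width in the cylindrical limit; 5.5 um wide tubes give ~0.18)
```

The growth rate is the pipeline's estimate of the calibrated 400.2 µm²/h
(within sampling error of 12 jittered tubes); the first-vs-last comparison
shows the slow bulging/transition phase followed by rapid tip growth, with
the unanimous ranking giving Friedman Q = n; and the conversion factor lets
PT area (µm²) be read as PT length (µm).

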