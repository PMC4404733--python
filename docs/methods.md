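# Methods

This note documents the models, conventions, and numerical choices behind
`pollengerm`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Geometric models of tube emergence

Both germination models are *kinematic*: they prescribe shapes over time and
make no claim about turgor or cell-wall mechanics.

**Protrusion.** A rectangle of width *w* (default 5.5 µm) and length
*f*·*e* (frame index × elongation per frame) capped by a semicircular dome
of diameter *w*, emerging from the germination site along the outward radial
direction. Frame 0 is pre-emergence (empty region). The junction between
grain and tube keeps a constant width.

**Bulging.** A circle whose proximal ("lowermost") point stays anchored at
the germination site grows by a constant radius increment per frame for
`bulge_frames` frames (default 20). Afterwards the bulge outline is frozen
and a dome-tipped cylinder of width *w* elongates from its distal point.
Because the inflating circle is tangent to the convex grain boundary, the
measured junction width (the chord of the region across a thin band just
outside the boundary) widens as the bulge inflates — the signature that
separates the models in real data.

Geometry is exact vector polygons (shapely): the grain ellipse is a 720-gon
and circular arcs use ≥ 180 vertices, so polygon areas serve as ground truth
for rasterized measurements (agreement within 2% at 0.1 µm/px for regions
above ~100 px; below that, pixel quantization dominates). `match_net_area`
adjusts the protrusion elongation rate so both models end at the same net
area (≤ 1% difference; the bulging schedule is the reference). The area
*courses* of the matched models still differ mid-way — a constant diameter
increment makes bulge area quadratic in time while protrusion area is
linear — and only converge during late elongation; the package treats the
identical *net* increase as the matching contract.

**Trajectory classification.** The observed roundness course is compared to
both model templates (measured from the default-parameter models with the
same rasterized measurement used for images). The time axis is normalized to
the observed duration and additionally stretched over a factor grid
(geometric, 1/3…3, 13 points) because an observation window need not span
the same fraction of the course as the template; the amplitude is fit by
least squares. The label is the template with the smaller mean-squared
residual; near-equal residuals (within 5%) or a flat series yield an
explicit tie. On 100 seeded simulations with roundness noise σ = 0.03 and
random window lengths the generating model is recovered in ≥ 95 cases.

## Synthetic microscopy

The renderer emulates a spinning-disc acquisition: 11 optical slices per
time point (0.8 µm spacing), 3-min frame interval, 16-bit counts.

* **Optics.** Each slice is the focal-plane image blurred with a Gaussian
  whose σ grows linearly with defocus distance (0.6 px/µm) and attenuated
  with a Gaussian falloff (scale 2.5 µm) that stands in for confocal
  optical sectioning. The attenuation matters quantitatively: without it,
  out-of-focus halo fills the concave grain/tube junction in the maximum
  projection and inflates small-tube areas by over 10%; with it, the
  measured areas are unbiased against vector ground truth (< 0.5% cohort
  bias). A full PSF model is deliberately out of scope.
* **Noise.** Poisson shot noise on the expected counts followed by additive
  Gaussian read noise (σ = 8 counts), the standard camera model. All
  randomness flows from one `numpy` generator seeded per render, so a fixed
  seed gives bit-identical stacks.
* **Channels.** Cytoplasm fills grain and tube uniformly (baseline
  1000 counts). The vesicle channel carries a dim cytoplasmic fill (15% of
  its 400-count baseline), transient Gaussian blobs (σ = 1.2 µm, default
  5× baseline, triangular 3-frame time profile) at scheduled cortex
  positions, and an inverted-cone tip accumulation (depth 3 µm) ramping up
  over 4 frames from the transition. Actin is a cortical band (1.2 µm) with
  a von-Mises angular profile (κ = 3) peaked opposite the germination site,
  plus three longitudinal cables after the scheduled bundling onset. The
  sperm-membrane channel is a thin bright curve whose tip sits 2 µm inside
  the grain until the scheduled translocation frame and then advances into
  the tube, staying outside the grain. Intensity scales are free parameters
  of the generator — no channel statistics are available to calibrate
  against — chosen so that signal-to-background ratios are realistic for
  the instrument class.
* **Frame geometry.** Default single renders use 512×512 px at 0.33 µm/px.
  Cohort simulations use 288×128 px at 0.5 µm/px, which keeps a grain plus
  an hour of rapid growth in frame at ~1 s per tube render; grain centers
  are placed off the half-pixel grid because an axis-aligned tube edge lying
  exactly on a row of pixel centers is a degenerate rasterization case.

**What the generator does not emulate:** diffraction and spectral
bleed-through, focus drift, photobleaching, cytoplasmic streaming texture,
grain movement, or debris. Passing recovery tests on these renders therefore
demonstrates that the measurement chain is correct and unbiased under the
stated image-formation model, not that it is robust to every artifact of
real microscopy.

## Cohort schedules and calibration

Each synthetic tube germinates after 2–3 pre-emergence frames and follows a
slow-bulge/fast-rapid schedule: bulge area rises linearly (radius ∝ √t) to
`area_15min` (default 16.7 µm²) over 5 frames, the radius then inflates to
*w*/2 over 3 frames, and a round-capped capsule of width *w* elongates at a
constant rate thereafter, making the area course continuous through the
transition. Published cohort means for the slow-phase area, the 45–60 min
increase, and the hourly cumulative rate are not mutually consistent under
any single such schedule, so each cohort is calibrated to exactly one
target: the rapid rate is solved in closed form from either the cumulative
area at 60 min (default 400.2 µm²), the 45–60 min window increase
(57.0 µm²), or given directly. Tube-to-tube variability is a multiplicative
factor (normal, σ = 0.15, clipped to [0.6, 1.4]) applied independently to
the early area and the rapid rate. Marker events (actin bundling onset, MGU
translocation) are scheduled at the frame whose ground-truth area is closest
to the stated target (300 and 350 µm² respectively).

## Measurement chain

* **Projection.** GFP-type channels are maximum-intensity projected; the
  brightfield channel is sum-projected.
* **Background floor.** The boundary between camera background and
  fluorescence is an Otsu split computed on log1p-transformed intensities.
  The log domain is essential: fluorescence histograms span orders of
  magnitude, and a linear Otsu lands between "everything" and a small very
  bright class (an injected peak or the tip cone) instead of between
  background and the dim cytoplasmic baseline. Log-Otsu is equivariant
  under intensity rescaling, so histogram-relative conventions survive
  affine changes of gain.
* **Stack thresholds.** All frames of one tube are pooled; the shape
  threshold selects the brightest 70% and the peak threshold the brightest
  0.5% of above-floor pixels (smallest gray value g with
  P(I > g | signal) ≤ fraction). These serve the vesicle-channel
  quantification. The cytoplasm channel, whose task is accurate area
  measurement, is binarized at a plain pooled Otsu threshold — for a
  uniformly filled cell this sits at the 50% isophote of the blurred edge,
  which is the unbiased boundary estimate.
* **Grain subtraction.** The grain mask is the largest connected component
  of the first (pre-emergence) frame's binary image, frozen thereafter; no
  drift correction. The tube is the largest grain-subtracted component
  touching the 1-px-dilated grain boundary; a 3×3 morphological opening
  removes single-pixel noise chains (replacing manual curation). The
  opening is part of the noisy-image pipeline; on noiseless renders it is
  unnecessary and would shave the jagged rim of very small regions.
* **Descriptors.** Area = pixel count × pixel-size²; the major axis comes
  from the moments-equivalent ellipse (ImageJ "fit ellipse" convention, not
  Feret), so roundness = 4A/(π·major²) is bounded by 1 with equality for a
  disc (values are clipped at 1 against discretization overshoot). Junction
  width is the maximal extent of tube pixels within the 1-px band outside
  the grain. Tube length is the geodesic length of the longest path through
  the morphological skeleton (Dijkstra double sweep, √2 diagonal weights);
  it is computed only on request because it dominates per-frame cost.
* **Coordinates.** Pixel-centered, 0-based, row-major; all outputs in µm/µm².

## Kinetics

Tracks are germination-aligned: the germination frame is the first whose
tube area reaches 10 px sustained for two consecutive frames (robust to
single-frame noise blips at default noise; the visual call it replaces is
recovered to ±1 frame on seeded renders), and t = 0 is the preceding frame.
QC keeps tubes observed ≥ 60 min post-germination and not obstructed.

The early-vs-late comparison takes each tube's mean frame-wise increase over
the first and last 10 post-germination frames and runs Friedman's two-way
analysis of variance by ranks with k = 2, mid-ranks for ties and the
standard tie-corrected χ² approximation (Q = n when all tubes rank late
above early). k = 2 is kept rather than reduced to a sign test to mirror
the classical workflow. The χ² approximation tracks an exact 2ⁿ sign-flip
permutation null closely only in the strong-separation tail (≥ 11 of 12
concordant pairs, where the gap is < 0.005); at moderate effect sizes the
exact null is too discrete for any continuous approximation — the
comparison this test exists for lives deep in that tail.

The area→length conversion factor is the through-origin least-squares slope
of tube length against area over frames with area ≥ 100 µm²; for a cylinder
of width *w* it converges to 1/*w* (0.182 µm⁻¹ at the default 5.5 µm) as
the tube elongates. Phase annotation places the bulging/transition boundary
at the roundness maximum within the first 30 min and the transition/rapid
boundary where the frame-wise increase first exceeds 50% of the last-10-
frame mean; degenerate tracks (flat roundness, or no frame reaching the
rapid criterion) are flagged rather than force-labeled. Deceleration events
are local minima of the 3-frame moving-average increase within the rapid
phase, reported with the area at which they occur. The overall growth rate
is defined as the mean cumulative area at exactly 60 min post-germination,
expressed per hour, since observation windows vary.

## Polarization events

Vesicle-peak series follow the variable-ROI convention: per frame the ROI is
the largest connected component above the 0.5% peak threshold, integrated
intensity is mean gray × ROI size (= the ROI pixel sum), and each tube's
series is normalized to its maximum. Peaks are local maxima with prominence
≥ 0.2 of the per-tube maximum; a peak is site-concordant when the direction
from the grain centroid to the intensity-weighted ROI centroid lies within
30° of the germination direction (estimated from the early tube centroid,
not taken from ground truth). Prominence and cone half-width are free
parameters exposed in the config; the reporting windows ([−60,−36],
[−12,−9], [−6,−3] min) are closed at both ends with the earlier window
taking boundary ties.

Abnormal-pattern labels are assigned with precedence second-tube →
branching → arrest: a second sustained germination event > 45° from the
first; two simultaneous peak-threshold ROIs > 30° apart (each at least 25%
of the frame's largest ROI, so noise clusters cannot fake a second focus);
or normalized vesicle intensity below 10% of its maximum while the
frame-wise increase stays below 10% of the cohort median for ≥ 5 frames.
The joint arrest criterion exists so that photobleaching alone is never
called an arrest.

Actin polarity is the mean cortical intensity per 10° bin over a 3-px band
inside the grain boundary, pre-germination frames only; the polarity
direction is the intensity-weighted circular mean and the index its
resultant length (0 uniform, 1 focused). MGU translocation is the first
frame from which the farthest above-threshold sperm-membrane pixel from the
grain centroid stays outside the grain mask for all later frames; the
membrane channel is thresholded at half-maximum above the background floor
because a floor-level threshold would let the defocus halo of the thin
bright curve masquerade as the tip. Adding later frames can delay or
confirm, never advance, a detected translocation.

## Problem sizes

Unit tests render 96×192 px, 5-slice stacks (~0.1 s each). Cohort-level
tests and the acceptance script use the cohort geometry above: 66 tubes for
the first-vs-last Friedman comparison, 30 grains for the peak-frequency
table, 12–20 tubes for the calibrated window/event recoveries — sizes at
which each recovery's two-standard-error band is a meaningful test of the
pipeline while a full run stays within a few minutes on one CPU.

## Known limitations

* The renderer's image-formation model is deliberately simple (see above);
  recovery results bound measurement error under that model only.
* Junction width is measured as the extent of a 1-px boundary band and is
  resolution-dependent at the ±1 px level; it is used as a qualitative
  (constant vs widening) signature, as in visual scoring.
* `classify_trajectory` compares against default-parameter templates; tubes
  with grossly different grain geometry would need regenerated templates.
* Grain drift, focus drift, and photobleaching corrections are out of scope;
  tracks from drifting acquisitions should be excluded by the QC flag.
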