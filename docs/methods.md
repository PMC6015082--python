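# Methods

This note documents the models, conventions and parameter choices
behind `endopolar`, and what the synthetic benchmarks do and do not
establish about real data.

## Coordinate and angle conventions

Pixel coordinates are 0-based `(row, col)` with pixel centers on the
integer grid; physical positions are `(x, y) = (col, row) · pixel_size`
in micrometres. Angles are degrees in `[0, 360)`, computed on
`(dx, −dy)` so that the visually counter-clockwise direction is
positive. The published analyses do not fix a lateral sign convention
(whether 90° lies left or right of the motion); all quantities reported
here (front-quadrant fraction, Rao's U, bin fractions) are symmetric
under reflection, so the choice is observable only in per-spot angle
tables. The convention is defined once in `geometry.py` and used
everywhere.

## Nucleus segmentation, tracking and kinematics

Nuclei are segmented per frame from the max z-projection of the nuclear
channel: Gaussian smoothing with σ = nucleus radius / 4 (in pixels),
Otsu threshold on the smoothed image, hole filling, and a minimum-area
filter at 25% of the expected nucleus area. The source analyses state
only "smoothing and thresholding"; these scales are the package's own
defaults and are configurable.

Linking is greedy nearest-neighbour between consecutive frames under a
maximum jump (default 1.5× nucleus radius per frame): candidate pairs
are accepted in order of increasing distance, ties broken toward the
smaller detection label, making the procedure deterministic. No
gap-closing or probabilistic tracking is attempted; on the
well-separated nuclei this pipeline targets, greedy linking agrees with
the optimal (Hungarian) assignment, which the test suite verifies on
seeded instances.

Per-frame velocity is the forward difference `(c[t+1] − c[t]) / Δt`, so
the direction at frame *t* describes the step being taken — the same
step relative to which the generator draws that frame's endosome
angles. Frames displacing less than `min_displacement` (default half a
pixel) keep their speed but have no direction: a stalled nucleus
defines no velocity frame, and spots on such frames are excluded from
the angular pooling (the count is logged). Persistence is net
displacement over path length, in [0, 1].

## Endosome detection and the velocity frame

Spots are enhanced with a scale-normalized Laplacian of Gaussian at the
expected spot σ. The response threshold is `median + k · 1.4826 · MAD`
(k = 5 by default): both statistics scale linearly with intensity, so
detection is invariant to a global intensity scale, and the LoG response
is unaffected by an additive offset. Regional maxima (8-connectivity;
a plateau yields a single marker) seed a watershed on the inverted
response restricted to the above-threshold support, splitting touching
spots; empirically the split resolves pairs down to ~3σ separation, and
detection is exact on noiseless spots ≥ 4σ apart. Spot centroids are
intensity-weighted. Spots are assigned to the nearest tracked nucleus
within 3× nucleus radius ("around each nucleus" is otherwise
unqualified); unassigned spots are dropped and counted.

Angles pool over all endosome-frame observations of a condition.
Endosomes are re-drawn each frame by the generator and not linked in
time by the detector, matching the pooled, identity-free statistics.
This pooling treats each observation as independent; no hierarchical
correction for cell-level pseudoreplication is applied, which is a
known limitation of the pooled design.

## Rao's spacing test

For sorted angles with circular gaps *Tᵢ* (including the wrap-around
gap) and λ = 360/n, `U = ½ Σ |Tᵢ − λ|`; U is rotation- and
order-invariant, 0 for perfectly even spacing and `360(1 − 1/n)` when
all angles coincide. The p-value is Monte-Carlo:
`(1 + #{U* ≥ U}) / (R + 1)` over R uniform null samples at the observed
n (default R = 9999). The add-one estimator never returns 0 and is
exact at any n, avoiding interpolation in published critical-value
tables; fewer than 999 replicates cannot resolve p < 0.001 and triggers
a warning. Null generation is vectorized and chunked to bound memory.

## Angular mixture calibration

Synthetic endosome angles follow
`w · vonMises(μ, κ) + (1 − w) · Uniform[0, 360)`. The front-quadrant
mass of this mixture is `w · (F_κ(π/4) − F_κ(−π/4)) + (1 − w)/4`;
`kappa_for_front_fraction` inverts it by Brent's method. The confined
control regime is defined as front-quadrant mass 0.5 (κ ≈ 1.055 at
w = 1), the measured polarization level of that condition; uniformity
(κ = 0 or w = 0) is the large-pore regime.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes,
not the optics or mechanics of the experiment. Defaults: 0.5 µm pixels,
5-min frames, 8 µm nucleus radius, speed 0.4 µm/min, turn persistence
0.7 (direction update θ += (1 − persistence) · N(0, 90°), the simplest
persistent walk consistent with reporting speed and directionality),
constant step length, reflective borders (no truncation bias in angle
pooling), 12 endosomes per cell at radii 4–20 µm, centrosome placed at
1.5× nucleus radius along the movement direction when "ahead" (flag
Bernoulli per frame) and at 0.35× when not, 28% deformed nuclei,
30 degradation spots per cell in control fields. Rendering: nuclei as
filled ellipses (axis ratio 1.15) or two-lobed peanuts (lobe radius
0.75× nominal, lobe separation 1.8× lobe radius), point objects as
Gaussian peaks of the configured spot σ with bilinear sub-pixel
placement, Gaussian PSF blur (σ 0.8 px), then Poisson noise and
additive Gaussian read noise on a 100-count background, stored as
16-bit unsigned integers. Identical parameters and seed give
byte-identical output.

The benchmark nucleus population for the shape classifier carries
exactly `round(n · deformed_fraction)` deformed members in shuffled
order: the population's ground-truth rate is the set rate, so the
recovered fraction measures classifier error rather than label-sampling
noise. In generated movies, deformation labels are per-cell Bernoulli
draws.

Not modelled: collagen-fibril mechanics, photobleaching, 3-D PSF
optics, endosome motion between frames, cell-cell contact or overlap.
Passing end-to-end tests on these scenes shows the computational
pipeline is correct and unbiased under the stated imaging regime; it
does not validate segmentation or detection against the harder optical
conditions of real 3-D collagen movies.

## Collagenolysis quantification

Degradation spots: LoG filter, robust threshold, connected components,
minimum size 4 px (the 8-px exclusion is specific to the Tks5
invadopodia assay and is not applied here), automatic with no manual
correction. The degradation index is spots per cell normalized to the
control mean = 100; the index is linear in spot count and the control
mean is 100 by construction.

Line scans sample maximal intensity along a polyline at pixel pitch,
taking at each sample the maximum within a configurable transverse
width. Normalization maps (cell back, nucleus center, cell front) onto
(−1, 0, 1) by a two-segment piecewise-linear coordinate map — a single
affine map cannot pin three points in general — implemented by
inverting the map on the output grid (201 points over [−1, 1]), which
lands the references exactly and ignores samples outside the back–front
span. References may be supplied manually or derived from the DAPI
profile (weighted centroid; 10%-of-max edges) as a flagged extension.

## Morphometrics

Shape descriptors use the Crofton perimeter estimator (the chain-code
perimeter overestimates digitized circles by ~5%). A nucleus is
"deformed" when solidity < 0.92 or it has ≥ 2 convexity defects deeper
than 10% of the equivalent radius. The published scoring was visual
against supplementary criteria not included in the available text;
this rule is an explicit, configurable proxy calibrated on the
generator's labeled templates (error-free on those templates — real
nuclei are harder).

"Centrosome ahead of the nucleus front edge" is operationalized as the
scalar projection of the centrosome onto the movement direction
exceeding the maximal projection over nucleus-mask pixels, evaluated
only on frames with a defined direction. Centrosome–nucleus distance is
Euclidean distance to the nearest boundary pixel, 0 inside the mask.

Tks5 area uses IsoData thresholding inside the cell mask (Otsu by
flag), discards regions < 8 px, and reports the remainder as percent of
cell area. The invasion index sums per-slice DAPI intensity at depths
≥ 30 µm over the total; depth 0 is the first acquired slice (the gel
surface), with a `first_nonzero` origin option for acquisitions that
start above the gel. Ablation displacement is the net window
displacement projected on the movement direction, signed positive
toward movement, returned as a (pre, post) pair per cell.

## Problem sizes and numerical choices

The reproduction script measures the polarized Rao P at n = 500 with
9999 replicates; test calibration over 200 uniform samples of n = 300
at 1999 replicates; the full movie pipeline on 10 cells × 30 frames
(768² px); degradation on 10 + 10 fields of 5 cells; centrosome scoring
on 20 tracks × 50 frames; shape classification on 300 nuclei. The
pytest end-to-end check runs the movie pipeline at 8 cells × 24 frames;
both sizes give sampling error well inside the ±5-point bands. Bin
edges and the front quadrant are half-open (`[315°, 360) ∪ [0°, 45°)`).
Tracking ties break toward the smaller label; plateau maxima form one
marker; all Monte-Carlo and generator randomness is seeded.
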