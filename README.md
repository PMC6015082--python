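# endopolar

Quantitative image analysis for confined tumor-cell migration: how do
cells position their MT1-MMP collagenase stores and focus matrix
degradation when squeezing their stiff nucleus through a dense collagen
network?

`endopolar` re-implements, as a tested and reusable Python library, the
measurements used to answer that question from multi-channel
fluorescence time-lapse data:

* **Endosome polarity in the nucleus-velocity frame.** Nuclei are
  segmented and tracked; each detected MT1-MMP endosome is expressed in
  a per-frame polar coordinate system with origin at the nucleus
  centroid and 0° along the instantaneous direction of nuclear movement
  (front = 0°, rear = 180°). Pooled angles are binned into a 15° rose
  histogram and summarized by the *front-quadrant fraction* — the share
  of endosomes within ±45° of the movement direction (0.25 under
  uniformity).
* **Rao's spacing test of circular uniformity.** For sorted angles with
  circular gaps *Tᵢ* and equal-spacing value λ = 360°/n,
  *U* = ½ Σ |Tᵢ − λ|. Significance comes from a Monte-Carlo null of
  uniform samples at the observed *n* (add-one estimator, exact at any
  sample size).
* **Pericellular collagenolysis.** Degradation spots in cleaved-collagen
  (Col1-¾C) images are detected by Laplacian-of-Gaussian filtering;
  the *degradation index* is spots per cell, normalized so the control
  condition's mean is 100. Line-scan intensity profiles along the cell
  axis are mapped onto a common coordinate (cell back = −1, nucleus
  center = 0, cell front = +1) and averaged.
* **Morphometrics.** Nuclear deformation scoring (solidity and
  convexity-defect lobe count), centrosome-to-nucleus-rim distance, the
  percentage of frames with the centrosome ahead of the nucleus front
  edge, Tks5 invadopodia area (excluding regions < 8 px), transwell
  invasion index (DAPI intensity beyond 30 µm depth), and laser-ablation
  centrosome displacement.

Because the underlying raw movies are not publicly deposited, the
package ships a first-class **synthetic scene generator** that produces
ground-truthed movies with the same statistical structure (persistent
nuclear random walks, von Mises-mixture endosome clouds, Bernoulli
centrosome placement, two-lobed deformed nuclei, Poisson + Gaussian
camera noise), so every stage can be validated end to end against known
truth.

## Worked example

`examples/02_endosome_polarity.py` renders a confined-control scene
whose true endosome angles put 50% of spots in the front quadrant, then
runs the full pipeline — segment, track, detect, transform, pool, test:

```text
tracked nuclei: 6
pooled endosome observations: 1253
front-quadrant fraction: 0.492 (0.25 would be unpolarized)
Rao's spacing: U = 161.6 deg, P = 0.0001 (9999 MC replicates)
```

The pipeline recovers the generated 50% front polarization to within a
point, and Rao's test rejects uniformity at P < 0.001 — the polarized,
confined phenotype. `examples/03_degradation_index.py` shows the
collagenolysis read-out: treatment fields generated at 40% of the
control spot density come out at a mean index of 40.6, i.e. a 59.4%
reduction. The other examples cover scene simulation, line-scan
normalization and morphometrics; each prints the numbers it computes
and a line on what they mean.

A thin command line mirrors the library for batch use:

```sh
endopolar simulate --config scene.yaml --out sim/
endopolar run-all sim/movie.tif --seed 1 --out analysis/
```

## Layout

```
src/endopolar/      library (synthetic, io, tracking, detection,
                    circular, collagenolysis, morphometrics, pipeline, cli)
examples/           one short narrative script per capability
tests/              pytest suite (unit, property and end-to-end tests)
docs/methods.md     models, conventions, parameter choices, limitations
scripts/acceptance.py   headline-number reproduction
```
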