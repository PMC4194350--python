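# Methods

## Detection model

Deposits are dye-dark objects on a light, slowly varying background, so
binarisation is relative to a local statistic: pixel *p* is foreground
iff `grey(p) < mean(W×W window at p) − offset`, with reflected padding
at the borders. The arithmetic local mean was chosen as the simplest
statistic that compensates for background gradients; the consequence,
verified by a property test, is exact invariance of the binary map
under a global intensity shift. Greyscale conversion uses the standard
luma weights (0.299, 0.587, 0.114), configurable.

Defaults (calibrated for 1200 dpi scans of wild-type plates):

| parameter | default | unit | why |
|---|---|---|---|
| window | 51 | px | odd; exceeds the typical deposit diameter so the mean is background-dominated |
| offset | 0.06 | intensity | above scanner noise, far below deposit contrast (~0.5) |
| min_area | 40 | px | rejects dust/dirt specks |
| max_area | 50 000 | px | rejects smears and moulding shadows |
| connectivity | 8 | — | diagonal-touching pixels are one deposit |
| ROD cutoff | 0.5 | circularity | sits in the valley between the two shape modes |

Area bounds rescale by `(dpi/1200)²` with a logged warning when the
image dpi differs; shape features remain resolution-sensitive, so
comparisons should only be drawn between identically processed scans.
Foreground regions are labelled 8-connectedly (labels 1..n in raster
order of first pixel), holes are filled per component (background
enclosed by the component, 4-connected — the dual of 8-connected
foreground; any other component lying inside a cavity is treated as part
of the cavity), and the size filter applies inclusive bounds. An
optional single-pass morphological opening (disc radius 1) before
labelling can separate weakly confluent deposits; it is off by default
and no splitting of merged deposits is attempted beyond it.

## Shape, colour and dye content

The perimeter is the closed polygon traced through the centres of the
outer border pixels by Moore border following: 1 per axial step, √2 per
diagonal step; components of one or two pixels return 0 by convention
(the size filter removes them in practice). Circularity is
`4π·area/perimeter²` clamped to [0, 1], since discretised contours of
small compact regions can overshoot 1.

A known property of this perimeter definition is that chain-length
polygons overestimate the true arc length of digitised *smooth* curves
by ≈5% on average, so rasterised discs measure circularity ≈0.91–0.94
rather than exactly 1 (squares, whose borders are axis-aligned, are
measured exactly). Both shape classes are far from the 0.5 cutoff, so
this bias does not affect ROD classification; it is the same behaviour
as contour-based perimeters in mainstream image libraries. Bias-corrected
step weights exist but would break the exact square perimeter and were
not adopted.

The ROD flag is `circularity < cutoff` (strict: a deposit at the cutoff
is non-ROD). Colour is the per-deposit mean RGB and the HSL of that
mean colour — not a circular mean of per-pixel hues, which would raise
circular-statistics ambiguities; hue is reported as integer degrees in
[0, 359], achromatic colours take hue 0 and saturation 0. IOD is
`area·(1 − meanL)`; it is a valid dye-amount proxy only when the scan is
calibrated so lightness is linear in dye concentration, which is the
user's responsibility.

## Plate summaries and statistics

Totals (spot count, area, IOD) are divided by the user-entered fly
count; means are unweighted over deposits. Pooled colour analyses all
subset pixels as one object, computed exactly as the area-weighted mean
of per-deposit mean RGB (means over disjoint pixel sets), which also
allows re-summarisation from exported tables that carry no pixel data.
Empty subsets report zero totals and NaN means — explicitly missing,
never zero, so downstream statistics skip rather than bias.

Tests: Student's pooled-variance t (Welch available as an option),
Mann–Whitney U with `U_a = #(a_i > b_j) + ties/2` (so `U_a + U_b =
n_a·n_b`), exact two-sided p by full enumeration of group assignments
when the combined n ≤ 16 without ties (cheap at the 6–8 replicates
typical of plate groups), otherwise a tie- and continuity-corrected
normal approximation. Jarque–Bera uses biased central moments and the
asymptotic χ²(2) p-value, with a flag marking n < 30 where that
asymptotic is unreliable — the test is displayed guidance for choosing
between t and U, never an automatic switch. Holm–Bonferroni is the
step-down adjustment over all comparisons requested in one call; with
correction disabled the adjusted p equals the raw p.

## Synthetic plates

The generator emulates what matters to the pipeline: a light background
(0.88) with a smooth low-frequency gradient (amplitude 0.05) that
defeats a global threshold but not a local one; hard-edged deposits of
two classes — discs of radius 8–14 px and capsules of width 5–8 px at
aspect ratio 5–7 (the oblong/ROD class), giving a cleanly bimodal
circularity distribution around the 0.5 cutoff; blue hues (210–250°,
neutral pH) with capsules darker (lightness 0.15–0.30 vs 0.35–0.55),
mirroring the concentrated RODs of mated females; and ~12 sub-threshold
specks (radius ≤ 2.2 px) below the minimum size filter. Placement is
rejection-sampled with a 4 px separation unless overlap is allowed;
a single seeded Generator stream makes plates bit-reproducible. The
default plate is 600×600 px with 30 + 30 deposits — the benchmark
condition for classification accuracy. Capsules of aspect ~2:1
("transitional" shapes whose manual class is itself uncertain) can be
generated by overriding `oblong_aspect` but are excluded from the
default benchmark.

What the generator does *not* emulate: sensor noise, anti-aliased and
diffuse deposit edges, overlapping or confluent deposits, hue gradients
within a deposit, plate moulding shadows, and in-range artefacts. Green
benchmarks therefore demonstrate the correctness of the pipeline's
logic under clean, well-separated conditions, not detection performance
on dirty real scans — on real plates 10–20% of detections can be
artefacts requiring manual curation via the include flag.

## Numerical and design choices

* Threshold comparison is strict (`<`); ties at exactly `mean − offset`
  are background.
* Border padding for the local mean is reflective, avoiding spurious
  foreground at plate edges.
* Hole filling is idempotent and never removes pixels; component areas
  only grow.
* The exact Mann–Whitney branch and the normal-approximation branch
  meet at combined n = 16; p-values are capped at 1.
* Degenerate t-test inputs (zero pooled variance) short-circuit to
  t = 0, p = 1 for equal means and an infinite statistic otherwise.
* Batch processing is sequential and keyed by plate id: results are
  independent of job order, a failing image is recorded in the audit
  trail without aborting the batch, and an injectable clock makes saved
  stores byte-stable for determinism checks.
* The experiment store is a plain directory (JSON + CSVs) rather than a
  database: same hierarchy, diff-able, no service dependencies. Manual
  curation edits the `include` column of a deposit CSV followed by
  re-summarisation.

## Problem sizes

Benchmarks use 600×600 px plates (about a quarter of a full 1200 dpi
plate crop) and 20-plate batches; detection takes ~70 ms per plate, so
the full accuracy benchmark runs in a few seconds. Statistical
calibration checks use 1000 two-group replicates at n = 8 per group
(t-test size) and 200 replicates of n = 5000 (Jarque–Bera under the
null).

## Known limitations

* No splitting of confluent deposits; the optional opening only
  separates single-pixel bridges.
* Chain-length perimeter bias on smooth digital contours (above);
  circularity of large discs plateaus near 0.91 instead of 1.
* Hue of very desaturated deposits is numerically unstable (as for any
  HSL readout); the dye keeps real deposits saturated.
* The asymptotic Jarque–Bera p is anti-conservative at plate-group
  sizes; treat it as guidance, as the flag indicates.
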