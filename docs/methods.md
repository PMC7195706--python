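# Methods

## The counting model

A filter-assay image is scored by object detection over two classes: the
**seed** (an entire seed body, germinated or not) and the **radicle onset**
(the junction where the embryonic root emerges from a germinated seed).
The number of radicle-onset detections equals the number of germinated
seeds, so the per-image deliverable is the triple (total seeds, radicle
onsets, germination % = 100 · onsets / seeds). The two classes are counted
**independently** — no onset-to-seed matching is attempted — which mirrors
how validation against hand counts is done (pooled totals per class) and
means germination above 100% is representable; such values are reported
as computed and flagged with a warning, never clamped. An image with zero
detected seeds has undefined germination, serialized as the literal `NA`
and excluded (but tallied) by the evaluation metric; this degenerate case
has no established convention, so `NA` is this package's choice.

### Coordinate conventions

Internally boxes are 0-based, half-open `[x_min, x_max) × [y_min, y_max)`
with continuous coordinates. Pascal-VOC XML (the LabelImg dialect) is read
as 1-based inclusive (`x_min_internal = xmin_voc − 1`,
`x_max_internal = xmax_voc`); Darknet text as normalized center/size.
Routing both dialects through one internal hub keeps every converter a
two-way map with a round-trip contract: exact for VOC integers, within one
pixel of quantization for normalized text.

## Detection post-processing

A single-stage grid detector emits, per cell `(i, j)` and anchor `a`, the
raw vector `(t_x, t_y, t_w, t_h, objectness logit, class logits)`. Decoding
follows the standard closed form: center
`((j + σ(t_x)), (i + σ(t_y))) · resolution/S`, size
`anchor_wh · exp(t_w, t_h)`, probabilities through independent sigmoids.
The decoder handles one grid per call and performs no filtering — exactly
`S·S·anchors` detections out — so thresholding and suppression remain
separately testable.

Filtering keeps detections with **objectness ≥ P** (inclusive; the
confidence used is objectness alone, not objectness × class probability).
Suppression is greedy class-wise NMS at IoU 0.45 by default: detectors
emit overlapping candidates and require it, while cross-class overlaps are
deliberately untouched because a radicle-onset box legitimately overlaps
its seed's box.

Anchor shapes are derived from annotated boxes by K-means (K = 9) under
the distance `1 − IoU` of center-aligned boxes; plain Euclidean on (w, h)
is an option. The update step moves a representative to its members' mean
but keeps the previous representative whenever the mean would increase the
within-cluster distance sum, which makes the objective provably
non-increasing under the IoU metric (a plain mean update does not
guarantee this). Initialization is farthest-point seeding from a seeded
RNG start, so well-separated shape clusters always receive one
representative each and runs are deterministic. Emptied clusters are
reseeded with the box farthest from its representative.

The letterbox maps native resolution (e.g. a ~2500 × 2500 merged filter
image, or a 2560 × 1920 raw capture) onto the square network input
(608 px default) by aspect-preserving scaling plus symmetric neutral-gray
padding; the transform is stored and inverted to return detections to
native pixels within one pixel.

The network's training recipe (SGD, momentum 0.9, learning rate 1e-3,
weight decay 5e-4, 20 000 epochs with lr/10 at 16 000 and 18 000, 608 px
input, HSV/flip/jitter augmentation) is carried as validated,
round-trippable configuration metadata only; training itself is outside
this package's scope, and the classical backend (below) fills the
detector's role in all executable paths.

## The synthetic assay generator

The simulator emulates the standard capture geometry: a 13 mm disc imaged
into a ~2500 px frame fixes the scale at ~192 px/mm (no µm/px is given by
assay protocols; this is the one derived constant everything else hangs
off). Defaults encode the study conditions:

| parameter | default | rationale |
|---|---|---|
| image_size | 2500 px | merged full-filter frame |
| filter_diameter | 2400 px | 13 mm disc at ~192 px/mm, small border |
| n_seeds | 50 | typical load per filter |
| germination_fraction | 0.40 | gives the observed ~2.5:1 seed:radicle annotation imbalance |
| seed_axis_px | 25–38 px | < 200 µm seeds at ~192 px/mm |
| seed_aspect | 0.55–0.95 | seed bodies are stubby ellipses |
| radicle_length_px | 20–120 px | emerging to well-developed radicles |
| radicle_width_px | 3–6 px | thin root filament |
| debris_density | 30 | impurities of seed-like size/contrast |
| noise_sigma | 6 gray levels | sensor/texture noise |

`n_seeds` is the exact per-image count (not a sampled mean): assay
protocols load a target number of seeds per filter, and exact counts make
every scene's ground truth a sharp oracle. Germinated seeds are
`round(n_seeds · fraction)`, assigned to random seeds.

Placement is rejection sampling against an occupancy mask: each seed's
margin-dilated footprint (ellipse plus, if germinated, its radicle curve)
must not touch previously placed objects, with a bounded retry budget
(default 100 per object) and a helpful error beyond it. Radicles are
quadratic-curvature polylines leaving one pole of the seed outward, stamped
as discs of the radicle half-width. The radicle-onset ground-truth box is a
square with side equal to the seed's minor axis centered on the pole —
onset annotations mark a location, not an extent, so the box size is a
package convention. Debris are unions of jittered discs with intensity
drawn across the seed/radicle contrast range, left unannotated.

Per-image seeds derive from the master seed via
`SeedSequence.generate_state`, a documented mixing function stable across
platforms, making whole datasets reproducible from one integer.

What the simulator does **not** model: glass-fibre texture, uneven
illumination, optical blur, touching/overlapping seeds, debris that
physically contacts seeds, and color. Passing tests therefore demonstrate
the correctness of the counting/evaluation machinery and the detector's
behavior under the modelled variation, not performance on real
micrographs.

## The classical reference detector

The reference backend is intentionally classical so that its failure
modes are transparent. Steps: (1) locate the bright disc by Otsu
thresholding, largest component, hole filling; (2) mark objects as pixels
darker than the disc median by a contrast offset (45 gray levels) inside
the disc; (3) per connected component, morphological opening with a
radius-4 disk strips structures thinner than ~9 px — i.e. the radicle —
leaving the seed body; (4) the body is gated by smooth score ramps on its
major/minor axis lengths and solidity; (5) the residual (component minus
dilated body) is an onset candidate if large and elongated enough and
attached to the body, with the junction located at the residual pixel
nearest the body; one onset maximum per seed component.

Each detection's pseudo-objectness is the product of its shape-score
ramps clipped to [0.01, 0.99] — a normalized shape-score margin — so
threshold sweeps over P behave smoothly: true objects score near the top
of the range, debris scores spread across it. The gate ranges are tied to
the simulator's default geometry and are parameters
(`ClassicalParams`) for other geometries.

## Stitching

Half-filter pairs are merged by a 1-D translation search: candidate
overlaps are scored by normalized cross-correlation of the shared rows, the
best is accepted if it correlates above 0.5, and the overlap is blended
with a linear ramp. Overlaps leaving fewer than 16 new rows are never
considered, and if the excluded full-overlap alignment correlates at least
as well as the best admissible one the pair is rejected as near-identical
(the minimum-new-content guard). Perspective or rotational mosaicking is
out of scope.

## Evaluation and model selection

The metric is the **average germination difference**: the mean over images
of |predicted − true| germination, in percentage points — a per-image
absolute mean, not a pooled-count difference. Model selection evaluates
this metric over a grid — training checkpoints at fixed P = 0.05, then
P ∈ {0.01, …, 0.10} for the chosen checkpoint — and selects the minimum,
breaking ties toward the smaller threshold / earlier checkpoint (selection
grids in practice have unique minima; the tie rule just makes the
machinery total). Per-class accuracy is the signed pooled underestimation
`(hand − tool)/hand · 100` (positive = undercount, reported to three
decimals), and per-image errors are histogrammed into half-open 5-point
ranges with a pooled overflow bin at 30, as percentages of images.

## Numerical and formatting choices

- Percentages and rates print with two decimals (`50.00`, `0.67`);
  underestimation with three; internal values stay full precision.
- CSV output is comma-delimited UTF-8 with a fixed four-column header;
  results tables are written atomically (temp file + rename).
- Overlay colors are fixed per class (seeds purple, onsets bright green,
  haustoria red); drawing never alters image dimensions.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical (config, seed) reproduces scenes,
  anchors and runs bit-for-bit.

## Problem sizes used in the checks

The end-to-end recovery check runs 50 full-size (2500 px) clean assays
(no debris) through simulation, classical detection at P = 0.06, NMS and
counting; unit-level checks use reduced scenes (700–900 px discs, 12–20
seeds, radicles capped at 60–70 px so the geometry still fits) — the same
object geometry on a smaller field, chosen to keep the suite quick while
exercising identical code paths. Randomized oracle suites use 1000 NMS
instances and 100 anchor-recovery trials.

## Known limitations

- The classical backend assumes the simulator's contrast polarity (dark
  objects on a bright disc) and roughly its scale; real micrographs would
  need gate recalibration and would not reach the clean-scene recovery
  shown here.
- With debris enabled, debris of seed-like shape scores mid-to-high
  pseudo-objectness and inflates seed counts at the default P; this is the
  intended stress behavior, not a bug.
- The extended (haustorium) class exists in the type system, annotation
  formats and summary arithmetic, but no backend detects haustoria; the
  segmentation summary consumes externally supplied counts.
- The raw-grid backend decodes one scale per call; multi-scale outputs are
  concatenated by the caller.
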