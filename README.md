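# strigacount

Automated counting of *Striga* seeds and radicle onsets in glass-fibre
filter germination assays.

## The problem

*Striga hermonthica* is a root-parasitic weed devastating cereal production
across Sub-Saharan Africa. Its life cycle starts with seed germination
triggered by host-derived signals, so screens for control compounds —
germination stimulants for suicidal germination, or inhibitors — revolve
around a standard bioassay: ~50 seeds spread on a 13 mm glass-fibre filter,
exposed to a treatment, then scored under a dissecting microscope. Because
the seeds are under 200 µm, manual counting of seeds and emerged radicles is
the throughput bottleneck.

This package implements the full counting workflow around an
object-detection model of that assay, plus everything needed to test it
without real imagery or trained network weights:

- **annotations** — canonical box/annotation types; LabelImg-style
  Pascal-VOC XML and Darknet normalized-text readers/writers; the
  germination formula `germ % = 100 · radicles / seeds`.
- **simulate** — a synthetic assay-image generator (bright filter disc,
  dark elliptical seeds, thin curved radicles, debris) with exact
  ground-truth annotations and bit-reproducible scenes.
- **detect** — detector post-processing: IoU, raw grid-cell/anchor output
  decoding, objectness threshold filtering, class-wise greedy NMS, and the
  letterbox resize between native and network resolution.
- **anchors** — K-means anchor-box derivation (distance `1 − IoU` of
  center-aligned boxes, K = 9 by default).
- **classical** — a fully classical reference detector
  (threshold/morphology/shape gating with smooth pseudo-objectness scores)
  that stands in for the neural backend so the pipeline runs end to end.
- **quantify** — per-image counts, the four-column results CSV
  (sample, total seeds, germinated seeds, germination %), box overlays, and
  the extended-system summary arithmetic (rates and mean object sizes from
  per-class pixel counts).
- **evaluate** — the average germination difference metric (mean
  |predicted − true| germination per image, in percentage points),
  checkpoint and threshold sweeps with minimum selection, per-class
  underestimation percentages, and 5-point error-range histograms.
- **stitch / pipeline / cli** — translation-only merging of top/bottom
  half-filter image pairs, run orchestration, and a thin `strigacount`
  command-line interface (`simulate`, `stitch`, `detect`, `validate`,
  `anchors`, `report`).

## Worked example

Simulate three small assays, count them at the default operating point
(objectness threshold P = 0.06, NMS IoU 0.45), and compare with the known
truth (`examples/count_filter_images.py`):

```text
sample      seeds  radicles   germ %   truth
sim_000        20         8    40.00   (20, 8)
sim_001        20         8    40.00   (20, 8)
sim_002        20         8    40.00   (20, 8)
```

Each row is one filter image: total seeds detected, radicle onsets
(= germinated seeds), and their ratio as the germination percentage — the
same four columns the `detect` subcommand writes to `counts.csv`.

Selecting the threshold P against hand counts
(`examples/threshold_sweep.py`), with false positives planted at
objectness 0.015–0.055 so P = 0.06 is the first grid point recovering the
exact counts:

```text
 setting  avg_germ_diff  seed_deviation  radicle_deviation
    0.01      13.333333           -50.0                0.0
    ...
    0.06       0.000000             0.0                0.0

selected P = 0.06 (avg germination difference 0.00 points)
```

Negative seed deviation marks overcounting from surviving false positives;
the sweep picks the smallest P that minimizes the average germination
difference.

The other examples cover scene simulation (`simulate_assay.py`), anchor
derivation (`anchor_clustering.py`), image-pair stitching
(`stitch_halves.py`), and the extended-system size/rate arithmetic
(`extended_summary.py`).

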