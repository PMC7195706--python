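"""Model evaluation against hand counts: metric, sweeps, histograms, tables.

The central accuracy metric is the average germination difference: the mean
over images of the absolute difference, in percentage points, between the
predicted and the hand-counted germination percentage.  Model selection is a
grid search over operating settings — training checkpoints at a fixed
confidence threshold, then the confidence threshold P itself over
0.01-0.10 — picking the setting that minimizes this metric (ties break
toward the smaller / earlier setting).

Per-class accuracy is summarized as a signed underestimation percentage of
pooled totals (positive = the tool counted fewer than the hand count), and
per-image errors as a frequency histogram over 5-point error ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GroundTruthCount
from .detect import Detection, nms, objectness_filter
from .quantify import CountResult, count_image

DEFAULT_P_GRID: tuple[float, ...] = tuple(round(0.01 * k, 2) for k in range(1, 11))


@dataclass(frozen=True)
class GermDiffResult:
    """Mean absolute germination difference plus the exclusion tally."""

    value: float
    n_images: int
    n_excluded: int


@dataclass(frozen=True)
class SweepPoint:
    setting: object
    avg_germ_diff: float
    seed_deviation: float
    radicle_deviation: float


@dataclass(frozen=True)
class SweepResult:
    """Grid of evaluated settings and the selected (minimizing) one."""

    points: tuple[SweepPoint, ...]
    selected: SweepPoint

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"setting": p.setting, "avg_germ_diff": p.avg_germ_diff,
              "seed_deviation": p.seed_deviation,
              "radicle_deviation": p.radicle_deviation}
             for p in self.points]
        )


@dataclass(frozen=True)
class ErrorHistogram:
    """Per-image error frequencies over half-open ranges [0,5), [5,10), ...

    The final bin pools everything at or above ``max_edge``.  Percentages of
    images sum to 100.
    """

    edges: tuple[float, ...]
    percentages: tuple[float, ...]
    n_images: int

    def as_table(self) -> pd.DataFrame:
        labels = [
            f"{self.edges[i]:g}-{self.edges[i + 1]:g}"
            for i in range(len(self.edges) - 1)
        ] + [f">={self.edges[-1]:g}"]
        return pd.DataFrame({"error_range_pct": labels,
                             "images_pct": self.percentages})


@dataclass(frozen=True)
class EvalReport:
    """Full validation summary at one operating point."""

    avg_germ_diff: float
    per_class_deviation: dict[str, float]
    histogram: ErrorHistogram
    n_images: int
    n_excluded: int
    operating_point: tuple[object, float]
    sweep: SweepResult | None = None


def _germ_pairs(
    predicted: Sequence[CountResult], truth: Sequence[GroundTruthCount]
) -> tuple[list[tuple[float, float]], int]:
    truth_by_sample = {t.sample: t for t in truth}
    overlap = [p for p in predicted if p.sample in truth_by_sample]
    if not overlap:
        raise ValueError("no overlapping sample names between predictions and truth")
    pairs: list[tuple[float, float]] = []
    excluded = 0
    import warnings

    for p in overlap:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred_pct = p.germination_pct
            true_pct = truth_by_sample[p.sample].germination_pct
        if pred_pct is None or true_pct is None:
            excluded += 1
            continue
        pairs.append((pred_pct, true_pct))
    return pairs, excluded


def avg_germ_diff(
    predicted: Sequence[CountResult], truth: Sequence[GroundTruthCount]
) -> GermDiffResult:
    """Mean absolute germination difference in percentage points.

    Images whose germination is undefined on either side (zero counted
    seeds) are excluded from the mean and counted in ``n_excluded``.
    """
    pairs, excluded = _germ_pairs(predicted, truth)
    if not pairs:
        return GermDiffResult(value=float("nan"), n_images=0, n_excluded=excluded)
    diffs = [abs(pred - true) for pred, true in pairs]
    return GermDiffResult(
        value=float(np.mean(diffs)), n_images=len(pairs), n_excluded=excluded
    )


def per_image_diffs(
    predicted: Sequence[CountResult], truth: Sequence[GroundTruthCount]
) -> list[float]:
    """Per-image absolute germination differences (defined pairs only)."""
    pairs, _ = _germ_pairs(predicted, truth)
    return [abs(p - t) for p, t in pairs]


def underestimation_pct(hand_total: int, tool_total: int) -> float:
    """Signed pooled-count deviation: ``(hand - tool) / hand * 100``.

    Positive means the tool undercounts; overestimation comes out negative
    and is not clamped.  Reported to three decimals.
    """
    if hand_total <= 0:
        raise ValueError("hand_total must be positive")
    return round((hand_total - tool_total) / hand_total * 100.0, 3)


def error_histogram(
    per_image_diffs: Sequence[float], bin_width: float = 5.0,
    max_edge: float = 30.0,
) -> ErrorHistogram:
    """Bin per-image errors into half-open 5-point ranges, as % of images.

    Errors at or beyond ``max_edge`` pool into a final overflow bin.
    """
    diffs = np.asarray(per_image_diffs, dtype=float)
    if diffs.size == 0:
        raise ValueError("no per-image differences supplied")
    if (diffs < 0).any():
        raise ValueError("differences must be non-negative")
    edges = np.arange(0.0, max_edge + bin_width / 2, bin_width)
    counts = np.zeros(len(edges), dtype=float)  # last slot = overflow
    for d in diffs:
        if d >= max_edge:
            counts[-1] += 1
        else:
            counts[int(d // bin_width)] += 1
    pct = counts / diffs.size * 100.0
    return ErrorHistogram(
        edges=tuple(edges), percentages=tuple(pct), n_images=int(diffs.size)
    )


def _pooled_deviation(
    results: Sequence[CountResult], truth_by_sample: Mapping[str, GroundTruthCount]
) -> tuple[float, float]:
    hand_seeds = sum(truth_by_sample[r.sample].n_seeds for r in results
                     if r.sample in truth_by_sample)
    hand_rad = sum(truth_by_sample[r.sample].n_radicles for r in results
                   if r.sample in truth_by_sample)
    tool_seeds = sum(r.total_seeds for r in results if r.sample in truth_by_sample)
    tool_rad = sum(r.n_radicles for r in results if r.sample in truth_by_sample)
    seed_dev = (underestimation_pct(hand_seeds, tool_seeds)
                if hand_seeds > 0 else float("nan"))
    rad_dev = (underestimation_pct(hand_rad, tool_rad)
               if hand_rad > 0 else float("nan"))
    return seed_dev, rad_dev


def _evaluate_setting(
    setting: object,
    score_sets: Mapping[str, Sequence[Detection]],
    truth: Sequence[GroundTruthCount],
    P: float,
    nms_iou: float,
) -> SweepPoint:
    results = [
        count_image(sample, nms(objectness_filter(dets, P), nms_iou))
        for sample, dets in score_sets.items()
    ]
    metric = avg_germ_diff(results, truth)
    truth_by_sample = {t.sample: t for t in truth}
    seed_dev, rad_dev = _pooled_deviation(results, truth_by_sample)
    return SweepPoint(
        setting=setting, avg_germ_diff=metric.value,
        seed_deviation=seed_dev, radicle_deviation=rad_dev,
    )


def sweep_threshold(
    score_sets: Mapping[str, Sequence[Detection]],
    truth: Sequence[GroundTruthCount],
    grid: Sequence[float] = DEFAULT_P_GRID,
    nms_iou: float = 0.45,
) -> SweepResult:
    """Evaluate the counting metric over a grid of confidence thresholds P.

    ``score_sets`` maps sample name to *unfiltered* detections carrying
    objectness, so each P can be applied afresh (filter, then NMS, then
    count).  The selected P minimizes the average germination difference;
    ties break toward the smallest P.
    """
    if len(grid) == 0:
        raise ValueError("threshold grid must not be empty")
    points = tuple(
        _evaluate_setting(P, score_sets, truth, P, nms_iou)
        for P in sorted(grid)
    )
    selected = min(points, key=lambda p: (p.avg_germ_diff, p.setting))
    return SweepResult(points=points, selected=selected)


def sweep_checkpoints(
    checkpoint_outputs: Mapping[object, Mapping[str, Sequence[Detection]]],
    truth: Sequence[GroundTruthCount],
    P: float = 0.05,
    nms_iou: float = 0.45,
) -> SweepResult:
    """Evaluate a set of training checkpoints at a fixed threshold P.

    ``checkpoint_outputs`` maps a checkpoint label (e.g. epoch number) to
    that checkpoint's per-sample unfiltered detections.  The checkpoint with
    the lowest average germination difference is selected; ties break toward
    the earliest checkpoint (input order).
    """
    if not checkpoint_outputs:
        raise ValueError("no checkpoints supplied")
    points = []
    order = {label: i for i, label in enumerate(checkpoint_outputs)}
    for label, score_sets in checkpoint_outputs.items():
        points.append(_evaluate_setting(label, score_sets, truth, P, nms_iou))
    selected = min(points, key=lambda p: (p.avg_germ_diff, order[p.setting]))
    return SweepResult(points=tuple(points), selected=selected)


def comparison_table(
    hand: tuple[int, int, float],
    tool: tuple[int, int, float],
    per_image_diffs: Sequence[float],
) -> pd.DataFrame:
    """Hand-count vs tool summary in the standard three-row layout.

    ``hand`` and ``tool`` are (seed total, radicle total, average
    germination %).  Rows: hand-count, tool, underestimation %; columns:
    seeds, radicles, average germination %, average difference per image.
    """
    hand_seeds, hand_rad, hand_germ = hand
    tool_seeds, tool_rad, tool_germ = tool
    avg_diff = float(np.mean(per_image_diffs)) if len(per_image_diffs) else float("nan")
    return pd.DataFrame(
        {
            "seeds": [hand_seeds, tool_seeds,
                      underestimation_pct(hand_seeds, tool_seeds)],
            "radicles": [hand_rad, tool_rad,
                         underestimation_pct(hand_rad, tool_rad)],
            "avg_germination_pct": [round(hand_germ, 2), round(tool_germ, 2),
                                    np.nan],
            "avg_diff_per_image": [round(avg_diff, 2), np.nan, np.nan],
        },
        index=["hand_count", "tool", "underestimation_pct"],
    )


def build_eval_report(
    score_sets: Mapping[str, Sequence[Detection]],
    truth: Sequence[GroundTruthCount],
    grid: Sequence[float] = DEFAULT_P_GRID,
    nms_iou: float = 0.45,
    model_id: object = "classical",
) -> EvalReport:
    """Run the threshold sweep and summarize the selected operating point."""
    sweep = sweep_threshold(score_sets, truth, grid=grid, nms_iou=nms_iou)
    P = float(sweep.selected.setting)
    results = [
        count_image(sample, nms(objectness_filter(dets, P), nms_iou))
        for sample, dets in score_sets.items()
    ]
    metric = avg_germ_diff(results, truth)
    diffs = per_image_diffs(results, truth)
    hist = error_histogram(diffs)
    return EvalReport(
        avg_germ_diff=metric.value,
        per_class_deviation={
            "seed": sweep.selected.seed_deviation,
            "radicle": sweep.selected.radicle_deviation,
        },
        histogram=hist,
        n_images=metric.n_images,
        n_excluded=metric.n_excluded,
        operating_point=(model_id, P),
        sweep=sweep,
    )
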