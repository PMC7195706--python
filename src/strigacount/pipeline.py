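"""Run orchestration: configured detection and validation over image sets.

Ties the stages together the way a screening lab uses them: point a run at
a directory of filter images, get back a four-column counts CSV plus one
overlay PNG per image; or supply a hand-count table and get the threshold
sweep, error histogram and comparison report.  Results files are written
atomically (write to a temp file, then rename), so a crashed run never
leaves a half-written table.
"""

from __future__ import annotations

import glob as globmod
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .annotations import GroundTruthCount, read_ground_truth_table
from .classical import ClassicalParams, detect_classical
from .detect import (Detection, decode_raw, load_raw_grid, nms,
                     objectness_filter)
from .evaluate import EvalReport, SweepResult, build_eval_report
from .quantify import CountResult, count_image, render_overlay, write_counts_table

log = logging.getLogger("strigacount")


@dataclass
class RunConfig:
    """One run's settings: inputs, backend, operating point, output paths.

    The default operating point is objectness threshold P = 0.06 with
    class-wise NMS at IoU 0.45.
    """

    inputs: Sequence[str] = field(default_factory=list)
    backend: str = "classical"          # classical | raw-grids
    threshold: float = 0.06
    nms_iou: float = 0.45
    output_dir: str = "results"
    rng_seed: int = 0
    write_overlays: bool = True
    anchors: Sequence[tuple[float, float]] | None = None
    classical_params: ClassicalParams | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold P must lie in [0, 1]")
        if self.backend not in ("classical", "raw-grids"):
            raise ValueError(f"unknown backend {self.backend!r}")


def setup_logging(output_dir, verbose: bool = False) -> None:
    """Console + run-log-file logging."""
    Path(output_dir).mkdir(parents=True, exist_ok=True)
    handlers = [
        logging.StreamHandler(),
        logging.FileHandler(Path(output_dir) / "run.log"),
    ]
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def resolve_inputs(patterns: Sequence[str]) -> list[Path]:
    paths: list[Path] = []
    for pattern in patterns:
        p = Path(pattern)
        if p.is_dir():
            paths.extend(sorted(p.glob("*.png")) + sorted(p.glob("*.jpg")))
        else:
            paths.extend(Path(m) for m in sorted(globmod.glob(str(pattern))))
    if not paths:
        raise FileNotFoundError(f"no input images match {list(patterns)}")
    return paths


def atomic_write_counts(results: Sequence[CountResult], destination) -> None:
    """Write the counts CSV via a temp file + rename, never partially."""
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(
        dir=destination.parent, suffix=".csv.part"
    )
    os.close(fd)
    try:
        write_counts_table(results, tmp)
        os.replace(tmp, destination)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _detect_one(
    image: np.ndarray, config: RunConfig, raw_path: Path | None = None
) -> list[Detection]:
    if config.backend == "classical":
        return detect_classical(image, config.classical_params)
    if config.anchors is None:
        raise ValueError("raw-grids backend requires an anchor set")
    raw = load_raw_grid(raw_path)
    return decode_raw(raw, config.anchors)


def run_detect(config: RunConfig) -> list[CountResult]:
    """Detect, filter, suppress and count over every input image.

    Writes ``counts.csv`` (four columns) and, per image, an
    ``<stem>_annotated.png`` overlay into the output directory.  Unreadable
    images are skipped with a logged warning; the run continues.
    """
    paths = resolve_inputs(config.inputs)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: list[CountResult] = []
    for path in paths:
        t0 = time.perf_counter()
        try:
            image = iio.imread(path)
        except Exception as exc:  # unreadable input: skip, keep running
            log.warning("skipping unreadable image %s: %s", path, exc)
            continue
        dets = _detect_one(image, config, raw_path=path.with_suffix(""))
        kept = nms(objectness_filter(dets, config.threshold), config.nms_iou)
        result = count_image(path.stem, kept)
        results.append(result)
        if config.write_overlays:
            overlay = render_overlay(image, kept)
            iio.imwrite(out_dir / f"{path.stem}_annotated.png", overlay)
        log.info(
            "%s: %d seeds, %d radicles (%.2f s)",
            path.stem, result.total_seeds, result.n_radicles,
            time.perf_counter() - t0,
        )
    if not results:
        raise RuntimeError("no readable input images")
    atomic_write_counts(results, out_dir / "counts.csv")
    return results


def run_validate(
    config: RunConfig, truth_table
) -> tuple[EvalReport, SweepResult]:
    """Sweep the confidence threshold against a hand-count table.

    ``truth_table`` is a CSV path or a list of :class:`GroundTruthCount`.
    Every input image must have a truth row; missing samples are an error.
    """
    if isinstance(truth_table, (str, Path)):
        truth = read_ground_truth_table(truth_table)
    else:
        truth = list(truth_table)
    truth_names = {t.sample for t in truth}
    paths = resolve_inputs(config.inputs)
    missing = [p.stem for p in paths if p.stem not in truth_names]
    if missing:
        raise ValueError(
            f"hand-count table is missing samples: {', '.join(missing)}"
        )
    score_sets: dict[str, list[Detection]] = {}
    for path in paths:
        image = iio.imread(path)
        score_sets[path.stem] = _detect_one(
            image, config, raw_path=path.with_suffix("")
        )
        log.info("%s: %d raw detections", path.stem, len(score_sets[path.stem]))
    report = build_eval_report(
        score_sets, truth, nms_iou=config.nms_iou, model_id=config.backend
    )
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.sweep.as_frame().to_csv(out_dir / "threshold_sweep.csv", index=False)
    report.histogram.as_table().to_csv(out_dir / "error_histogram.csv", index=False)
    log.info(
        "selected P=%.2f with avg germination difference %.2f points",
        report.operating_point[1], report.avg_germ_diff,
    )
    return report, report.sweep


def validate_scenes(
    scenes, truth: Sequence[GroundTruthCount] | None = None,
    nms_iou: float = 0.45,
    classical_params: ClassicalParams | None = None,
) -> EvalReport:
    """In-memory validation of simulated scenes with the classical backend."""
    score_sets = {
        s.annotation.image_id: detect_classical(s.image, classical_params)
        for s in scenes
    }
    if truth is None:
        truth = [s.ground_truth for s in scenes]
    return build_eval_report(score_sets, truth, nms_iou=nms_iou)
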