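"""Turning detections into deliverables: counts, tables, overlays.

The workflow's two outputs per run are (i) an overlay image per input with
seed and radicle boxes drawn in distinct colors, and (ii) a four-column CSV
(sample, total seeds, germinated seeds, germination percentage).  Seed and
radicle detections are counted independently — a radicle onset is not
matched to a particular seed detection — so germination above 100% is
possible and is reported, not clamped.

Also included is the extended-system summary arithmetic: given per-class
object and pixel counts from a (hypothetical) semantic segmentation, derive
germination and haustoria-development rates and mean per-object sizes.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import Box, clip_box, format_pct, germination_pct
from .detect import Detection

#: Overlay colors (RGB): seeds purple, radicle onsets bright green,
#: haustoria red — one fixed color per class.
OVERLAY_COLORS: dict[str, tuple[int, int, int]] = {
    "seed": (160, 32, 240),
    "radicle": (0, 255, 0),
    "haustorium": (255, 40, 40),
}


@dataclass(frozen=True)
class CountResult:
    """Per-image record: sample name, seed count, radicle count, germination %."""

    sample: str
    total_seeds: int
    n_radicles: int

    def __post_init__(self) -> None:
        if self.total_seeds < 0 or self.n_radicles < 0:
            raise ValueError("counts must be non-negative")

    @property
    def germination_pct(self) -> float | None:
        return germination_pct(self.total_seeds, self.n_radicles)


def count_image(sample: str, dets: Sequence[Detection]) -> CountResult:
    """Count post-NMS detections per class for one image."""
    seeds = sum(1 for d in dets if d.predicted_class == "seed")
    radicles = sum(1 for d in dets if d.predicted_class == "radicle")
    return CountResult(sample=sample, total_seeds=seeds, n_radicles=radicles)


def write_counts_table(results: Sequence[CountResult], destination) -> None:
    """Write the four-column results CSV.

    Columns: sample, total_seeds, germinated_seeds, germination_pct; one row
    per image in input order; percentages with two decimals; undefined
    germination rendered as the literal ``NA``.  Duplicate sample names are
    flagged with a warning but still written.
    """
    seen: set[str] = set()
    for r in results:
        if r.sample in seen:
            warnings.warn(f"duplicate sample name {r.sample!r} in results",
                          UserWarning, stacklevel=2)
        seen.add(r.sample)
    destination = Path(destination)
    with destination.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample", "total_seeds", "germinated_seeds", "germination_pct"]
        )
        for r in results:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # overflow already flagged upstream
                pct = r.germination_pct
            writer.writerow(
                [r.sample, r.total_seeds, r.n_radicles, format_pct(pct)]
            )


def render_overlay(image: np.ndarray, dets: Sequence[Detection],
                   line_width: int = 3) -> np.ndarray:
    """Draw one rectangle per detection on an RGB copy of the image.

    Output dimensions equal the input's; boxes reaching outside the image are
    clipped with a warning.  Deterministic: same inputs, same pixels.
    """
    from PIL import Image, ImageDraw

    if image.ndim == 2:
        rgb = np.stack([image] * 3, axis=-1)
    else:
        rgb = image.copy()
    h, w = rgb.shape[:2]
    canvas = Image.fromarray(rgb.astype(np.uint8))
    draw = ImageDraw.Draw(canvas)
    for det in dets:
        box = det.box
        if box.x_min < 0 or box.y_min < 0 or box.x_max > w or box.y_max > h:
            warnings.warn(
                f"detection box outside {w}x{h} image clipped for display",
                UserWarning, stacklevel=2,
            )
            box = clip_box(box, w, h)
        color = OVERLAY_COLORS[det.predicted_class]
        draw.rectangle(
            [box.x_min, box.y_min, box.x_max - 1, box.y_max - 1],
            outline=color, width=line_width,
        )
    return np.asarray(canvas)


# ---------------------------------------------------------------------------
# Extended-system summary arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationSummary:
    """Rates and mean per-object sizes from per-class object/pixel counts.

    Stores full precision; :meth:`report` rounds to the two decimals used in
    tabular output.  ``mean_size`` entries are mm² per object (``None`` for a
    class with no objects).
    """

    n_seeds: int
    n_germinated: int
    n_haustoria: int
    class_pixel_counts: dict[str, int]
    pixel_area: float
    germination_rate: float | None
    haustoria_rate: float | None
    mean_size: dict[str, float | None]

    def report(self) -> dict[str, float | None]:
        rounded = lambda v: None if v is None else round(v, 2)
        out: dict[str, float | None] = {
            "germination_rate": rounded(self.germination_rate),
            "haustoria_rate": rounded(self.haustoria_rate),
        }
        for cls, v in self.mean_size.items():
            out[f"mean_size_{cls}_mm2"] = rounded(v)
        return out


def segmentation_summary(
    n_seeds: int,
    n_germinated: int,
    n_haustoria: int,
    class_pixel_counts: dict[str, int],
    pixel_area: float,
) -> SegmentationSummary:
    """Summary arithmetic for the extended (segmentation-capable) system.

    ``germination_rate = n_germinated / n_seeds`` and
    ``haustoria_rate = n_haustoria / n_germinated`` (``None`` when the
    denominator is zero); ``mean_size(class) = pixels(class) / objects(class)
    * pixel_area`` with objects = seeds, germinated seeds, or haustoria for
    the seed, radicle and haustorium classes respectively.

    Example: 6 seeds of which 3 germinated and 2 with haustoria, pixel
    counts 400/300/100 and 0.1 mm² per pixel give rates 0.50 and 0.67 and
    mean sizes 6.67, 10 and 5 mm².
    """
    if min(n_seeds, n_germinated, n_haustoria) < 0:
        raise ValueError("object counts must be non-negative")
    if pixel_area <= 0 or not math.isfinite(pixel_area):
        raise ValueError("pixel_area must be positive and finite")
    objects = {"seed": n_seeds, "radicle": n_germinated,
               "haustorium": n_haustoria}
    mean_size: dict[str, float | None] = {}
    for cls, n_obj in objects.items():
        pixels = int(class_pixel_counts.get(cls, 0))
        if pixels < 0:
            raise ValueError(f"negative pixel count for {cls}")
        if n_obj == 0:
            if pixels > 0:
                raise ValueError(
                    f"{pixels} {cls} pixels reported but zero {cls} objects"
                )
            mean_size[cls] = None
        else:
            mean_size[cls] = pixels / n_obj * pixel_area
    germination_rate = n_germinated / n_seeds if n_seeds > 0 else None
    if n_germinated == 0 and n_haustoria > 0:
        raise ValueError("haustoria reported without germinated seeds")
    haustoria_rate = n_haustoria / n_germinated if n_germinated > 0 else None
    return SegmentationSummary(
        n_seeds=n_seeds,
        n_germinated=n_germinated,
        n_haustoria=n_haustoria,
        class_pixel_counts=dict(class_pixel_counts),
        pixel_area=pixel_area,
        germination_rate=germination_rate,
        haustoria_rate=haustoria_rate,
        mean_size=mean_size,
    )
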