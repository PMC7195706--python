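"""Detection post-processing: IoU, objectness filtering, NMS, grid decoding.

A single-stage detector emits, for every grid cell and anchor, four box
parameters, an objectness logit and per-class logits.  This module decodes
those raw grids into pixel-space :class:`Detection` objects, and provides the
standard post-processing chain (confidence thresholding, class-wise greedy
non-maximum suppression) plus the aspect-preserving letterbox resize used to
map between native image resolution and the network input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .annotations import Box

DETECT_CLASSES: tuple[str, ...] = ("seed", "radicle")


@dataclass(frozen=True)
class Detection:
    """One detector output: a box with objectness and class probabilities."""

    box: Box
    objectness: float
    class_probs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.objectness <= 1.0:
            raise ValueError(f"objectness {self.objectness} outside [0, 1]")
        for name, p in self.class_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"class probability {name}={p} outside [0, 1]")

    @property
    def predicted_class(self) -> str:
        if self.class_probs:
            return max(self.class_probs, key=self.class_probs.get)
        return self.box.label


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def objectness_filter(dets: Sequence[Detection], P: float) -> list[Detection]:
    """Keep detections with objectness >= ``P`` (the confidence threshold).

    Order is preserved.  Raising ``P`` can only shrink the result.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"threshold P={P} outside [0, 1]")
    return [d for d in dets if d.objectness >= P]


def nms(dets: Sequence[Detection], iou_threshold: float = 0.45) -> list[Detection]:
    """Greedy class-wise non-maximum suppression.

    Detections are visited by descending objectness; one is removed if it
    overlaps an already-retained detection of the same class with IoU above
    the threshold.  Cross-class overlaps are untouched (a radicle-onset box
    legitimately overlaps its seed's box).
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1)")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].objectness)
    kept: list[int] = []
    for i in order:
        d = dets[i]
        cls = d.predicted_class
        if any(
            dets[j].predicted_class == cls and iou(d.box, dets[j].box) > iou_threshold
            for j in kept
        ):
            continue
        kept.append(i)
    kept.sort()
    return [dets[i] for i in kept]


# ---------------------------------------------------------------------------
# Raw grid decoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawOutputGrid:
    """Raw detector output for one scale: shape (S, S, A, 5 + n_classes).

    Per cell and anchor the last axis holds ``(t_x, t_y, t_w, t_h,
    objectness logit, class logits...)``.
    """

    values: np.ndarray
    input_resolution: int = 608
    class_names: tuple[str, ...] = DETECT_CLASSES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4 or v.shape[0] != v.shape[1]:
            raise ValueError(
                f"raw grid must have shape (S, S, A, 5+C), got {v.shape}"
            )
        if v.shape[3] != 5 + len(self.class_names):
            raise ValueError(
                f"last axis {v.shape[3]} inconsistent with "
                f"{len(self.class_names)} classes"
            )
        object.__setattr__(self, "values", v)

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def anchors_per_cell(self) -> int:
        return self.values.shape[2]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def decode_raw(
    raw: RawOutputGrid,
    anchors: Sequence[tuple[float, float]],
    input_resolution: int | None = None,
) -> list[Detection]:
    """Decode a raw output grid into pixel-space detections (no filtering).

    For cell (i, j) and anchor a with prior size (w_a, h_a)::

        center = (j + sigmoid(t_x), i + sigmoid(t_y)) * (resolution / S)
        size   = (w_a * exp(t_w), h_a * exp(t_h))
        objectness = sigmoid(objectness logit)
        class probability = sigmoid(class logit)   (class-independent)

    Exactly ``S * S * anchors_per_cell`` detections are returned; thresholding
    and suppression are separate steps.  Coordinates are in the letterboxed
    input-resolution frame; use :meth:`LetterboxTransform.unmap_box` to return
    to native image coordinates.
    """
    resolution = input_resolution or raw.input_resolution
    S = raw.grid_size
    A = raw.anchors_per_cell
    anchors = list(anchors)
    if len(anchors) != A:
        raise ValueError(
            f"grid has {A} anchors per cell but {len(anchors)} anchor "
            "shapes were supplied"
        )
    v = raw.values
    cell = resolution / S
    dets: list[Detection] = []
    for i in range(S):
        for j in range(S):
            for a, (aw, ah) in enumerate(anchors):
                t = v[i, j, a]
                cx = (j + _sigmoid(t[0])) * cell
                cy = (i + _sigmoid(t[1])) * cell
                bw = aw * np.exp(t[2])
                bh = ah * np.exp(t[3])
                obj = float(_sigmoid(t[4]))
                probs = {
                    name: float(_sigmoid(t[5 + k]))
                    for k, name in enumerate(raw.class_names)
                }
                label = max(probs, key=probs.get)
                box = Box(
                    max(0.0, cx - bw / 2),
                    max(0.0, cy - bh / 2),
                    max(max(0.0, cx - bw / 2) + 1e-6, cx + bw / 2),
                    max(max(0.0, cy - bh / 2) + 1e-6, cy + bh / 2),
                    label,
                )
                dets.append(Detection(box=box, objectness=obj, class_probs=probs))
    return dets


def save_raw_grid(raw: RawOutputGrid, path) -> None:
    """Write a raw grid as a .npy array plus a small YAML sidecar descriptor."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), raw.values)
    sidecar = {
        "grid_size": raw.grid_size,
        "anchors_per_cell": raw.anchors_per_cell,
        "n_classes": len(raw.class_names),
        "class_names": list(raw.class_names),
        "input_resolution": raw.input_resolution,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def load_raw_grid(path) -> RawOutputGrid:
    """Load a raw grid written by :func:`save_raw_grid`, validating the sidecar."""
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    values = np.load(path.with_suffix(".npy"))
    grid = RawOutputGrid(
        values=values,
        input_resolution=int(meta["input_resolution"]),
        class_names=tuple(meta["class_names"]),
    )
    if grid.grid_size != int(meta["grid_size"]):
        raise ValueError(
            f"sidecar grid_size {meta['grid_size']} does not match "
            f"array shape {values.shape}"
        )
    return grid


# ---------------------------------------------------------------------------
# Letterbox resize
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LetterboxTransform:
    """Invertible mapping between native and letterboxed coordinates."""

    scale: float
    pad_x: float
    pad_y: float
    orig_width: int
    orig_height: int

    def map_box(self, box: Box) -> Box:
        return replace(
            box,
            x_min=box.x_min * self.scale + self.pad_x,
            y_min=box.y_min * self.scale + self.pad_y,
            x_max=box.x_max * self.scale + self.pad_x,
            y_max=box.y_max * self.scale + self.pad_y,
        )

    def unmap_box(self, box: Box) -> Box:
        x_min = (box.x_min - self.pad_x) / self.scale
        y_min = (box.y_min - self.pad_y) / self.scale
        x_max = (box.x_max - self.pad_x) / self.scale
        y_max = (box.y_max - self.pad_y) / self.scale
        return replace(
            box,
            x_min=max(0.0, x_min),
            y_min=max(0.0, y_min),
            x_max=min(float(self.orig_width), max(x_max, 1e-6)),
            y_max=min(float(self.orig_height), max(y_max, 1e-6)),
        )


def letterbox(
    image: np.ndarray, input_resolution: int, pad_value: int = 114
) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize onto a square canvas with neutral-gray padding.

    Returns the resized image and the transform mapping native pixel
    coordinates into the canvas.  ``unmap_box(map_box(b))`` recovers ``b``
    within a pixel.
    """
    from skimage.transform import resize

    if input_resolution <= 0:
        raise ValueError("input_resolution must be positive")
    h, w = image.shape[:2]
    scale = input_resolution / max(h, w)
    new_h = int(round(h * scale))
    new_w = int(round(w * scale))
    resized = resize(
        image, (new_h, new_w), preserve_range=True, anti_aliasing=True
    ).astype(image.dtype)
    if image.ndim == 3:
        canvas = np.full(
            (input_resolution, input_resolution, image.shape[2]),
            pad_value, dtype=image.dtype,
        )
    else:
        canvas = np.full(
            (input_resolution, input_resolution), pad_value, dtype=image.dtype
        )
    pad_y = (input_resolution - new_h) // 2
    pad_x = (input_resolution - new_w) // 2
    canvas[pad_y:pad_y + new_h, pad_x:pad_x + new_w] = resized
    transform = LetterboxTransform(
        scale=scale, pad_x=float(pad_x), pad_y=float(pad_y),
        orig_width=w, orig_height=h,
    )
    return canvas, transform
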