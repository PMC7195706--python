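"""Anchor-box derivation by K-means clustering of annotated box shapes.

Anchor boxes are prior (width, height) shapes the detector's output boxes
are parameterized against; deriving them from the training annotations
(classically with K = 9 clusters) lets the decoder start from shapes the
assay actually produces.  The clustering distance is ``1 - IoU`` of
center-aligned boxes, the convention introduced with anchor clustering;
plain Euclidean distance on (w, h) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .annotations import Box

_MAX_ITER = 300


@dataclass(frozen=True)
class AnchorSet:
    """K anchor (width, height) pairs in pixels, sorted by area ascending."""

    shapes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        shapes = tuple(
            (float(w), float(h)) for w, h in self.shapes
        )
        if not shapes:
            raise ValueError("anchor set must not be empty")
        if any(w <= 0 or h <= 0 for w, h in shapes):
            raise ValueError("anchor dimensions must be positive")
        object.__setattr__(
            self, "shapes", tuple(sorted(shapes, key=lambda s: s[0] * s[1]))
        )

    def __len__(self) -> int:
        return len(self.shapes)

    def __iter__(self):
        return iter(self.shapes)


def iou_wh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU of center-aligned boxes given as (..., 2) width/height arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    inter = np.minimum(a[..., 0], b[..., 0]) * np.minimum(a[..., 1], b[..., 1])
    union = a[..., 0] * a[..., 1] + b[..., 0] * b[..., 1] - inter
    return inter / union


def _distances(wh: np.ndarray, reps: np.ndarray, metric: str) -> np.ndarray:
    # (n, K) distance matrix
    if metric == "iou":
        return 1.0 - iou_wh(wh[:, None, :], reps[None, :, :])
    return np.linalg.norm(wh[:, None, :] - reps[None, :, :], axis=-1)


def kmeans_anchors(
    boxes: Sequence[Box] | np.ndarray,
    K: int = 9,
    rng_seed: int = 0,
    metric: Literal["iou", "euclidean"] = "iou",
) -> AnchorSet:
    """Cluster annotated box shapes into K anchor (width, height) pairs.

    Lloyd-style iteration: assign every shape to its nearest representative
    (distance ``1 - IoU`` of center-aligned boxes, or Euclidean), then move
    each representative to its members' mean — keeping the old representative
    whenever the mean would worsen the within-cluster distance, so the
    objective is non-increasing.  An emptied cluster is reseeded with the
    shape farthest from its current representative.  Deterministic for a
    given ``rng_seed``.
    """
    if isinstance(boxes, np.ndarray):
        wh = np.asarray(boxes, dtype=float).reshape(-1, 2)
    else:
        wh = np.array([[b.width, b.height] for b in boxes], dtype=float)
    if wh.size == 0:
        raise ValueError("no boxes supplied")
    distinct = np.unique(wh, axis=0)
    if len(distinct) < K:
        raise ValueError(
            f"need at least K={K} distinct (w, h) shapes, got {len(distinct)}"
        )
    rng = np.random.default_rng(rng_seed)
    # farthest-point initialization: immune to all-seeds-in-one-cluster starts
    chosen = [int(rng.integers(len(distinct)))]
    while len(chosen) < K:
        d_min = _distances(distinct, distinct[chosen], metric).min(axis=1)
        d_min[chosen] = -1.0
        chosen.append(int(d_min.argmax()))
    reps = distinct[chosen].copy()

    def objective(assign: np.ndarray, reps_: np.ndarray) -> float:
        d = _distances(wh, reps_, metric)
        return float(d[np.arange(len(wh)), assign].mean())

    assign = _distances(wh, reps, metric).argmin(axis=1)
    best_obj = objective(assign, reps)
    for _ in range(_MAX_ITER):
        # update step, guarded to never increase the objective
        for k in range(K):
            members = wh[assign == k]
            if len(members) == 0:
                far = _distances(wh, reps, metric)[
                    np.arange(len(wh)), assign
                ].argmax()
                reps[k] = wh[far]
                continue
            candidate = members.mean(axis=0)
            old_cost = _distances(members, reps[k][None, :], metric).sum()
            new_cost = _distances(members, candidate[None, :], metric).sum()
            if new_cost <= old_cost:
                reps[k] = candidate
        new_assign = _distances(wh, reps, metric).argmin(axis=1)
        new_obj = objective(new_assign, reps)
        if new_obj > best_obj + 1e-12:  # reseeding may perturb; keep best state
            break
        best_obj = new_obj
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
    return AnchorSet(shapes=tuple((w, h) for w, h in reps))


def anchor_objective(
    boxes: Sequence[Box] | np.ndarray,
    anchors: AnchorSet,
    metric: Literal["iou", "euclidean"] = "iou",
) -> float:
    """Mean distance from each box shape to its nearest anchor."""
    if isinstance(boxes, np.ndarray):
        wh = np.asarray(boxes, dtype=float).reshape(-1, 2)
    else:
        wh = np.array([[b.width, b.height] for b in boxes], dtype=float)
    reps = np.array(list(anchors), dtype=float)
    return float(_distances(wh, reps, metric).min(axis=1).mean())
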