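"""Translation-only stitching of top/bottom half-filter image pairs.

Each filter is captured as two overlapping shots (the full disc does not fit
the camera's field of view); the full view is recovered by vertically
aligning the pair.  Alignment is a 1-D search over candidate overlaps
scored by normalized cross-correlation of the shared rows, with the overlap
region blended by a linear ramp.  Full perspective mosaicking is out of
scope: captures on this rig differ by translation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class StitchError(RuntimeError):
    """Raised when no overlap correlates reliably."""


@dataclass(frozen=True)
class StitchResult:
    image: np.ndarray
    overlap_px: int
    correlation: float


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-9:
        return 0.0
    return float(np.dot(a, b) / denom)


def stitch_pair(
    top: np.ndarray,
    bottom: np.ndarray,
    max_shift: int = 600,
    min_overlap: int = 10,
    corr_floor: float = 0.5,
    min_new_rows: int = 16,
) -> StitchResult:
    """Merge a top/bottom image pair by maximizing row-overlap correlation.

    Candidate overlaps from ``min_overlap`` to ``max_shift`` rows are scored
    by the normalized cross-correlation between the top image's last rows
    and the bottom image's first rows; the best-scoring overlap wins.
    Overlaps that would contribute fewer than ``min_new_rows`` new rows are
    never considered (the minimum-new-content rule, which rejects the
    degenerate full-overlap solution for near-identical inputs).  A best
    correlation below ``corr_floor`` raises :class:`StitchError` ("no
    reliable overlap").  The merged height is ``top + bottom - overlap``
    rows; shared rows are blended with a linear ramp.
    """
    if top.shape[1:] != bottom.shape[1:]:
        raise ValueError("images must have equal widths (and channels)")
    h_top, h_bot = top.shape[0], bottom.shape[0]
    cap = min(h_top, h_bot) - min_new_rows
    hi = min(max_shift, cap)
    if hi < min_overlap:
        raise StitchError("no admissible overlap window")
    best_o, best_c = None, -np.inf
    for o in range(min_overlap, hi + 1):
        c = _ncc(top[-o:], bottom[:o])
        if c > best_c:
            best_o, best_c = o, c
    if best_o is None or best_c < corr_floor:
        raise StitchError(
            f"no reliable overlap: best correlation {best_c:.3f} "
            f"below floor {corr_floor}"
        )
    # degenerate-pair guard: if the excluded full-overlap alignment beats
    # every admissible one, the two inputs are (near-)identical images
    o_full = min(h_top, h_bot)
    c_full = _ncc(top[-o_full:], bottom[:o_full])
    if c_full >= best_c:
        raise StitchError(
            "only the degenerate full-overlap alignment is reliable; "
            "the images appear to be near-identical rather than a "
            "top/bottom pair"
        )
    o = best_o
    merged = np.empty(
        (h_top + h_bot - o,) + top.shape[1:], dtype=float
    )
    merged[: h_top - o] = top[: h_top - o]
    ramp = np.linspace(0.0, 1.0, o)
    shape = (o,) + (1,) * (top.ndim - 1)
    w = ramp.reshape(shape)
    merged[h_top - o : h_top] = (
        (1.0 - w) * top[-o:].astype(float) + w * bottom[:o].astype(float)
    )
    merged[h_top:] = bottom[o:]
    out = np.clip(np.rint(merged), 0, 255).astype(top.dtype)
    return StitchResult(image=out, overlap_px=o, correlation=best_c)
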