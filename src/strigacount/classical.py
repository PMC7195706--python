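"""Classical reference detector for filter-assay images.

A fully classical backend — background-normalized thresholding,
morphological cleanup, connected components with shape gating — that plays
the detector's role so the whole counting pipeline (threshold sweep, NMS,
counting, evaluation) runs end to end without trained network weights.

Seeds are found as dark compact components on the bright filter disc whose
opened body has plausible elliptical axes and solidity.  A radicle onset is
found as a thin elongated residual that survives subtracting the opened
body from its component and stays attached to it; one onset is emitted per
qualifying seed.  Each detection carries a pseudo-objectness in [0.01, 0.99]
derived from smooth shape-score margins, so objectness-threshold sweeps
behave like they do for a learned detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, opening

from .annotations import Box
from .detect import Detection


@dataclass(frozen=True)
class ClassicalParams:
    """Shape gates, tied to the simulator's default geometry.

    At ~192 px/mm a (< 200 µm) seed body spans roughly 25-38 px on its major
    axis and 14-36 px on its minor axis; gates are kept loose around that.
    ``open_radius`` must exceed half the radicle width (3-6 px) so opening
    strips the radicle from the seed body.
    """

    contrast_offset: float = 45.0     # object = darker than disc median by this
    min_object_area: int = 60         # px; rejects specks before labelling
    open_radius: int = 4
    seed_major_range: tuple[float, float] = (16.0, 52.0)
    seed_minor_range: tuple[float, float] = (8.0, 44.0)
    solidity_floor: float = 0.85
    softness: float = 2.0             # px scale of the score ramps
    radicle_min_area: int = 25        # px of thin residual to call an onset
    radicle_elongation_floor: float = 2.0


def _ramp(x: float, lo: float, hi: float, soft: float) -> float:
    """Smooth membership of x in [lo, hi]: ~1 well inside, ~0 well outside."""
    up = 1.0 / (1.0 + np.exp(-(x - lo) / soft))
    down = 1.0 / (1.0 + np.exp((x - hi) / soft))
    return float(up * down)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def estimate_disc(gray: np.ndarray) -> tuple[np.ndarray, float]:
    """Locate the bright filter disc; returns its filled mask and median level."""
    from skimage.filters import threshold_otsu

    finite = gray[np.isfinite(gray)]
    if finite.size == 0 or np.ptp(finite) < 1e-6:
        return np.zeros_like(gray, dtype=bool), float("nan")
    t = threshold_otsu(gray)
    bright = gray > t
    if not bright.any():
        return np.zeros_like(gray, dtype=bool), float("nan")
    disc = _largest_component(bright)
    disc = ndimage.binary_fill_holes(disc)
    return disc, float(np.median(gray[disc]))


def detect_classical(
    image: np.ndarray, params: ClassicalParams | None = None
) -> list[Detection]:
    """Detect seeds and radicle onsets in an assay image.

    Returns unfiltered detections (objectness over the full [0.01, 0.99]
    range); apply :func:`strigacount.detect.objectness_filter` and
    :func:`strigacount.detect.nms` downstream.
    """
    params = params or ClassicalParams()
    if image.size == 0:
        return []
    gray = image.astype(float)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)

    disc, disc_level = estimate_disc(gray)
    if not disc.any() or not np.isfinite(disc_level):
        return []
    objects = (gray < disc_level - params.contrast_offset) & disc
    # drop specks below a third of the minimum plausible object
    objects = ndimage.binary_opening(objects, structure=np.ones((2, 2)))
    lab = label(objects)

    selem = disk(params.open_radius)
    detections: list[Detection] = []
    for region in regionprops(lab):
        if region.area < params.min_object_area:
            continue
        r0, c0, r1, c1 = region.bbox
        pad = params.open_radius + 2
        rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
        crop = np.zeros(
            (min(r1 + pad, lab.shape[0]) - rr0, min(c1 + pad, lab.shape[1]) - cc0),
            dtype=bool,
        )
        sub = lab[rr0:rr0 + crop.shape[0], cc0:cc0 + crop.shape[1]]
        crop[sub == region.label] = True

        body = opening(crop, selem)
        if not body.any():
            continue
        body = _largest_component(body)
        bprops = regionprops(body.astype(np.uint8))[0]
        major = bprops.axis_major_length
        minor = bprops.axis_minor_length
        score = (
            _ramp(major, *params.seed_major_range, params.softness)
            * _ramp(minor, *params.seed_minor_range, params.softness)
            * (1.0 / (1.0 + np.exp(-(bprops.solidity - params.solidity_floor) / 0.03)))
        )
        seed_obj = float(np.clip(score, 0.01, 0.99))
        br0, bc0, br1, bc1 = bprops.bbox
        seed_box = Box(
            float(cc0 + bc0), float(rr0 + br0),
            float(cc0 + bc1), float(rr0 + br1), "seed",
        )
        detections.append(Detection(
            box=seed_box, objectness=seed_obj,
            class_probs={"seed": seed_obj, "radicle": 0.01},
        ))

        # radicle onset: thin residual attached to the body
        residual = crop & ~dilation(body, disk(1))
        res_lab, n_res = ndimage.label(residual)
        if n_res == 0:
            continue
        attached = dilation(body, disk(3))
        best = None
        for rprop in regionprops(res_lab):
            if rprop.area < params.radicle_min_area:
                continue
            res_mask = res_lab == rprop.label
            if not (res_mask & attached).any():
                continue
            elong = rprop.axis_major_length / max(rprop.axis_minor_length, 1.0)
            if best is None or rprop.area > best[0].area:
                best = (rprop, res_mask, elong)
        if best is None:
            continue
        rprop, res_mask, elong = best
        rad_score = seed_obj * _ramp(
            elong, params.radicle_elongation_floor, 1e9, 0.5
        )
        rad_obj = float(np.clip(rad_score, 0.01, 0.99))
        # junction: residual pixel nearest the seed body
        dist = ndimage.distance_transform_edt(~body)
        res_r, res_c = np.nonzero(res_mask)
        j = np.argmin(dist[res_r, res_c])
        jr, jc = float(rr0 + res_r[j]), float(cc0 + res_c[j])
        half = max(minor / 2.0, 4.0)
        H, W = lab.shape
        rad_box = Box(
            max(0.0, jc - half), max(0.0, jr - half),
            min(float(W), jc + half), min(float(H), jr + half), "radicle",
        )
        detections.append(Detection(
            box=rad_box, objectness=rad_obj,
            class_probs={"seed": 0.01, "radicle": rad_obj},
        ))
    return detections
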