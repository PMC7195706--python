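"""Bounding-box annotation types and format converters.

The counting workflow touches two annotation dialects: LabelImg-style
Pascal-VOC XML (used when hand-annotating filter images) and Darknet-style
normalized text files (used when training the detector).  Both are converted
through one internal convention: 0-based, half-open pixel coordinates
``[x_min, x_max) x [y_min, y_max)`` with continuous values.

Class vocabulary is fixed: ``seed`` (an ungerminated or germinated seed
body), ``radicle`` (the radicle onset of a germinated seed) and
``haustorium`` (reserved for the extended system).  Matching is
case-insensitive on read and lower-case on write.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from lxml import etree

CLASS_NAMES: tuple[str, ...] = ("seed", "radicle", "haustorium")

#: Darknet class indices, in file order.
CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}


class AnnotationError(ValueError):
    """Raised for malformed annotation documents or invalid geometry."""


class GerminationOverflowWarning(UserWarning):
    """More radicle onsets than seeds: germination above 100%.

    The two classes are counted independently, so this can happen; the value
    is reported as computed, not clamped.
    """


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with a class label, in pixel coordinates.

    Coordinates are 0-based and half-open: a box spanning pixel columns
    0..9 inclusive has ``x_min=0, x_max=10``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str

    def __post_init__(self) -> None:
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(c) for c in coords):
            raise AnnotationError(f"box coordinates must be finite, got {coords}")
        if min(coords) < 0:
            raise AnnotationError(f"box coordinates must be >= 0, got {coords}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise AnnotationError(
                f"box must have positive extent: {coords}"
            )
        if self.label not in CLASS_NAMES:
            raise AnnotationError(
                f"unknown class {self.label!r}; accepted names: {', '.join(CLASS_NAMES)}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class ImageAnnotation:
    """All boxes for one image, with the image's pixel dimensions."""

    image_id: str
    width: int
    height: int
    boxes: tuple[Box, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise AnnotationError(
                f"image dimensions must be positive, got {self.width}x{self.height}"
            )
        object.__setattr__(self, "boxes", tuple(self.boxes))
        for i, box in enumerate(self.boxes):
            if box.x_max > self.width or box.y_max > self.height:
                raise AnnotationError(
                    f"box {i} ({box.label}) exceeds image bounds "
                    f"{self.width}x{self.height}: "
                    f"({box.x_min}, {box.y_min}, {box.x_max}, {box.y_max})"
                )

    def count(self, label: str) -> int:
        return sum(1 for b in self.boxes if b.label == label)

    @property
    def n_seeds(self) -> int:
        return self.count("seed")

    @property
    def n_radicles(self) -> int:
        return self.count("radicle")


@dataclass(frozen=True)
class GroundTruthCount:
    """Hand-count record for one filter image: seeds, radicles, germination."""

    sample: str
    n_seeds: int
    n_radicles: int

    def __post_init__(self) -> None:
        if self.n_seeds < 0 or self.n_radicles < 0:
            raise AnnotationError("counts must be non-negative")

    @property
    def germination_pct(self) -> float | None:
        return germination_pct(self.n_seeds, self.n_radicles)


def germination_pct(n_seeds: int, n_radicles: int) -> float | None:
    """Germination percentage, ``100 * n_radicles / n_seeds``.

    Returns ``None`` (serialized as the literal ``NA``) when no seeds were
    counted.  Values above 100 are possible because seed and radicle
    detections are counted independently; they are returned as computed and
    flagged with :class:`GerminationOverflowWarning`.
    """
    if n_seeds < 0 or n_radicles < 0:
        raise ValueError("counts must be non-negative")
    if n_seeds == 0:
        return None
    pct = 100.0 * n_radicles / n_seeds
    if pct > 100.0:
        warnings.warn(
            f"germination {pct:.2f}% exceeds 100% "
            f"({n_radicles} radicles vs {n_seeds} seeds)",
            GerminationOverflowWarning,
            stacklevel=2,
        )
    return pct


def format_pct(value: float | None, decimals: int = 2) -> str:
    """Render a percentage for tabular output; ``None`` becomes ``NA``."""
    if value is None:
        return "NA"
    return f"{value:.{decimals}f}"


# ---------------------------------------------------------------------------
# Pascal-VOC (LabelImg dialect)
# ---------------------------------------------------------------------------

def _require(parent: etree._Element, tag: str) -> etree._Element:
    child = parent.find(tag)
    if child is None:
        raise AnnotationError(f"missing <{tag}> element under <{parent.tag}>")
    return child


def _int_text(elem: etree._Element) -> int:
    try:
        return int(round(float(elem.text)))
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"non-numeric value in <{elem.tag}>: {elem.text!r}") from exc


def parse_voc(source) -> ImageAnnotation:
    """Parse a LabelImg/Pascal-VOC XML document into an :class:`ImageAnnotation`.

    VOC stores 1-based inclusive pixel indices; these are converted to the
    internal 0-based half-open convention (``x_min`` decremented by one,
    ``x_max`` kept).

    ``source`` may be a path, a file object, or an XML string/bytes.
    """
    try:
        if isinstance(source, (str, bytes)) and (
            (isinstance(source, str) and source.lstrip().startswith("<"))
            or (isinstance(source, bytes) and source.lstrip().startswith(b"<"))
        ):
            root = etree.fromstring(
                source.encode() if isinstance(source, str) else source
            )
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise AnnotationError(f"malformed XML: {exc}") from exc

    filename = root.findtext("filename", default="")
    image_id = filename.rsplit(".", 1)[0] if filename else ""
    size = _require(root, "size")
    width = _int_text(_require(size, "width"))
    height = _int_text(_require(size, "height"))

    boxes: list[Box] = []
    for i, obj in enumerate(root.iterfind("object")):
        name = (_require(obj, "name").text or "").strip().lower()
        if name not in CLASS_NAMES:
            raise AnnotationError(
                f"object {i}: unknown class {name!r}; "
                f"accepted names: {', '.join(CLASS_NAMES)}"
            )
        bnd = _require(obj, "bndbox")
        xmin = _int_text(_require(bnd, "xmin"))
        ymin = _int_text(_require(bnd, "ymin"))
        xmax = _int_text(_require(bnd, "xmax"))
        ymax = _int_text(_require(bnd, "ymax"))
        try:
            box = Box(xmin - 1, ymin - 1, xmax, ymax, name)
        except AnnotationError as exc:
            raise AnnotationError(f"object {i}: {exc}") from exc
        if box.x_max > width or box.y_max > height:
            raise AnnotationError(
                f"object {i}: box ({xmin},{ymin},{xmax},{ymax}) "
                f"outside {width}x{height} image"
            )
        boxes.append(box)

    return ImageAnnotation(image_id=image_id, width=width, height=height,
                           boxes=tuple(boxes))


def write_voc(annotation: ImageAnnotation) -> str:
    """Serialize an annotation to LabelImg-style Pascal-VOC XML.

    Inverse of :func:`parse_voc` for integer-coordinate annotations:
    ``parse_voc(write_voc(a)) == a``.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = f"{annotation.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(annotation.width)
    etree.SubElement(size, "height").text = str(annotation.height)
    etree.SubElement(size, "depth").text = "3"
    for box in annotation.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = box.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(box.x_min)) + 1)
        etree.SubElement(bnd, "ymin").text = str(int(round(box.y_min)) + 1)
        etree.SubElement(bnd, "xmax").text = str(int(round(box.x_max)))
        etree.SubElement(bnd, "ymax").text = str(int(round(box.y_max)))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Darknet normalized text
# ---------------------------------------------------------------------------

def parse_darknet_txt(
    lines: str | Iterable[str], width: int, height: int, image_id: str = ""
) -> ImageAnnotation:
    """Parse Darknet-style annotation lines for an image of the given size.

    Each line is ``class_index center_x center_y box_w box_h`` with the four
    geometry values normalized to [0, 1].  Class indices: 0=seed, 1=radicle,
    2=haustorium.
    """
    if isinstance(lines, str):
        lines = lines.splitlines()
    index_to_class = {i: name for name, i in CLASS_INDEX.items()}
    boxes: list[Box] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise AnnotationError(
                f"line {lineno}: expected 5 fields, got {len(parts)}"
            )
        try:
            cls = int(parts[0])
            cx, cy, bw, bh = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: non-numeric field") from exc
        if cls not in index_to_class:
            raise AnnotationError(
                f"line {lineno}: unknown class index {cls}; "
                f"valid indices: {sorted(index_to_class)}"
            )
        for name, v in (("center_x", cx), ("center_y", cy),
                        ("width", bw), ("height", bh)):
            if not 0.0 <= v <= 1.0:
                raise AnnotationError(
                    f"line {lineno}: {name}={v} outside [0, 1]"
                )
        x_min = max(0.0, (cx - bw / 2) * width)
        y_min = max(0.0, (cy - bh / 2) * height)
        x_max = min(float(width), (cx + bw / 2) * width)
        y_max = min(float(height), (cy + bh / 2) * height)
        boxes.append(Box(x_min, y_min, x_max, y_max, index_to_class[cls]))
    return ImageAnnotation(image_id=image_id, width=width, height=height,
                           boxes=tuple(boxes))


def write_darknet_txt(annotation: ImageAnnotation, decimals: int = 6) -> str:
    """Serialize to Darknet-style normalized text, one line per box.

    Round-trip through :func:`parse_darknet_txt` preserves centers and sizes
    to within one pixel (quantization of the printed decimals).
    """
    lines = []
    for box in annotation.boxes:
        cx, cy = box.center
        lines.append(
            f"{CLASS_INDEX[box.label]} "
            f"{cx / annotation.width:.{decimals}f} "
            f"{cy / annotation.height:.{decimals}f} "
            f"{box.width / annotation.width:.{decimals}f} "
            f"{box.height / annotation.height:.{decimals}f}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def clip_box(box: Box, width: float, height: float) -> Box:
    """Clip a box to image bounds (used when rendering overlays)."""
    return replace(
        box,
        x_min=min(max(box.x_min, 0.0), width - 1),
        y_min=min(max(box.y_min, 0.0), height - 1),
        x_max=max(min(box.x_max, float(width)), 1.0),
        y_max=max(min(box.y_max, float(height)), 1.0),
    )


def read_ground_truth_table(path) -> list[GroundTruthCount]:
    """Read a hand-count table (CSV with sample, seeds, radicles columns)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    sample_col = cols.get("sample")
    seed_col = cols.get("total_seeds") or cols.get("n_seeds") or cols.get("seeds")
    rad_col = (cols.get("germinated_seeds") or cols.get("n_radicles")
               or cols.get("radicles"))
    if not (sample_col and seed_col and rad_col):
        raise AnnotationError(
            "hand-count table needs sample, seeds and radicles columns; "
            f"got {list(df.columns)}"
        )
    return [
        GroundTruthCount(str(r[sample_col]), int(r[seed_col]), int(r[rad_col]))
        for _, r in df.iterrows()
    ]
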