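"""Domain types and I/O for crowd annotation records, expert ground truth, and masks.

Coordinate convention: pixel coordinates are 0-based with x increasing rightwards
and y downwards.  A :class:`Rectangle` is half-open, ``[x0, x1) x [y0, y1)``, so
its pixel area is exactly ``(x1 - x0) * (y1 - y0)``.  Rectangles that overshoot
the image bounds are clipped on ingest rather than rejected, since click-drag
input routinely overshoots; zero-area rectangles are kept but flagged degenerate.

File formats are plain tab-separated text.  An annotations file has columns
``image_id, annotator_id, group, label, rectangles``; a truth file has columns
``image_id, width, height, true_label, rectangles``.  The ``rectangles`` column
serializes zero or more rectangles as a semicolon-separated list of
``x0,y0,x1,y1`` quadruples.  Masks are exported as single-channel PNG with 0 for
background and 255 for lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image

GROUPS = ("nonmasters", "masters", "nonmasters_trained")
LABELS = ("healthy", "nonhealthy")
TRUE_LABELS = ("normal", "mild", "severe")

ANNOTATION_COLUMNS = ["image_id", "annotator_id", "group", "label", "rectangles"]
TRUTH_COLUMNS = ["image_id", "width", "height", "true_label", "rectangles"]


class ValidationError(ValueError):
    """A record violates the file schema or a domain invariant."""


@dataclass(frozen=True, order=True)
class Rectangle:
    """Axis-aligned half-open pixel rectangle ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 < self.x0 or self.y1 < self.y0:
            raise ValidationError(
                f"inverted rectangle ({self.x0},{self.y0},{self.x1},{self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def is_degenerate(self) -> bool:
        return self.area == 0

    def clipped(self, width: int, height: int) -> "Rectangle":
        """Clip to the image bounds ``[0, width) x [0, height)``."""
        x0 = min(max(self.x0, 0), width)
        x1 = min(max(self.x1, 0), width)
        y0 = min(max(self.y0, 0), height)
        y1 = min(max(self.y1, 0), height)
        return Rectangle(x0, y0, x1, y1)

    def serialize(self) -> str:
        return f"{self.x0},{self.y0},{self.x1},{self.y1}"

    @classmethod
    def parse(cls, text: str) -> "Rectangle":
        parts = text.split(",")
        if len(parts) != 4:
            raise ValidationError(f"rectangle needs 4 coordinates, got {text!r}")
        try:
            x0, y0, x1, y1 = (int(p) for p in parts)
        except ValueError as exc:
            raise ValidationError(f"non-integer rectangle coordinate in {text!r}") from exc
        return cls(x0, y0, x1, y1)


def serialize_rectangles(rects: tuple[Rectangle, ...] | list[Rectangle]) -> str:
    return ";".join(r.serialize() for r in rects)


def parse_rectangles(text: str) -> tuple[Rectangle, ...]:
    text = text.strip()
    if not text:
        return ()
    return tuple(Rectangle.parse(part) for part in text.split(";"))


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotator's response to one image: a class label plus rectangles.

    ``label == "healthy"`` may still carry rectangles (the capture UI is not
    assumed to forbid it); the classification arm ignores them.
    """

    image_id: str
    annotator_id: str
    group: str
    label: str
    rectangles: tuple[Rectangle, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}; expected one of {LABELS}")
        object.__setattr__(self, "rectangles", tuple(self.rectangles))


@dataclass(frozen=True)
class ImageTruth:
    """Expert ground truth for one image.

    ``true_label == "normal"`` implies no expert rectangles; an abnormal image
    carries at least one non-degenerate rectangle.
    """

    image_id: str
    width: int
    height: int
    true_label: str
    expert_rectangles: tuple[Rectangle, ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"image {self.image_id!r}: non-positive dimensions {self.width}x{self.height}"
            )
        if self.true_label not in TRUE_LABELS:
            raise ValidationError(
                f"unknown true_label {self.true_label!r}; expected one of {TRUE_LABELS}"
            )
        rects = tuple(r.clipped(self.width, self.height) for r in self.expert_rectangles)
        object.__setattr__(self, "expert_rectangles", rects)
        if self.true_label == "normal" and rects:
            raise ValidationError(f"normal image {self.image_id!r} carries expert rectangles")
        if self.true_label != "normal" and not any(not r.is_degenerate for r in rects):
            raise ValidationError(
                f"abnormal image {self.image_id!r} needs at least one non-degenerate rectangle"
            )

    @property
    def is_healthy(self) -> bool:
        return self.true_label == "normal"


@dataclass
class BinaryMask:
    """A 2-D boolean pixel grid, stored row-major (``pixels[y, x]``)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask pixels must be a 2-D grid")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def positive_count(self) -> int:
        return int(self.pixels.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            np.array_equal(self.pixels, other.pixels)
        )


@dataclass
class AverageMask:
    """Per-pixel crowd vote fractions: value = (votes at pixel) / n_annotators.

    Internally stores the integer vote counts so every value is an exact
    ``k / n_annotators``.
    """

    counts: np.ndarray
    n_annotators: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValidationError("vote counts must be a 2-D grid")
        if self.n_annotators < 1:
            raise ValidationError("average mask needs at least one annotator")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_annotators:
            raise ValidationError("vote counts outside [0, n_annotators]")

    @property
    def height(self) -> int:
        return self.counts.shape[0]

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.counts / self.n_annotators


# ---------------------------------------------------------------------------
# rasterization


def rasterize(rect: Rectangle, width: int, height: int) -> BinaryMask:
    """Rasterize one rectangle to a binary mask.

    Pixel ``(x, y)`` is positive iff ``x0 <= x < x1`` and ``y0 <= y < y1``;
    the positive count equals the clipped rectangle area.
    """
    if width <= 0 or height <= 0:
        raise ValidationError(f"non-positive image dimensions {width}x{height}")
    r = rect.clipped(width, height)
    pixels = np.zeros((height, width), dtype=bool)
    pixels[r.y0 : r.y1, r.x0 : r.x1] = True
    return BinaryMask(pixels)


def union_mask(rects: tuple[Rectangle, ...] | list[Rectangle], width: int, height: int) -> BinaryMask:
    """Pixelwise OR of the rasterized rectangles (empty mask for no rectangles)."""
    if width <= 0 or height <= 0:
        raise ValidationError(f"non-positive image dimensions {width}x{height}")
    pixels = np.zeros((height, width), dtype=bool)
    for rect in rects:
        r = rect.clipped(width, height)
        pixels[r.y0 : r.y1, r.x0 : r.x1] = True
    return BinaryMask(pixels)


def annotator_mask(record: AnnotationRecord, truth: ImageTruth) -> BinaryMask:
    """Union of one annotator's rectangles on the image's pixel grid."""
    if record.image_id != truth.image_id:
        raise ValidationError(
            f"record image {record.image_id!r} does not match truth image {truth.image_id!r}"
        )
    return union_mask(record.rectangles, truth.width, truth.height)


def expert_mask(truth: ImageTruth) -> BinaryMask:
    """Union of the expert's lesion rectangles (empty for a normal image)."""
    return union_mask(truth.expert_rectangles, truth.width, truth.height)


# ---------------------------------------------------------------------------
# file I/O


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_annotations(path) -> list[AnnotationRecord]:
    """Read an annotations table; validates every row and preserves row order.

    Raises :class:`ValidationError` naming the offending row for unknown labels
    or groups, inverted rectangles, or duplicate ``(image_id, annotator_id)``.
    """
    df = _read_table(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            record = AnnotationRecord(
                image_id=row.image_id,
                annotator_id=row.annotator_id,
                group=row.group,
                label=row.label,
                rectangles=parse_rectangles(row.rectangles),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i + 1}: {exc}") from exc
        key = (record.image_id, record.annotator_id)
        if key in seen:
            raise ValidationError(
                f"{path}, row {i + 1}: duplicate response {key} (one response per annotator per image)"
            )
        seen.add(key)
        records.append(record)
    return records


def write_annotations(records: list[AnnotationRecord], path) -> None:
    df = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "annotator_id": [r.annotator_id for r in records],
            "group": [r.group for r in records],
            "label": [r.label for r in records],
            "rectangles": [serialize_rectangles(r.rectangles) for r in records],
        },
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_truths(path) -> list[ImageTruth]:
    """Read a ground-truth table; rectangles are clipped to the stated dimensions."""
    df = _read_table(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    truths: list[ImageTruth] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            truth = ImageTruth(
                image_id=row.image_id,
                width=int(row.width),
                height=int(row.height),
                true_label=row.true_label,
                expert_rectangles=parse_rectangles(row.rectangles),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {i + 1}: {exc}") from exc
        if truth.image_id in seen:
            raise ValidationError(f"{path}, row {i + 1}: duplicate image {truth.image_id!r}")
        seen.add(truth.image_id)
        truths.append(truth)
    return truths


def write_truths(truths: list[ImageTruth], path) -> None:
    df = pd.DataFrame(
        {
            "image_id": [t.image_id for t in truths],
            "width": [t.width for t in truths],
            "height": [t.height for t in truths],
            "true_label": [t.true_label for t in truths],
            "rectangles": [serialize_rectangles(t.expert_rectangles) for t in truths],
        },
        columns=TRUTH_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_mask_image(mask: BinaryMask, path) -> None:
    """Export a mask as single-channel PNG (0 = background, 255 = lesion)."""
    img = Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L")
    img.save(path, format="PNG")


def read_mask_image(path) -> BinaryMask:
    img = Image.open(path).convert("L")
    return BinaryMask(np.asarray(img) >= 128)


def write_report_table(rows: pd.DataFrame, path) -> None:
    """Write a results table as tab-separated text with a header row."""
    rows.to_csv(path, sep="\t", index=False)
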