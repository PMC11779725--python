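"""Readers/writers and calibration for every format the pipeline touches.

Images are grayscale 8-bit arrays wrapped in :class:`CalibratedImage`,
which carries the physical size of the field of view so that densities
and areas come out in mm^-2 and um^2 regardless of pixel resolution.
Detector boxes travel as normalized YOLO-style text, segmentation labels
as labelme-style polygon JSON, masks as 0/255 PNG, and trait tables as
CSV with a fixed column schema.

Conventions: pixel coordinates are 0-based; bounding boxes are half-open
on their upper edges, so the pixel area of a box is (x1-x0)*(y1-y0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "MAGNIFICATION_FIELDS",
    "CalibratedImage",
    "BoundingBox",
    "TraitTable",
    "TRAIT_COLUMNS",
    "GROUP_COLUMNS",
    "POLYGON_LABELS",
    "read_image",
    "write_image",
    "resize_image",
    "read_mask",
    "write_mask",
    "parse_yolo_boxes",
    "format_yolo_boxes",
    "read_yolo_boxes",
    "write_yolo_boxes",
    "parse_polygons",
    "format_polygons",
    "polygons_to_masks",
    "read_trait_csv",
    "write_trait_csv",
]

#: Physical field edge length (um) of a full frame at each calibrated
#: magnification of the rapid scanning electron microscope.  At the native
#: 1024 px frame these give 767/1024 ~ 0.749 um/px (350x) and
#: 298/1024 ~ 0.291 um/px (900x).
MAGNIFICATION_FIELDS: dict[str, float] = {"350x": 767.0, "900x": 298.0}

#: Semantic labels accepted in polygon annotation files.
POLYGON_LABELS = ("stomatal_complex", "guard_cell_and_pore")

#: The 11 trait columns of a trait table, in canonical order.
TRAIT_COLUMNS = ["SD", "SW", "SL", "SA", "SP", "GCPA", "SCA", "SR", "SE", "PGCPA", "PSCA"]

#: Grouping metadata columns.
GROUP_COLUMNS = ["cultivar", "sampling_day", "layer", "replicate", "field_of_view"]


@dataclass(frozen=True)
class CalibratedImage:
    """A grayscale pixel grid plus its physical calibration.

    Parameters
    ----------
    pixels
        2-D uint8 array of intensities.
    um_per_px
        Physical edge length of one pixel in micrometres.
    field_width_um, field_height_um
        Physical size of the imaged field of view.
    magnification_tag
        One of ``"350x"``, ``"900x"`` or ``"other"``; informational.
    """

    pixels: np.ndarray
    um_per_px: float
    field_width_um: float
    field_height_um: float
    magnification_tag: str = "other"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale image, got shape {px.shape}")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        h, w = px.shape
        for n, length, name in ((w, self.field_width_um, "width"), (h, self.field_height_um, "height")):
            if length <= 0:
                raise ValueError(f"field_{name}_um must be positive")
            if abs(self.um_per_px * n - length) > 0.005 * length:
                raise ValueError(
                    f"calibration inconsistent: {n} px x {self.um_per_px:.5f} um/px "
                    f"!= field {name} {length} um (0.5% tolerance)"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_area_mm2(self) -> float:
        """Physical field area in mm^2 (invariant under resizing)."""
        return self.field_width_um * self.field_height_um * 1e-6


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, 0-based, half-open on x1/y1."""

    x0: int
    y0: int
    x1: int
    y1: int
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate box: [{self.x0},{self.x1})x[{self.y0},{self.y1})")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))


class TraitTable:
    """Rows of per-stoma trait records with grouping metadata.

    Wraps a :class:`pandas.DataFrame` that must contain all 11 trait
    columns (``SD`` may be NaN on per-stoma rows; it attaches at the
    field-of-view level).  Grouping columns are optional but preserved.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing mandatory column(s): {', '.join(missing)}")
        order = [c for c in GROUP_COLUMNS if c in df.columns] + TRAIT_COLUMNS
        extra = [c for c in df.columns if c not in order]
        self.df = df[order + extra].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def traits(self) -> pd.DataFrame:
        """The numeric trait columns only."""
        return self.df[TRAIT_COLUMNS]


# ---------------------------------------------------------------------------
# images and masks


def _resolve_scale(n_px: int, magnification_tag: str | None, um_per_px: float | None) -> tuple[float, str]:
    if um_per_px is not None:
        return float(um_per_px), magnification_tag or "other"
    if magnification_tag in MAGNIFICATION_FIELDS:
        return MAGNIFICATION_FIELDS[magnification_tag] / n_px, magnification_tag
    raise ValueError(
        f"unknown magnification {magnification_tag!r} and no explicit um_per_px; "
        f"known tags: {sorted(MAGNIFICATION_FIELDS)}"
    )


def read_image(
    path: str | Path,
    magnification_tag: str | None = None,
    um_per_px: float | None = None,
) -> CalibratedImage:
    """Load a PNG/TIFF micrograph as a calibrated 8-bit grayscale image.

    RGB inputs are collapsed to luminance.  The pixel scale comes from
    the magnification table (field edge / pixel count) unless an
    explicit ``um_per_px`` override is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with Image.open(path) as im:
        px = np.asarray(im.convert("L"), dtype=np.uint8)
    h, w = px.shape
    scale, tag = _resolve_scale(w, magnification_tag, um_per_px)
    return CalibratedImage(px, scale, scale * w, scale * h, tag)


def write_image(img: CalibratedImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF."""
    px = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
    Image.fromarray(px.astype(np.uint8)).save(Path(path))


def resize_image(img: CalibratedImage, side: int, *, nearest: bool = False) -> CalibratedImage:
    """Resample to ``side x side`` pixels, conserving the physical field.

    Intensity images use bilinear interpolation; pass ``nearest=True``
    for masks so the output remains strictly 2-valued.  ``um_per_px`` is
    rescaled so that field length is unchanged.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    h, w = img.pixels.shape
    if (h, w) == (side, side):
        return img
    order = 0 if nearest else 1
    out = _sk_resize(
        img.pixels.astype(float), (side, side), order=order, anti_aliasing=False, preserve_range=True
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return replace(img, pixels=out, um_per_px=img.field_width_um / side)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG mask; any nonzero pixel counts as foreground."""
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("L")) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a 0/255 8-bit PNG."""
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(Path(path))


# ---------------------------------------------------------------------------
# YOLO-format boxes


def parse_yolo_boxes(text: str, image_w: int, image_h: int) -> list[BoundingBox]:
    """Parse normalized ``class cx cy w h [conf]`` lines into pixel boxes.

    Boxes are converted with ``x0 = round((cx - w/2) * W)`` and are
    half-open on the upper edges.  Out-of-range or degenerate lines are
    rejected with the line number in the message.
    """
    boxes: list[BoundingBox] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"line {lineno}: expected 5 or 6 fields, got {len(parts)}: {line!r}")
        try:
            vals = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field in {line!r}") from exc
        cx, cy, w, h = vals[:4]
        conf = vals[4] if len(vals) == 5 else None
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"line {lineno}: {name}={v} outside [0, 1]")
        if w <= 0 or h <= 0:
            raise ValueError(f"line {lineno}: degenerate box (w={w}, h={h})")
        x0 = int(round((cx - w / 2) * image_w))
        x1 = int(round((cx + w / 2) * image_w))
        y0 = int(round((cy - h / 2) * image_h))
        y1 = int(round((cy + h / 2) * image_h))
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"line {lineno}: box collapses to zero pixels at this resolution")
        boxes.append(BoundingBox(x0, y0, x1, y1, conf))
    return boxes


def format_yolo_boxes(boxes: Iterable[BoundingBox], image_w: int, image_h: int) -> str:
    """Inverse of :func:`parse_yolo_boxes` (round-trips within 1 px)."""
    lines = []
    for b in boxes:
        cx = (b.x0 + b.x1) / 2 / image_w
        cy = (b.y0 + b.y1) / 2 / image_h
        w = (b.x1 - b.x0) / image_w
        h = (b.y1 - b.y0) / image_h
        fields = f"0 {cx:.9f} {cy:.9f} {w:.9f} {h:.9f}"
        if b.confidence is not None:
            fields += f" {b.confidence:.6f}"
        lines.append(fields)
    return "\n".join(lines) + ("\n" if lines else "")


def read_yolo_boxes(path: str | Path, image_w: int, image_h: int) -> list[BoundingBox]:
    return parse_yolo_boxes(Path(path).read_text(), image_w, image_h)


def write_yolo_boxes(boxes: Iterable[BoundingBox], path: str | Path, image_w: int, image_h: int) -> None:
    Path(path).write_text(format_yolo_boxes(boxes, image_w, image_h))


# ---------------------------------------------------------------------------
# labelme-style polygons


@dataclass(frozen=True)
class LabeledPolygon:
    """One labeled polygon: ``label`` plus (x, y) vertices in pixel units."""

    label: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.label not in POLYGON_LABELS:
            raise ValueError(f"unknown polygon label {self.label!r}; accepted: {', '.join(POLYGON_LABELS)}")
        if len(self.points) < 3:
            raise ValueError(f"polygon needs >= 3 vertices, got {len(self.points)}")


def parse_polygons(doc: str | dict) -> list[LabeledPolygon]:
    """Parse a labelme-style JSON document into labeled polygons."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    polys = []
    for shape in doc.get("shapes", []):
        pts = tuple((float(x), float(y)) for x, y in shape["points"])
        polys.append(LabeledPolygon(shape["label"], pts))
    return polys


def format_polygons(polygons: Sequence[LabeledPolygon], image_w: int, image_h: int) -> str:
    """Serialize polygons to a labelme-style JSON document string."""
    doc = {
        "version": "5.0.0",
        "shapes": [
            {"label": p.label, "points": [[x, y] for x, y in p.points], "shape_type": "polygon"}
            for p in polygons
        ],
        "imageWidth": image_w,
        "imageHeight": image_h,
    }
    return json.dumps(doc, indent=1)


def _rasterize_even_odd(points: Sequence[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    """Even-odd (ray crossing) polygon fill over pixel centers.

    A pixel (row i, col j) is foreground iff its center (j+0.5, i+0.5)
    lies inside the polygon under the even-odd rule.
    """
    h, w = shape
    pts = np.asarray(points, float)
    xmin = max(int(np.floor(pts[:, 0].min() - 1)), 0)
    xmax = min(int(np.ceil(pts[:, 0].max() + 1)), w)
    ymin = max(int(np.floor(pts[:, 1].min() - 1)), 0)
    ymax = min(int(np.ceil(pts[:, 1].max() + 1)), h)
    out = np.zeros(shape, bool)
    if xmax <= xmin or ymax <= ymin:
        return out
    cx = np.arange(xmin, xmax) + 0.5
    cy = np.arange(ymin, ymax) + 0.5
    X, Y = np.meshgrid(cx, cy)
    inside = np.zeros(X.shape, bool)
    x0, y0 = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        if ay == by:
            continue  # horizontal edge never crosses a horizontal ray properly
        cond = (ay > Y) != (by > Y)
        with np.errstate(invalid="ignore"):
            xint = ax + (Y - ay) * (bx - ax) / (by - ay)
        inside ^= cond & (X < xint)
    out[ymin:ymax, xmin:xmax] = inside
    return out


def polygons_to_masks(
    polygons: Sequence[LabeledPolygon], image_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize labeled polygons into (complex_mask, gcp_mask).

    Interiors are filled under the even-odd rule; guard-cell-and-pore
    pixels falling outside any complex polygon are kept as-is (the mask
    fusion stage reconciles them).
    """
    complex_mask = np.zeros(image_shape, bool)
    gcp_mask = np.zeros(image_shape, bool)
    for p in polygons:
        filled = _rasterize_even_odd(p.points, image_shape)
        if p.label == "stomatal_complex":
            complex_mask |= filled
        else:
            gcp_mask |= filled
    return complex_mask, gcp_mask


# ---------------------------------------------------------------------------
# trait CSV


def read_trait_csv(path: str | Path) -> TraitTable:
    """Read a trait CSV, checking that every mandatory trait column exists."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    return TraitTable(df)


def write_trait_csv(table: TraitTable, path: str | Path) -> None:
    """Write a trait table losslessly (full float precision, stable order)."""
    table.df.to_csv(Path(path), index=False, float_format="%.17g")
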