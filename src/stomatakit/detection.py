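"""Stomatal counting: bounding boxes and density per field of view.

A learned detector is not reproducible from published hyperparameters
alone, so the counting stage is defined as a protocol — any callable
mapping a :class:`~stomatakit.io.CalibratedImage` to scored boxes — and
this module ships a deterministic classical reference implementation
(thresholding, morphological closing, connected components, area
filter) that is exact on imagery following the synthetic generator's
intensity contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

from scipy import ndimage

from .io import BoundingBox, CalibratedImage

__all__ = ["DetectionResult", "Detector", "reference_detect", "stomatal_density"]


@dataclass(frozen=True)
class DetectionResult:
    """Scored stomatal boxes for one image."""

    boxes: list[BoundingBox]
    source_image: str = ""

    @property
    def count(self) -> int:
        return len(self.boxes)


class Detector(Protocol):
    """Contract for a pluggable detector: image in, scored boxes out."""

    def __call__(self, img: CalibratedImage) -> DetectionResult: ...


def reference_detect(
    img: CalibratedImage,
    intensity_threshold: float = 160.0,
    min_area_um2: float = 1000.0,
    max_area_um2: float = 20000.0,
    closing_radius: int = 1,
) -> DetectionResult:
    """Detect stomatal complexes as dark blobs on a bright background.

    Pixels darker than ``intensity_threshold`` are closed morphologically,
    hole-filled, labelled (8-connectivity) and filtered to physical areas
    within ``[min_area_um2, max_area_um2]``; each surviving component
    yields a tight bounding box with confidence 1.0.  Deterministic.
    """
    dark = img.pixels < intensity_threshold
    if closing_radius > 0:
        st = ndimage.generate_binary_structure(2, 2)
        dark = ndimage.binary_closing(dark, structure=st, iterations=closing_radius)
    dark = ndimage.binary_fill_holes(dark)
    labels, n = ndimage.label(dark, structure=ndimage.generate_binary_structure(2, 2))
    s2 = img.um_per_px ** 2
    boxes: list[BoundingBox] = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        region = labels[sl] > 0
        area_um2 = region.sum() * s2
        if min_area_um2 <= area_um2 <= max_area_um2:
            y, x = sl
            boxes.append(BoundingBox(x.start, y.start, x.stop, y.stop, confidence=1.0))
    return DetectionResult(boxes)


def stomatal_density(count: int, img: CalibratedImage) -> float:
    """Stomatal density SD: stomata per mm^2 of the calibrated field.

    SD = count / (field width (um) x field height (um) x 1e-6), so the
    value is invariant to resizing (physical field area is conserved).
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    area = img.field_area_mm2
    if area <= 0:
        raise ValueError("field area must be positive")
    return count / area
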