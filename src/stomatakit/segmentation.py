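"""Semantic masks, mask fusion, and connectivity-based instance extraction.

The pipeline uses two semantic masks per field of view — the intact
stomatal complex and the guard-cell-and-pore (GCP) region — which are
fused by pixelwise union into a refined stomatal-structure mask.
Individual stomata are then extracted as 8-connected components of the
fused mask, each carrying its GCP pixel subset.

As with detection, the learned segmenter is abstracted behind a
protocol; the classical reference implementation classifies pixels into
non-overlapping intensity bands (the synthetic generator's contract)
followed by morphological hole-filling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import ndimage

from .io import BoundingBox, CalibratedImage
from .synthetic import SceneParams

__all__ = ["MaskPair", "StomaInstance", "Segmenter", "bands_from_levels", "reference_segment",
           "fuse_masks", "label_stomata"]

_STRUCT8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class MaskPair:
    """The two semantic masks of one image, with their pixel scale."""

    complex_mask: np.ndarray
    gcp_mask: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        if self.complex_mask.shape != self.gcp_mask.shape:
            raise ValueError(
                f"mask shapes differ: {self.complex_mask.shape} vs {self.gcp_mask.shape}"
            )


@dataclass(frozen=True)
class StomaInstance:
    """One connected stomatal complex extracted from the fused mask.

    ``mask`` and ``gcp`` are local boolean grids over the instance's
    bounding box; ``gcp`` is always a pixel subset of ``mask``.
    """

    label: int
    bbox: BoundingBox
    mask: np.ndarray
    gcp: np.ndarray
    border_touching: bool

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def gcp_area_px(self) -> int:
        return int(self.gcp.sum())


class Segmenter(Protocol):
    """Contract for a pluggable segmenter: image in, mask pair out."""

    def __call__(self, img: CalibratedImage) -> MaskPair: ...


def bands_from_levels(levels: tuple[int, int, int] | SceneParams) -> dict[str, tuple[float, float]]:
    """Half-open intensity bands [lo, hi) from (background, subsidiary, gcp)
    gray levels, with boundaries at the midpoints between adjacent levels."""
    if isinstance(levels, SceneParams):
        levels = levels.intensity_levels
    bg, sub, gcp = levels
    if not (gcp < sub < bg):
        raise ValueError("expected gcp < subsidiary < background gray levels")
    lo_mid = (gcp + sub) / 2
    hi_mid = (sub + bg) / 2
    return {"gcp": (0.0, lo_mid), "subsidiary": (lo_mid, hi_mid), "background": (hi_mid, 256.0)}


def reference_segment(
    img: CalibratedImage,
    level_bands: dict[str, tuple[float, float]] | None = None,
) -> MaskPair:
    """Segment by intensity banding followed by morphological hole-filling.

    ``complex_mask`` collects pixels in the subsidiary or GCP bands;
    ``gcp_mask`` the GCP band only.  Bands must not overlap.  With the
    generator's default gray levels the default bands apply.
    """
    bands = level_bands if level_bands is not None else bands_from_levels((200, 120, 40))
    for k in ("gcp", "subsidiary"):
        if k not in bands:
            raise ValueError(f"level_bands must define a {k!r} band")
    items = sorted(bands.items(), key=lambda kv: kv[1][0])
    for (la, (a0, a1)), (lb, (b0, b1)) in zip(items, items[1:]):
        if a1 > b0:
            raise ValueError(f"overlapping intensity bands: {la} {a0, a1} and {lb} {b0, b1}")
    px = img.pixels.astype(float)
    g0, g1 = bands["gcp"]
    s0, s1 = bands["subsidiary"]
    gcp = (px >= g0) & (px < g1)
    sub = (px >= s0) & (px < s1)
    complex_mask = ndimage.binary_fill_holes(gcp | sub)
    gcp_mask = ndimage.binary_fill_holes(gcp)
    return MaskPair(complex_mask, gcp_mask, img.um_per_px)


def fuse_masks(pair: MaskPair) -> np.ndarray:
    """Fuse the two semantic masks into the refined structure mask.

    The two binary masks are combined by pixelwise union (the idempotent
    reading of summing binary masks), so no foreground pixel of either
    input is ever lost and GCP pixels that leaked outside the complex
    mask are reclaimed into the structure.
    """
    return pair.complex_mask | pair.gcp_mask


def label_stomata(
    fused: np.ndarray,
    gcp_mask: np.ndarray,
    border_policy: str = "drop_for_traits",
    min_area_px: int = 0,
) -> list[StomaInstance]:
    """Extract per-stoma instances as 8-connected components of ``fused``.

    Each instance carries the intersection of its pixel set with
    ``gcp_mask``.  ``border_touching`` is set when any pixel lies on the
    frame edge; under ``border_policy="drop_for_traits"`` such instances
    are flagged for exclusion from size/shape traits downstream (their
    geometry is truncated by the frame), under ``"keep"`` they are
    treated like any other.  Components below ``min_area_px`` pixels are
    discarded as noise specks.
    """
    if border_policy not in ("keep", "drop_for_traits"):
        raise ValueError(f"unknown border_policy {border_policy!r}")
    if fused.shape != gcp_mask.shape:
        raise ValueError(f"mask shapes differ: {fused.shape} vs {gcp_mask.shape}")
    fused = np.asarray(fused, bool)
    gcp_mask = np.asarray(gcp_mask, bool)
    labels, n = ndimage.label(fused, structure=_STRUCT8)
    h, w = fused.shape
    out: list[StomaInstance] = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        local = labels[sl] == lab
        if local.sum() < min_area_px:
            continue
        y, x = sl
        border = y.start == 0 or x.start == 0 or y.stop == h or x.stop == w
        out.append(
            StomaInstance(
                label=lab,
                bbox=BoundingBox(x.start, y.start, x.stop, y.stop),
                mask=local,
                gcp=local & gcp_mask[sl],
                border_touching=border,
            )
        )
    return out
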