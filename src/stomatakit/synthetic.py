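"""Synthetic maize-epidermis micrographs with exact analytic ground truth.

The abaxial epidermis of maize carries stomata in parallel longitudinal
files.  Each stoma is modelled as an elliptical stomatal complex whose
centre holds the guard-cell-and-pore (GCP) region — drawn here as a
concentric, co-oriented ellipse scaled to a requested area fraction —
with the flanking remainder standing for the subsidiary cells.  Three
distinct gray levels (background, subsidiary, GCP) plus clipped additive
Gaussian noise give the reference detector and segmenter a well-defined
intensity contract, while the generative ellipse parameters provide
closed-form per-stoma traits to validate the measurement chain against.

Trait symbols follow the field's conventions: SA stomatal area, SL/SW
length/width, SP perimeter, GCPA/SCA guard-cell-and-pore / subsidiary
cell areas, SR roundness 4*pi*SA/SP^2, SE eccentricity sqrt(1-(b/a)^2),
PGCPA/PSCA the area fractions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy.special import ellipe

from .io import (
    BoundingBox,
    CalibratedImage,
    LabeledPolygon,
    TraitTable,
    format_polygons,
    format_yolo_boxes,
    write_image,
    write_mask,
    write_trait_csv,
)

__all__ = ["SceneParams", "SyntheticScene", "generate_scene", "scene_to_annotations", "write_scene",
           "load_scene_config", "save_scene_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SceneParams:
    """Generative parameters of one synthetic field of view.

    Defaults emulate a full 350x frame (767 um x 767 um at 1024 px) of
    maize abaxial epidermis with realistic trait ranges: stomatal length
    ~ 85-105 um, width ~ 52-59 um, density ~ 70-95 mm^-2 and a GCP area
    fraction around one half.
    """

    field_width_um: float = 767.0
    field_height_um: float = 767.0
    pixels_per_side: int = 1024
    target_density: float = 80.0          #: stomata per mm^2
    length_dist: tuple[float, float] = (95.0, 5.0)   #: (mean, sd) um
    width_dist: tuple[float, float] = (55.5, 1.8)    #: (mean, sd) um
    gcp_fraction_dist: tuple[float, float] = (0.50, 0.025)  #: GCPA/SA (mean, sd)
    orientation_jitter_deg: float = 6.0
    row_spacing_um: float = 90.0
    intensity_levels: tuple[int, int, int] = (200, 120, 40)  #: background, subsidiary, gcp
    noise_sd: float = 4.0                 #: gray levels
    seed: int = 0
    allow_border_clipped: bool = False    #: place stomata across the frame edge

    def __post_init__(self) -> None:
        if min(self.field_width_um, self.field_height_um) <= 0:
            raise ValueError("field dimensions must be positive")
        if self.pixels_per_side < 1:
            raise ValueError("pixels_per_side must be a positive integer")
        if self.target_density < 0:
            raise ValueError("target_density must be nonnegative")
        if self.length_dist[0] <= self.width_dist[0]:
            raise ValueError("mean stomatal length must exceed mean width")
        if not (0.0 < self.gcp_fraction_dist[0] < 1.0):
            raise ValueError("mean GCP area fraction must lie in (0, 1)")
        if self.orientation_jitter_deg < 0 or self.noise_sd < 0:
            raise ValueError("orientation jitter and noise sd must be nonnegative")
        if self.row_spacing_um <= 0:
            raise ValueError("row_spacing_um must be positive")
        lv = self.intensity_levels
        if not all(0 <= v <= 255 for v in lv):
            raise ValueError("intensity levels must lie in [0, 255]")
        if min(abs(a - b) for i, a in enumerate(lv) for b in lv[i + 1:]) < 20:
            raise ValueError("intensity levels must be pairwise >= 20 gray levels apart")

    @property
    def um_per_px(self) -> float:
        return self.field_width_um / self.pixels_per_side

    @property
    def field_area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um * 1e-6


@dataclass(frozen=True)
class SyntheticScene:
    """A generated field of view with its exact ground truth."""

    image: CalibratedImage
    complex_mask: np.ndarray
    gcp_mask: np.ndarray
    boxes: list[BoundingBox]
    truth_traits: TraitTable
    params: SceneParams

    @property
    def achieved_density(self) -> float:
        """Stomata per mm^2 actually placed (len(boxes) / field area)."""
        return len(self.boxes) / self.params.field_area_mm2


def ellipse_perimeter_um(a_um: float, b_um: float) -> float:
    """Exact perimeter of an ellipse with semi-axes a >= b (um), 4*a*E(e^2)."""
    m = 1.0 - (b_um / a_um) ** 2
    return 4.0 * a_um * float(ellipe(m))


def _analytic_traits(a_um: float, b_um: float, f_gcp: float) -> dict[str, float]:
    sa = math.pi * a_um * b_um
    sp = ellipse_perimeter_um(a_um, b_um)
    return {
        "SD": float("nan"),  # density attaches at field-of-view level
        "SW": 2 * b_um,
        "SL": 2 * a_um,
        "SA": sa,
        "SP": sp,
        "GCPA": f_gcp * sa,
        "SCA": (1 - f_gcp) * sa,
        "SR": 4 * math.pi * sa / sp ** 2,
        "SE": math.sqrt(1 - (b_um / a_um) ** 2),
        "PGCPA": f_gcp,
        "PSCA": 1 - f_gcp,
    }


def _bbox_half_extents_px(a_px: float, b_px: float, theta: float) -> tuple[float, float]:
    """Half extents of the axis-aligned bounding box of a rotated ellipse."""
    ex = math.hypot(a_px * math.cos(theta), b_px * math.sin(theta))
    ey = math.hypot(a_px * math.sin(theta), b_px * math.cos(theta))
    return ex, ey


def _render_ellipse(mask: np.ndarray, cx: float, cy: float, a: float, b: float, theta: float) -> None:
    """OR a rotated ellipse into ``mask`` (pixel-center inclusion test)."""
    h, w = mask.shape
    ex, ey = _bbox_half_extents_px(a, b, theta)
    x0 = max(int(math.floor(cx - ex)) - 1, 0)
    x1 = min(int(math.ceil(cx + ex)) + 1, w)
    y0 = max(int(math.floor(cy - ey)) - 1, 0)
    y1 = min(int(math.ceil(cy + ey)) + 1, h)
    if x1 <= x0 or y1 <= y0:
        return
    xs = np.arange(x0, x1) + 0.5 - cx
    ys = np.arange(y0, y1) + 0.5 - cy
    X, Y = np.meshgrid(xs, ys)
    ct, st = math.cos(theta), math.sin(theta)
    U = X * ct + Y * st
    V = -X * st + Y * ct
    mask[y0:y1, x0:x1] |= (U / a) ** 2 + (V / b) ** 2 <= 1.0


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Generate one reproducible synthetic epidermis field of view.

    The stoma count is ``round(target_density x field area in mm^2)``
    when that many non-overlapping complexes fit; otherwise as many as
    can be placed are kept and a warning is logged.  Placement follows
    jittered parallel rows (the longitudinal stomatal files of the maize
    epidermis) with rejection sampling against bounding-box overlap.
    Identical parameters, including the seed, give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    s = params.um_per_px
    W = params.pixels_per_side
    H = max(int(round(params.field_height_um / s)), 1)

    n_target = int(round(params.target_density * params.field_area_mm2))
    mean_len = params.length_dist[0]
    if mean_len >= min(params.field_width_um, params.field_height_um):
        raise ValueError(
            f"infeasible geometry: mean stomatal length {mean_len} um does not fit in a "
            f"{params.field_width_um} x {params.field_height_um} um field"
        )

    complex_mask = np.zeros((H, W), bool)
    gcp_mask = np.zeros((H, W), bool)
    boxes: list[BoundingBox] = []
    records: list[dict] = []

    # candidate rows across the field, jittered; stomata files run along x
    row_spacing_px = params.row_spacing_um / s
    n_rows = max(int(H / row_spacing_px), 1)
    row_ys = (np.arange(n_rows) + 0.5) * H / n_rows

    placed_boxes: list[tuple[float, float, float, float]] = []
    gap_px = 6.0 / s  # minimum clearance between bounding boxes, um -> px

    attempts = 0
    max_attempts = max(3000 * n_target, 3000)
    while len(boxes) < n_target and attempts < max_attempts:
        attempts += 1
        length = rng.normal(*params.length_dist)
        width = rng.normal(*params.width_dist)
        f_gcp = rng.normal(*params.gcp_fraction_dist)
        if not (width > 4 * s and length > width and 0.02 < f_gcp < 0.98):
            continue
        a, b = (length / 2) / s, (width / 2) / s  # px
        theta = math.radians(rng.normal(0.0, params.orientation_jitter_deg)) if params.orientation_jitter_deg else 0.0
        ex, ey = _bbox_half_extents_px(a, b, theta)
        row = row_ys[rng.integers(0, n_rows)]
        cy = row + rng.normal(0.0, 0.1 * row_spacing_px)
        cx = rng.uniform(0, W)
        if not params.allow_border_clipped:
            if not (ex + 1 <= cx <= W - ex - 1 and ey + 1 <= cy <= H - ey - 1):
                continue
        cand = (cx - ex - gap_px / 2, cy - ey - gap_px / 2, cx + ex + gap_px / 2, cy + ey + gap_px / 2)
        if any(cand[0] < q[2] and q[0] < cand[2] and cand[1] < q[3] and q[1] < cand[3] for q in placed_boxes):
            continue
        placed_boxes.append(cand)

        _render_ellipse(complex_mask, cx, cy, a, b, theta)
        k = math.sqrt(f_gcp)
        _render_ellipse(gcp_mask, cx, cy, a * k, b * k, theta)

        x0 = max(int(math.floor(cx - ex)), 0)
        x1 = min(int(math.ceil(cx + ex)), W)
        y0 = max(int(math.floor(cy - ey)), 0)
        y1 = min(int(math.ceil(cy + ey)), H)
        boxes.append(BoundingBox(x0, y0, x1, y1, confidence=None))

        rec = _analytic_traits(a * s, b * s, f_gcp)
        rec.update(stoma_id=len(boxes) - 1, cx_px=cx, cy_px=cy, theta_deg=math.degrees(theta))
        records.append(rec)

    if len(boxes) < n_target:
        logger.warning(
            "requested density %.1f mm^-2 (%d stomata) infeasible without overlap; placed %d",
            params.target_density, n_target, len(boxes),
        )

    bg, sub_level, gcp_level = params.intensity_levels
    img = np.full((H, W), float(bg))
    img[complex_mask] = sub_level
    img[gcp_mask] = gcp_level
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    image = CalibratedImage(pixels, s, params.field_width_um, params.field_height_um, "other")
    columns = ["stoma_id", "cx_px", "cy_px", "theta_deg"]
    df = pd.DataFrame(records, columns=columns + [c for c in records[0] if c not in columns]) if records \
        else pd.DataFrame(columns=columns + list(_analytic_traits(1.0, 0.5, 0.5)))
    return SyntheticScene(image, complex_mask, gcp_mask, boxes, TraitTable(df), params)


def _ellipse_polygon(cx: float, cy: float, a: float, b: float, theta: float, n: int = 64) -> tuple[tuple[float, float], ...]:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    ct, st = math.cos(theta), math.sin(theta)
    xs = cx + a * np.cos(t) * ct - b * np.sin(t) * st
    ys = cy + a * np.cos(t) * st + b * np.sin(t) * ct
    return tuple((float(x), float(y)) for x, y in zip(xs, ys))


def scene_to_annotations(scene: SyntheticScene) -> tuple[str, str, tuple[np.ndarray, np.ndarray]]:
    """Export a scene as (YOLO box text, labelme-style JSON, mask pair).

    The YOLO text and masks round-trip exactly through the package's own
    parsers; the polygon document approximates each generative ellipse
    with a 64-gon for annotation-tool interoperability.
    """
    W = scene.image.shape[1]
    H = scene.image.shape[0]
    yolo = format_yolo_boxes(scene.boxes, W, H)
    s = scene.image.um_per_px
    polys: list[LabeledPolygon] = []
    for rec in scene.truth_traits.df.itertuples():
        a, b = rec.SL / 2 / s, rec.SW / 2 / s
        th = math.radians(rec.theta_deg)
        polys.append(LabeledPolygon("stomatal_complex", _ellipse_polygon(rec.cx_px, rec.cy_px, a, b, th)))
        k = math.sqrt(rec.PGCPA)
        polys.append(LabeledPolygon("guard_cell_and_pore", _ellipse_polygon(rec.cx_px, rec.cy_px, a * k, b * k, th)))
    return yolo, format_polygons(polys, W, H), (scene.complex_mask.copy(), scene.gcp_mask.copy())


def write_scene(scene: SyntheticScene, outdir: str | Path, stem: str = "scene") -> dict[str, Path]:
    """Write image, masks, YOLO boxes, polygons and truth traits to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    yolo, polys, (cm, gm) = scene_to_annotations(scene)
    paths = {
        "image": outdir / f"{stem}.png",
        "complex_mask": outdir / f"{stem}_complex_mask.png",
        "gcp_mask": outdir / f"{stem}_gcp_mask.png",
        "boxes": outdir / f"{stem}_boxes.txt",
        "polygons": outdir / f"{stem}_polygons.json",
        "truth": outdir / f"{stem}_truth.csv",
    }
    write_image(scene.image, paths["image"])
    write_mask(cm, paths["complex_mask"])
    write_mask(gm, paths["gcp_mask"])
    paths["boxes"].write_text(yolo)
    paths["polygons"].write_text(polys)
    write_trait_csv(scene.truth_traits, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# configuration


def save_scene_config(params: SceneParams, path: str | Path) -> None:
    """Write a YAML config mapping 1:1 onto :class:`SceneParams` fields."""
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.__dict__.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_scene_config(path: str | Path) -> SceneParams:
    d = yaml.safe_load(Path(path).read_text())
    for k in ("length_dist", "width_dist", "gcp_fraction_dist", "intensity_levels"):
        if k in d:
            d[k] = tuple(d[k])
    return SceneParams(**d)
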