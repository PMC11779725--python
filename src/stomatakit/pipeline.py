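"""End-to-end helpers chaining segmentation, fusion and morphometry."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detection import stomatal_density
from .io import CalibratedImage, TraitTable
from .morphometry import measure_stoma, records_to_table
from .segmentation import StomaInstance, bands_from_levels, fuse_masks, label_stomata, reference_segment
from .synthetic import SyntheticScene

__all__ = ["measure_scene", "scene_trait_table", "match_instances_to_truth"]


def measure_scene(
    img: CalibratedImage,
    level_bands: dict[str, tuple[float, float]] | None = None,
    border_policy: str = "drop_for_traits",
    min_area_px: int = 16,
) -> tuple[list[StomaInstance], TraitTable]:
    """Segment an image, fuse masks, extract instances and measure traits.

    Returns every extracted instance plus a trait table over the
    instances retained under ``border_policy`` (border-truncated stomata
    are excluded from size/shape traits by default).  The table's SD
    column carries the field-level density count/area over all
    instances, border-touching included.
    """
    pair = reference_segment(img, level_bands)
    fused = fuse_masks(pair)
    instances = label_stomata(fused, pair.gcp_mask, border_policy, min_area_px=min_area_px)
    kept = [i for i in instances if border_policy == "keep" or not i.border_touching]
    records = [measure_stoma(i, img.um_per_px) for i in kept]
    table = records_to_table(records) if records else TraitTable(
        pd.DataFrame(columns=["SW", "SL", "SA", "SP", "GCPA", "SCA", "SR", "SE", "PGCPA", "PSCA", "SD"])
    )
    table.df["SD"] = stomatal_density(len(instances), img)
    return instances, table


def scene_trait_table(scene: SyntheticScene, **measure_kw) -> tuple[list[StomaInstance], TraitTable]:
    """Run the measurement chain on a synthetic scene with the bands
    implied by its generative gray levels."""
    bands = bands_from_levels(scene.params)
    return measure_scene(scene.image, level_bands=bands, **measure_kw)


def match_instances_to_truth(
    instances: list[StomaInstance], scene: SyntheticScene
) -> list[tuple[StomaInstance, pd.Series]]:
    """Pair extracted instances with the scene's analytic truth records
    by nearest bounding-box centre (one truth per instance)."""
    truth = scene.truth_traits.df
    centres = truth[["cx_px", "cy_px"]].to_numpy(float)
    pairs = []
    used: set[int] = set()
    for inst in instances:
        cx, cy = inst.bbox.center
        d2 = ((centres[:, 0] - cx) ** 2) + ((centres[:, 1] - cy) ** 2)
        order = np.argsort(d2)
        j = next((int(k) for k in order if int(k) not in used), None)
        if j is None:
            continue
        used.add(j)
        pairs.append((inst, truth.iloc[j]))
    return pairs
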