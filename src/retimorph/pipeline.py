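"""End-to-end trait extraction: vessel maps in, trait tables out.

Two-pass protocol for a dataset: a first pass skeletonizes every map and
collects per-branch calibers so the dataset-wide uber-mean ``Um`` can be
pooled across images; the second pass splits each map into caliber classes
at ``F * Um`` and computes the 25 traits per class.  For a single image
(or when ``per_image_um`` is set) the uber-mean is computed from that
image's own branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import extract_branches, skeletonize
from .traits import TRAIT_NAMES, assemble_trait_vector
from .vesselmap import (
    VesselMap,
    compute_uber_mean,
    estimate_caliber,
    split_by_caliber,
)

__all__ = ["ImageMorphometry", "measure_image", "extract_traits", "trait_table"]


@dataclass
class ImageMorphometry:
    """First-pass measurements of one map: skeleton, branches, calibers."""

    vmap: VesselMap
    skeleton: np.ndarray
    branch_points: list[np.ndarray]
    branch_calibers: np.ndarray

    @property
    def image_id(self) -> str:
        return self.vmap.image_id


def measure_image(vmap: VesselMap) -> ImageMorphometry:
    """Skeletonize a map and measure per-branch mean calibers."""
    skel = skeletonize(vmap.pixels)
    branches = extract_branches(skel)
    field = estimate_caliber(vmap, skel.pixels) if not vmap.is_empty else None
    calibers = np.array(
        [field.branch_mean(b.points) for b in branches] if field else [], dtype=float
    )
    return ImageMorphometry(
        vmap=vmap,
        skeleton=skel.pixels,
        branch_points=[b.points for b in branches],
        branch_calibers=calibers,
    )


def extract_traits(
    maps: list[VesselMap],
    factor: float = 0.5,
    per_image_um: bool = False,
) -> pd.DataFrame:
    """Extract the 75-trait table for a set of vessel maps.

    Returns a DataFrame with one row per (image_id, class) and the 25 trait
    columns in canonical order, plus branch/caliber bookkeeping columns.
    """
    measured = [measure_image(m) for m in maps]
    pooled = np.concatenate(
        [m.branch_calibers for m in measured if m.branch_calibers.size]
        or [np.array([])]
    )
    um_global = compute_uber_mean(pooled) if pooled.size and not per_image_um else None

    rows = []
    for m in measured:
        if m.branch_calibers.size:
            um = um_global if um_global is not None else compute_uber_mean(m.branch_calibers)
            split = split_by_caliber(m.vmap, m.branch_points, m.branch_calibers, um, factor)
            masks = split.masks
            n_thick = len(split.branch_classes["Thick"])
            n_thin = len(split.branch_classes["Thin"])
            mean_cal = float(m.branch_calibers.mean())
        else:  # empty map: all classes empty
            um, n_thick, n_thin, mean_cal = float("nan"), 0, 0, float("nan")
            empty = np.zeros_like(m.vmap.pixels)
            masks = {"Thin": empty, "Thick": empty, "Total": m.vmap.pixels}
        vectors = assemble_trait_vector(masks, image_id=m.image_id)
        for cls, traits in vectors.items():
            row = {
                "image_id": m.image_id,
                "class": cls,
                "n_branches": len(m.branch_points),
                "mean_caliber": mean_cal,
                "Um": um,
                "F": factor,
                "n_thick": n_thick,
                "n_thin": n_thin,
            }
            row.update(traits)
            rows.append(row)
    cols = ["image_id", "class", "n_branches", "mean_caliber", "Um", "F", "n_thick", "n_thin"]
    return pd.DataFrame(rows, columns=cols + list(TRAIT_NAMES))


def trait_table(df: pd.DataFrame, cls: str = "Total") -> pd.DataFrame:
    """One row per image for a single caliber class, trait columns only."""
    sub = df[df["class"] == cls].set_index("image_id")
    return sub[list(TRAIT_NAMES)]
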