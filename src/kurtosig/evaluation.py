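"""Grid resampling and spatial-overlap evaluation.

The DKI maps live on a coarse EPI grid (default 2x2x5 mm) while the manual
reference segmentation lives on a finer anatomical grid (default 1x1x3 mm).
Resampling is voxel-centre pull-back through both affines: every target voxel
centre is mapped into source index space and interpolated there — nearest
neighbour for masks (label integrity), nearest or trilinear for scalar maps.
Overlap of two masks on a common grid is quantified by the Dice coefficient
2|A∩B| / (|A|+|B|).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid, ParametricMap, SegmentationMask

__all__ = [
    "resample_to_grid",
    "dice",
    "OverlapReport",
    "overlap_report",
    "summarize_reports",
]


def _pullback_coords(source: Grid, target: Grid) -> np.ndarray:
    """Source-space fractional indices of every target voxel centre, (3, ...)."""
    tgt_idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in target.shape], indexing="ij"), axis=-1
    )
    world = target.index_to_world(tgt_idx)
    src_idx = source.world_to_index(world)
    return np.moveaxis(src_idx, -1, 0)


def resample_to_grid(
    source: Union[ParametricMap, SegmentationMask],
    target_grid: Grid,
    method: str = "nearest",
) -> Union[ParametricMap, SegmentationMask]:
    """Resample a map or mask onto ``target_grid`` in shared world space.

    Masks accept only ``nearest``; out-of-field voxels become False (masks)
    or NaN (maps). Identical grids return a verbatim copy.
    """
    if method not in ("nearest", "trilinear"):
        raise ValueError(f"unknown method {method!r}")
    is_mask = isinstance(source, SegmentationMask)
    if is_mask and method != "nearest":
        raise ValueError("masks must be resampled with method='nearest'")
    if source.grid.same_as(target_grid):
        if is_mask:
            return SegmentationMask(
                source.values.copy(), target_grid, provenance=source.provenance
            )
        return ParametricMap(source.values.copy(), source.kind, target_grid)

    coords = _pullback_coords(source.grid, target_grid)
    if is_mask or method == "nearest":
        # explicit nearest: a point is in-field iff it lies within the outer
        # voxel boundaries [-0.5, n-0.5]; ties round towards +infinity and
        # are clipped back into range (boundary-edge points stay in-field)
        shape = np.array(source.grid.shape).reshape(3, *([1] * 3))
        in_field = np.all((coords >= -0.5) & (coords <= shape - 0.5), axis=0)
        nearest = np.clip(np.floor(coords + 0.5).astype(int), 0, shape - 1)
        vals = source.values[tuple(nearest)]
        if is_mask:
            out = np.where(in_field, vals, False)
            return SegmentationMask(out, target_grid, provenance=source.provenance)
        out = np.where(in_field, vals, np.nan)
        return ParametricMap(out, source.kind, target_grid)
    out = ndimage.map_coordinates(
        source.values.astype(float),
        coords,
        order=1,
        mode="constant",
        cval=np.nan,
        prefilter=False,
    )
    return ParametricMap(out, source.kind, target_grid)


def dice(a: SegmentationMask, b: SegmentationMask) -> float:
    """Dice similarity coefficient of two masks on the same grid.

    Both-empty masks return 1.0 with an explicit warning (degenerate overlap
    of two empty sets); grids are never resampled implicitly.
    """
    if not a.grid.same_as(b.grid):
        raise ValueError("masks live on different grids; resample explicitly first")
    n_a = int(a.values.sum())
    n_b = int(b.values.sum())
    if n_a == 0 and n_b == 0:
        warnings.warn(
            "Dice of two empty masks is defined as 1.0", RuntimeWarning, stacklevel=2
        )
        return 1.0
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (n_a + n_b)


@dataclass
class OverlapReport:
    """One automatic-vs-reference comparison, Table-style."""

    dice: float
    n_auto: int
    n_ref: int
    n_intersection: int
    subgroup_label: str = ""
    case_id: str = ""
    grid_id: str = ""

    def __post_init__(self) -> None:
        if self.n_auto + self.n_ref > 0:
            expected = 2.0 * self.n_intersection / (self.n_auto + self.n_ref)
            assert self.dice == expected, "dice inconsistent with counts"


def overlap_report(
    auto: SegmentationMask,
    ref: SegmentationMask,
    subgroup_label: str = "",
    case_id: str = "",
    grid_id: str = "",
) -> OverlapReport:
    """Dice plus voxel counts for one case."""
    d = dice(auto, ref)
    return OverlapReport(
        dice=d,
        n_auto=int(auto.values.sum()),
        n_ref=int(ref.values.sum()),
        n_intersection=int((auto.values & ref.values).sum()),
        subgroup_label=subgroup_label,
        case_id=case_id,
        grid_id=grid_id,
    )


def summarize_reports(reports: List[OverlapReport]) -> pd.DataFrame:
    """Per-subgroup mean Dice plus a global average row."""
    if not reports:
        raise ValueError("no reports to summarize")
    df = pd.DataFrame(
        {
            "subgroup_label": [r.subgroup_label for r in reports],
            "dice": [r.dice for r in reports],
        }
    )
    per_group = (
        df.groupby("subgroup_label", sort=True)["dice"]
        .agg(n="size", mean_dice="mean")
        .reset_index()
    )
    overall = pd.DataFrame(
        [{"subgroup_label": "average", "n": len(df), "mean_dice": df["dice"].mean()}]
    )
    return pd.concat([per_group, overall], ignore_index=True)
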