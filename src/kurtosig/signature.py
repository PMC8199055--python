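"""Joint MK-MD feature space: healthy occupancy and the glioma signature.

Whole-brain MD and MK maps, read voxel-wise, populate a 2D histogram over
(MD, MK). In healthy brain the populated bins form a characteristic
crescent (high kurtosis at low diffusivity in white matter, down to free
water at high MD / low MK). Glioma tissue occupies a combination of MD and
MK values that healthy brain does not. This module makes that observation
operational:

* :func:`joint_histogram` bins one subject's maps;
* :func:`build_reference_occupancy` pools control subjects and marks every
  bin whose pooled relative frequency reaches ``tau`` (plus a Chebyshev
  dilation of ``dilate`` bins) as *occupied by healthy brain*;
* :func:`derive_signature_region` takes the complement within physiological
  MD/MK bounds — the glioma-specific signature region;
* :func:`label_voxels` back-projects the region onto a subject's maps,
  removing connected components smaller than ``min_cluster`` voxels
  (26-connectivity).

A manual rectangular gate (:func:`manual_gate_region`) mimics drawing the
anomalous scatter-plot area by hand instead of deriving it from controls.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import ParametricMap, SegmentationMask

__all__ = [
    "Binning",
    "Bounds",
    "JointHistogram",
    "OccupancyMask",
    "SignatureRegion",
    "joint_histogram",
    "build_reference_occupancy",
    "derive_signature_region",
    "manual_gate_region",
    "label_voxels",
    "TAU_DEFAULT",
    "DILATE_DEFAULT",
    "MIN_CLUSTER_DEFAULT",
]

TAU_DEFAULT = 1e-5
DILATE_DEFAULT = 1
MIN_CLUSTER_DEFAULT = 10


@dataclass(frozen=True)
class Binning:
    """Fixed bin edges for the joint histogram.

    Defaults: MD in [0, 3.5] step 0.05 (1e-3 mm^2/s), MK in [0, 3.0]
    step 0.02 — fine enough to separate the tumor cluster, coarse enough to
    avoid empty-bin speckle in the healthy occupancy.
    """

    md_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 3.5, 71)
    )
    mk_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 3.0, 151)
    )

    def __post_init__(self) -> None:
        for name in ("md_edges", "mk_edges"):
            e = np.asarray(getattr(self, name), dtype=float)
            if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
                raise ValueError(f"{name} must be strictly increasing, length >= 2")
            e = e.copy()
            e.setflags(write=False)
            object.__setattr__(self, name, e)

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.md_edges.size - 1, self.mk_edges.size - 1)

    @property
    def md_centers(self) -> np.ndarray:
        return 0.5 * (self.md_edges[:-1] + self.md_edges[1:])

    @property
    def mk_centers(self) -> np.ndarray:
        return 0.5 * (self.mk_edges[:-1] + self.mk_edges[1:])

    def same_as(self, other: "Binning") -> bool:
        return np.array_equal(self.md_edges, other.md_edges) and np.array_equal(
            self.mk_edges, other.mk_edges
        )


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value; -1 marks out of range. Right-closed last bin,
    matching numpy.histogram."""
    idx = np.digitize(values, edges) - 1
    idx[values == edges[-1]] = edges.size - 2
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


@dataclass(frozen=True)
class Bounds:
    """Physiological MD/MK limits, half-open intervals (lo, hi]."""

    md: Tuple[float, float] = (0.2, 3.0)
    mk: Tuple[float, float] = (0.1, 2.0)

    def __post_init__(self) -> None:
        if self.md[0] >= self.md[1] or self.mk[0] >= self.mk[1]:
            raise ValueError("bounds must satisfy lo < hi")


@dataclass
class JointHistogram:
    """Binned MK-MD occupancy counts for one subject (or pooled source)."""

    binning: Binning
    counts: np.ndarray
    n_total: int
    n_out_of_range: int
    n_invalid: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.binning.shape:
            raise ValueError("counts shape does not match binning")
        if int(self.counts.sum()) + self.n_out_of_range != self.n_total:
            raise ValueError("count conservation violated: sum(counts)+oor != n_total")


@dataclass
class OccupancyMask:
    """Bins occupied by the healthy reference (pooled controls)."""

    binning: Binning
    occupied: np.ndarray
    threshold_used: float
    n_subjects: int
    dilate: int = 0

    def __post_init__(self) -> None:
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.occupied.shape != self.binning.shape:
            raise ValueError("occupancy shape does not match binning")


@dataclass
class SignatureRegion:
    """Bins carrying the glioma-specific MD/MK combination."""

    binning: Binning
    region: np.ndarray
    bounds: Optional[Bounds] = None

    def __post_init__(self) -> None:
        self.region = np.asarray(self.region, dtype=bool)
        if self.region.shape != self.binning.shape:
            raise ValueError("region shape does not match binning")


def joint_histogram(
    md: ParametricMap,
    mk: ParametricMap,
    mask: SegmentationMask,
    binning: Optional[Binning] = None,
    source_id: str = "",
) -> JointHistogram:
    """Bin the masked, valid voxels of one subject's MD/MK maps."""
    binning = binning or Binning()
    if not md.grid.same_as(mk.grid) or not md.grid.same_as(mask.grid):
        raise ValueError("MD/MK maps and mask must share a grid")
    if md.kind != "MD" or mk.kind != "MK":
        raise ValueError("expected maps of kind MD and MK")
    sel = mask.values
    md_v = md.values[sel]
    mk_v = mk.values[sel]
    valid = np.isfinite(md_v) & np.isfinite(mk_v)
    n_invalid = int((~valid).sum())
    md_v, mk_v = md_v[valid], mk_v[valid]
    counts, _, _ = np.histogram2d(
        md_v, mk_v, bins=(binning.md_edges, binning.mk_edges)
    )
    counts = counts.astype(np.int64)
    n_total = int(valid.sum())
    return JointHistogram(
        binning=binning,
        counts=counts,
        n_total=n_total,
        n_out_of_range=n_total - int(counts.sum()),
        n_invalid=n_invalid,
        source_id=source_id,
    )


def build_reference_occupancy(
    histograms: Sequence[JointHistogram],
    tau: float = TAU_DEFAULT,
    dilate: int = DILATE_DEFAULT,
) -> OccupancyMask:
    """Pool control histograms into the healthy occupancy mask.

    A bin is occupied iff its pooled relative frequency is >= ``tau`` (and
    nonzero), or lies within ``dilate`` bins (Chebyshev distance) of such a
    bin. ``tau=0, dilate=0`` reduces to the support of the pooled histogram —
    the literal "does not occur in healthy brain" construction.
    """
    if not histograms:
        raise ValueError("need at least one reference histogram")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if dilate < 0:
        raise ValueError("dilate must be >= 0")
    binning = histograms[0].binning
    for h in histograms[1:]:
        if not h.binning.same_as(binning):
            raise ValueError("reference histograms have mismatched bin edges")
    pooled = np.sum([h.counts for h in histograms], axis=0)
    total = int(pooled.sum())
    freq = pooled / total if total else np.zeros_like(pooled, dtype=float)
    occ = (pooled > 0) & (freq >= tau)
    if dilate > 0:
        occ = ndimage.binary_dilation(
            occ, structure=np.ones((3, 3), dtype=bool), iterations=dilate
        )
    return OccupancyMask(
        binning=binning,
        occupied=occ,
        threshold_used=float(tau),
        n_subjects=len(histograms),
        dilate=int(dilate),
    )


def _bounds_mask(binning: Binning, bounds: Bounds) -> np.ndarray:
    """Bins whose centres fall inside the (lo, hi] physiological bounds."""
    md_in = (binning.md_centers > bounds.md[0]) & (binning.md_centers <= bounds.md[1])
    mk_in = (binning.mk_centers > bounds.mk[0]) & (binning.mk_centers <= bounds.mk[1])
    return md_in[:, None] & mk_in[None, :]


def derive_signature_region(
    occ: OccupancyMask, bounds: Optional[Bounds] = None
) -> SignatureRegion:
    """Glioma signature = complement of healthy occupancy within bounds."""
    bounds = bounds or Bounds()
    inside = _bounds_mask(occ.binning, bounds)
    if not inside.any():
        raise ValueError("physiological bounds exclude every bin")
    region = ~occ.occupied & inside
    assert not (region & occ.occupied).any()  # construction invariant
    return SignatureRegion(binning=occ.binning, region=region, bounds=bounds)


def manual_gate_region(
    binning: Binning,
    md_range: Tuple[float, float],
    mk_range: Tuple[float, float],
) -> SignatureRegion:
    """Explicit rectangular MD/MK gate, mimicking a hand-drawn scatter area."""
    gate = Bounds(md=md_range, mk=mk_range)
    return SignatureRegion(
        binning=binning, region=_bounds_mask(binning, gate), bounds=gate
    )


def label_voxels(
    md: ParametricMap,
    mk: ParametricMap,
    mask: SegmentationMask,
    region: SignatureRegion,
    min_cluster: int = MIN_CLUSTER_DEFAULT,
) -> SegmentationMask:
    """Back-project the signature region onto the maps.

    A voxel is labeled iff it is valid in both maps, inside the mask, and its
    (MD, MK) bin belongs to the region. 26-connected components smaller than
    ``min_cluster`` voxels are removed.
    """
    if not md.grid.same_as(mk.grid) or not md.grid.same_as(mask.grid):
        raise ValueError("maps and mask must share a grid")
    if min_cluster < 0:
        raise ValueError("min_cluster must be >= 0")
    binning = region.binning
    md_idx = _bin_index(md.values.ravel(), binning.md_edges)
    mk_idx = _bin_index(mk.values.ravel(), binning.mk_edges)
    ok = (
        mask.values.ravel()
        & np.isfinite(md.values.ravel())
        & np.isfinite(mk.values.ravel())
        & (md_idx >= 0)
        & (mk_idx >= 0)
    )
    labeled = np.zeros(md.values.size, dtype=bool)
    labeled[ok] = region.region[md_idx[ok], mk_idx[ok]]
    labeled = labeled.reshape(md.grid.shape)
    if min_cluster > 1 and labeled.any():
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        comp, n_comp = ndimage.label(labeled, structure=structure)
        sizes = np.bincount(comp.ravel())
        too_small = np.flatnonzero(sizes < min_cluster)
        labeled[np.isin(comp, too_small[too_small > 0])] = False
    return SegmentationMask(labeled, md.grid, provenance="auto")
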