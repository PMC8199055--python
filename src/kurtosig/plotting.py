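"""Scatter-plot rendering of the joint MK-MD feature space."""
from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .grids import ParametricMap, SegmentationMask
from .signature import OccupancyMask, SignatureRegion

__all__ = ["plot_signature_scatter"]


def plot_signature_scatter(
    md: ParametricMap,
    mk: ParametricMap,
    mask: SegmentationMask,
    region: Optional[SignatureRegion] = None,
    occupancy: Optional[OccupancyMask] = None,
    path=None,
    max_points: int = 50000,
):
    """Whole-brain MK-vs-MD scatter with optional occupancy/region overlay.

    Returns the matplotlib figure; saves a PNG when ``path`` is given.
    """
    sel = mask.values & np.isfinite(md.values) & np.isfinite(mk.values)
    md_v = md.values[sel]
    mk_v = mk.values[sel]
    if md_v.size > max_points:
        step = int(np.ceil(md_v.size / max_points))
        md_v, mk_v = md_v[::step], mk_v[::step]

    fig, ax = plt.subplots(figsize=(6, 5))
    for lattice, color, label in (
        (occupancy.occupied if occupancy else None, "#c6dbef", "healthy occupancy"),
        (region.region if region else None, "#fcae91", "signature region"),
    ):
        if lattice is None:
            continue
        binning = (occupancy or region).binning
        ax.pcolormesh(
            binning.md_edges,
            binning.mk_edges,
            np.where(lattice.T, 1.0, np.nan),
            cmap=matplotlib.colors.ListedColormap([color]),
            shading="flat",
        )
        ax.plot([], [], "s", color=color, label=label)
    ax.plot(md_v, mk_v, ".", ms=1, color="k", alpha=0.3, label="brain voxels")
    ax.set_xlabel(r"MD [$10^{-3}$ mm$^2$/s]")
    ax.set_ylabel("MK")
    ax.set_xlim(0, 3.5)
    ax.set_ylim(0, 2.0)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(str(path), dpi=120, metadata={"Software": None})
        plt.close(fig)
    return fig
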