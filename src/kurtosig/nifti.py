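"""NIfTI-1 and FSL bval/bvec readers and writers.

All volumes go through nibabel. The gradient table uses the FSL dialect:
one whitespace-separated row of b-values, and three bvec rows holding the
x, y, z components per volume. Maps are written float32 with NaN invalid
markers; masks uint8. Occupancy/region lattices serialise to a small
self-describing CSV.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np

from .grids import DWIVolume, Grid, ParametricMap, SegmentationMask
from .scheme import AcquisitionScheme
from .signature import Binning, OccupancyMask, SignatureRegion

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_map",
    "write_map",
    "read_mask",
    "write_mask",
    "write_occupancy",
    "read_occupancy",
    "write_region",
    "read_region",
]

_BVEC_NORM_TOL = 1e-3


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk inputs."""


def _load_nifti(path) -> Tuple[np.ndarray, Grid]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types
        raise FormatError(f"cannot read NIfTI header of {path}: {exc}") from exc
    affine = img.affine
    if affine is None:
        raise FormatError(f"{path}: affine missing")
    data = np.asarray(img.dataobj)
    shape3 = data.shape[:3]
    return data, Grid(shape3, affine)


def _save_nifti(path, data: np.ndarray, grid: Grid, dtype) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), np.asarray(grid.affine))
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Read a 4D DWI volume with its FSL-dialect gradient table.

    b-values are rounded to integer s/mm^2; bvec columns must be unit (or
    zero, at b=0) within 1e-3 and are renormalised exactly.
    """
    data, grid = _load_nifti(nifti_path)
    if data.ndim != 4:
        raise FormatError(f"{nifti_path}: expected a 4D DWI volume")
    bvals = np.loadtxt(str(bval_path), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        pass  # ambiguous 3x3: FSL rows are components, columns volumes
    if bvals.size != bvecs.shape[0] or bvals.size != data.shape[3]:
        raise FormatError(
            f"volume-count mismatch: {data.shape[3]} volumes, "
            f"{bvals.size} b-values, {bvecs.shape[0]} gradient vectors"
        )
    bvals = np.round(bvals).astype(float)
    norms = np.linalg.norm(bvecs, axis=1)
    nonzero = bvals > 0
    if np.any(np.abs(norms[nonzero] - 1.0) > _BVEC_NORM_TOL):
        raise FormatError("gradient vectors deviate from unit norm beyond 1e-3")
    bvecs = bvecs.copy()
    bvecs[nonzero] /= norms[nonzero, None]
    bvecs[~nonzero] = 0.0
    return DWIVolume(data, grid, AcquisitionScheme(bvals, bvecs))


def write_dwi(out_prefix, dwi: DWIVolume) -> Tuple[Path, Path, Path]:
    """Write <prefix>.nii + <prefix>.bval/.bvec (FSL dialect)."""
    prefix = Path(out_prefix)
    nii = prefix.with_suffix(".nii")
    _save_nifti(nii, dwi.signal, dwi.grid, np.float32)
    bval = prefix.with_suffix(".bval")
    bvec = prefix.with_suffix(".bvec")
    np.savetxt(str(bval), dwi.scheme.bvals[None, :], fmt="%.0f")
    np.savetxt(str(bvec), dwi.scheme.bvecs.T, fmt="%.8f")
    return nii, bval, bvec


def read_map(path, kind: str) -> ParametricMap:
    data, grid = _load_nifti(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D parametric map")
    return ParametricMap(data.astype(np.float32), kind, grid)


def write_map(path, pmap: ParametricMap) -> None:
    _save_nifti(path, pmap.values, pmap.grid, np.float32)


def read_mask(path, provenance: str = "manual") -> SegmentationMask:
    data, grid = _load_nifti(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise FormatError(f"{path}: mask contains non-binary values {uniq[:5]}")
    return SegmentationMask(data.astype(bool), grid, provenance=provenance)


def write_mask(path, mask: SegmentationMask) -> None:
    _save_nifti(path, mask.values.astype(np.uint8), mask.grid, np.uint8)


# -- bin-lattice CSV (occupancy / signature region) --------------------------

def _write_lattice(path, binning: Binning, flags: np.ndarray, meta: dict) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kurtosig-lattice", "1"])
        for key, val in sorted(meta.items()):
            w.writerow(["meta", key, repr(val)])
        w.writerow(["md_edges"] + [repr(float(x)) for x in binning.md_edges])
        w.writerow(["mk_edges"] + [repr(float(x)) for x in binning.mk_edges])
        w.writerow(["i", "j", "value"])
        for i, j in zip(*np.nonzero(flags)):
            w.writerow([int(i), int(j), 1])


def _read_lattice(path):
    meta: dict = {}
    md_edges = mk_edges = None
    cells = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][0] != "kurtosig-lattice":
        raise FormatError(f"{path}: not a kurtosig lattice CSV")
    for row in rows[1:]:
        if not row:
            continue
        if row[0] == "meta":
            try:
                meta[row[1]] = int(row[2])
            except ValueError:
                meta[row[1]] = float(row[2])
        elif row[0] == "md_edges":
            md_edges = np.array([float(x) for x in row[1:]])
        elif row[0] == "mk_edges":
            mk_edges = np.array([float(x) for x in row[1:]])
        elif row[0] == "i":
            continue
        else:
            cells.append((int(row[0]), int(row[1])))
    if md_edges is None or mk_edges is None:
        raise FormatError(f"{path}: missing bin edges")
    binning = Binning(md_edges=md_edges, mk_edges=mk_edges)
    flags = np.zeros(binning.shape, dtype=bool)
    for i, j in cells:
        flags[i, j] = True
    return binning, flags, meta


def write_occupancy(path, occ: OccupancyMask) -> None:
    _write_lattice(
        path,
        occ.binning,
        occ.occupied,
        {
            "threshold_used": occ.threshold_used,
            "n_subjects": occ.n_subjects,
            "dilate": occ.dilate,
        },
    )


def read_occupancy(path) -> OccupancyMask:
    binning, flags, meta = _read_lattice(path)
    return OccupancyMask(
        binning=binning,
        occupied=flags,
        threshold_used=float(meta.get("threshold_used", 0.0)),
        n_subjects=int(meta.get("n_subjects", 0)),
        dilate=int(meta.get("dilate", 0)),
    )


def write_region(path, region: SignatureRegion) -> None:
    meta = {}
    if region.bounds is not None:
        meta = {
            "md_lo": region.bounds.md[0],
            "md_hi": region.bounds.md[1],
            "mk_lo": region.bounds.mk[0],
            "mk_hi": region.bounds.mk[1],
        }
    _write_lattice(path, region.binning, region.region, meta)


def read_region(path) -> SignatureRegion:
    from .signature import Bounds

    binning, flags, meta = _read_lattice(path)
    bounds = None
    if "md_lo" in meta:
        bounds = Bounds(
            md=(float(meta["md_lo"]), float(meta["md_hi"])),
            mk=(float(meta["mk_lo"]), float(meta["mk_hi"])),
        )
    return SignatureRegion(binning=binning, region=flags, bounds=bounds)
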