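"""Mean-diffusivity / mean-kurtosis map estimation from multi-shell DWI.

The estimator works per gradient direction on the log signal. Along one
direction with b-series {0, b_1, ..., b_m} the kurtosis representation is
linear in (ln S0, D, W):

    ln S(b) = ln S0 - (b/1000) * D + (b/1000)^2 * W,      W = D^2 * K / 6,

with D in 1e-3 mm^2/s and K dimensionless. Solving the normal equations per
direction gives the apparent diffusivity D_app and, via K = 6 W / D^2, the
apparent kurtosis coefficient K_app (the degree of deviation from
mono-exponential, i.e. Gaussian, signal decay). MD and MK are the arithmetic
means of D_app and K_app over directions. This is deliberately *not* a full
22-parameter diffusion/kurtosis tensor fit: the pipeline consumes only
direction-averaged MD/MK.

Fitted parameters are projected onto physiological bounds
(0 < D <= d_max, 0 <= K <= k_max) and the projections are counted. Voxels
with nonpositive b=0 or shell signal are flagged invalid and carry NaN in the
output maps.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import DWIVolume, Grid, ParametricMap, SegmentationMask
from .scheme import AcquisitionScheme, B_SCALE

__all__ = [
    "predict_signal",
    "fit_voxel",
    "smooth_dwi",
    "fit_volume",
    "DiffusionKurtosisModel",
    "KurtosisFitResults",
    "VoxelFit",
    "FailureCode",
]

D_MAX_DEFAULT = 5.0  # 1e-3 mm^2/s
K_MAX_DEFAULT = 3.0
SIGMA_DEFAULT = 1.25  # in-plane voxels
_D_FLOOR = 1e-6


class FailureCode:
    """Per-voxel fit status codes."""

    VALID = 0
    NONPOSITIVE_B0 = 1
    NONPOSITIVE_SIGNAL = 2
    INSUFFICIENT_DATA = 3
    OUT_OF_MASK = 4

    NAMES = {
        0: "valid",
        1: "nonpositive_b0",
        2: "nonpositive_signal",
        3: "insufficient_data",
        4: "out_of_mask",
    }


def predict_signal(s0: float, d: float, k: float, b) -> np.ndarray | float:
    """Closed-form kurtosis-representation signal S(b).

    Parameters: ``s0`` [a.u.] > 0, ``d`` [1e-3 mm^2/s] > 0, ``k`` >= 0,
    ``b`` [s/mm^2] >= 0 (scalar or array). Emits a warning when b exceeds the
    representation's monotonic range b <= 3/(d*k).
    """
    if s0 <= 0 or d <= 0 or k < 0:
        raise ValueError("require s0 > 0, d > 0, k >= 0")
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b must be nonnegative")
    if k > 0 and np.any(b_arr * B_SCALE * d * k > 3.0):
        warnings.warn(
            "b exceeds the kurtosis representation's validity range 3/(d*k); "
            "predicted signal is non-monotone in b",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = b_arr * B_SCALE
    out = s0 * np.exp(-beta * d + beta**2 * d**2 * k / 6.0)
    return out if out.ndim else float(out)


@dataclass
class VoxelFit:
    """Per-voxel kurtosis fit: per-direction D/K plus their means."""

    s0: float
    d_app: np.ndarray
    k_app: np.ndarray
    md: float
    mk: float
    valid: bool
    code: int = FailureCode.VALID


def _design_pinv(bvals: np.ndarray) -> np.ndarray:
    beta = bvals * B_SCALE
    design = np.stack([np.ones_like(beta), -beta, beta**2], axis=1)
    return np.linalg.pinv(design)  # (3, n_b)


def _fit_series(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    k_max: float,
    d_max: float,
) -> tuple:
    """Vectorised per-direction log-linear fit.

    ``signals``: (N, n_volumes). Returns (s0, d_app, k_app, codes, n_d_proj,
    n_k_proj) with d_app/k_app of shape (N, n_dirs).
    """
    groups = scheme.direction_groups()
    if not groups:
        raise ValueError("scheme has no diffusion-weighted directions")
    b0 = int(scheme.b0_indices[0])
    vol_idx = np.stack([np.concatenate(([b0], g[1])) for g in groups])  # (n_dirs, n_b)
    b_series = scheme.bvals[vol_idx[0]]
    if not np.all(scheme.bvals[vol_idx] == b_series):
        # heterogeneous shells per direction: fall back to per-group designs
        pinvs = [_design_pinv(scheme.bvals[idx]) for idx in vol_idx]
    else:
        pinvs = None
    if np.unique(b_series).size < 3:
        raise ValueError("fewer than 3 usable b-values per direction")

    signals = np.asarray(signals, dtype=float)
    n = signals.shape[0]
    codes = np.full(n, FailureCode.VALID, dtype=np.int8)
    codes[signals[:, b0] <= 0] = FailureCode.NONPOSITIVE_B0
    used = signals[:, np.unique(vol_idx)]
    bad_shell = (used <= 0).any(axis=1) & (codes == FailureCode.VALID)
    codes[bad_shell] = FailureCode.NONPOSITIVE_SIGNAL
    ok = codes == FailureCode.VALID

    n_dirs = vol_idx.shape[0]
    d_app = np.full((n, n_dirs), np.nan)
    k_app = np.full((n, n_dirs), np.nan)
    s0_est = np.full(n, np.nan)
    n_d_proj = 0
    n_k_proj = 0
    if ok.any():
        ln_s = np.log(signals[np.ix_(ok, vol_idx.ravel())]).reshape(
            ok.sum(), n_dirs, vol_idx.shape[1]
        )
        if pinvs is None:
            pinv = _design_pinv(b_series)
            params = np.einsum("pk,ndk->ndp", pinv, ln_s)
        else:
            params = np.stack(
                [np.einsum("pk,nk->np", pinvs[j], ln_s[:, j, :]) for j in range(n_dirs)],
                axis=1,
            )
        d_raw = params[..., 1]
        w_raw = params[..., 2]
        n_d_proj = int(((d_raw <= 0) | (d_raw > d_max)).sum())
        d_fit = np.clip(d_raw, _D_FLOOR, d_max)
        k_raw = 6.0 * w_raw / d_fit**2
        n_k_proj = int(((k_raw < 0) | (k_raw > k_max)).sum())
        k_fit = np.clip(k_raw, 0.0, k_max)
        d_app[ok] = d_fit
        k_app[ok] = k_fit
        s0_est[ok] = np.exp(params[..., 0].mean(axis=1))
    return s0_est, d_app, k_app, codes, n_d_proj, n_k_proj


def fit_voxel(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    k_max: float = K_MAX_DEFAULT,
    d_max: float = D_MAX_DEFAULT,
) -> VoxelFit:
    """Fit a single voxel's per-volume signal series."""
    signals = np.asarray(signals, dtype=float).reshape(1, -1)
    if signals.shape[1] != len(scheme):
        raise ValueError("signal length does not match the scheme")
    s0, d_app, k_app, codes, _, _ = _fit_series(signals, scheme, k_max, d_max)
    code = int(codes[0])
    valid = code == FailureCode.VALID
    return VoxelFit(
        s0=float(s0[0]),
        d_app=d_app[0],
        k_app=k_app[0],
        md=float(np.mean(d_app[0])) if valid else float("nan"),
        mk=float(np.mean(k_app[0])) if valid else float("nan"),
        valid=valid,
        code=code,
    )


def smooth_dwi(dwi: DWIVolume, sigma: float) -> DWIVolume:
    """Isotropic (in mm) Gaussian smoothing of every volume.

    ``sigma`` is given in in-plane voxels, as smoothing kernels usually are;
    the physical width ``sigma * voxel_size[0]`` mm is converted to per-axis
    voxel units, so through-plane smoothing is scaled by slice thickness.
    ``sigma=0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return DWIVolume(dwi.signal.copy(), dwi.grid, dwi.scheme)
    voxel = dwi.grid.voxel_size
    sigma_mm = sigma * voxel[0]
    sigmas = tuple(sigma_mm / v for v in voxel) + (0.0,)
    smoothed = ndimage.gaussian_filter(
        np.asarray(dwi.signal, dtype=float), sigma=sigmas, mode="nearest"
    )
    return DWIVolume(smoothed, dwi.grid, dwi.scheme)


class DiffusionKurtosisModel:
    """Direction-wise log-linear kurtosis model for a masked DWI volume.

    Parameters
    ----------
    dwi : DWIVolume
        The 4D signal with its acquisition scheme.
    mask : SegmentationMask, optional
        Brain mask on the DWI grid; voxels outside are never fitted.
    sigma : float
        Pre-smoothing width in in-plane voxels (0 disables smoothing).
    k_max, d_max : float
        Upper projection bounds for apparent kurtosis and diffusivity.
    """

    def __init__(
        self,
        dwi: DWIVolume,
        mask: Optional[SegmentationMask] = None,
        sigma: float = SIGMA_DEFAULT,
        k_max: float = K_MAX_DEFAULT,
        d_max: float = D_MAX_DEFAULT,
    ):
        if mask is not None and not mask.grid.same_as(dwi.grid):
            raise ValueError("mask grid does not match the DWI grid")
        self.dwi = dwi
        self.mask = mask
        self.sigma = float(sigma)
        self.k_max = float(k_max)
        self.d_max = float(d_max)

    def fit(self) -> "KurtosisFitResults":
        dwi = smooth_dwi(self.dwi, self.sigma)
        grid = dwi.grid
        mask_arr = (
            self.mask.values
            if self.mask is not None
            else np.ones(grid.shape, dtype=bool)
        )
        flat = dwi.signal.reshape(-1, dwi.signal.shape[3])
        sel = mask_arr.ravel()
        codes = np.full(sel.size, FailureCode.OUT_OF_MASK, dtype=np.int8)
        md = np.full(sel.size, np.nan)
        mk = np.full(sel.size, np.nan)
        s0 = np.full(sel.size, np.nan)
        n_d_proj = n_k_proj = 0
        if sel.any():
            s0_m, d_app, k_app, c, n_d_proj, n_k_proj = _fit_series(
                flat[sel], dwi.scheme, self.k_max, self.d_max
            )
            codes[sel] = c
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
                md[sel] = np.mean(d_app, axis=1)
                mk[sel] = np.mean(k_app, axis=1)
            s0[sel] = s0_m
        counts = {
            FailureCode.NAMES[c]: int((codes == c).sum())
            for c in sorted(FailureCode.NAMES)
        }
        return KurtosisFitResults(
            model=self,
            md_map=ParametricMap(md.reshape(grid.shape), "MD", grid),
            mk_map=ParametricMap(mk.reshape(grid.shape), "MK", grid),
            s0_map=s0.reshape(grid.shape),
            failure_codes=codes.reshape(grid.shape),
            counts=counts,
            n_d_projected=n_d_proj,
            n_k_projected=n_k_proj,
        )


@dataclass
class KurtosisFitResults:
    """MD/MK maps plus per-voxel diagnostics from a model fit."""

    model: DiffusionKurtosisModel
    md_map: ParametricMap
    mk_map: ParametricMap
    s0_map: np.ndarray
    failure_codes: np.ndarray
    counts: Dict[str, int]
    n_d_projected: int
    n_k_projected: int

    @property
    def n_fitted(self) -> int:
        return self.counts.get("valid", 0)

    def summary(self) -> pd.DataFrame:
        """Fit diagnostics as a small table (one row per status/statistic)."""
        valid = self.failure_codes == FailureCode.VALID
        rows = [("voxels_" + k, v) for k, v in self.counts.items()]
        rows += [
            ("directions_d_projected", self.n_d_projected),
            ("directions_k_projected", self.n_k_projected),
            ("sigma_voxels", self.model.sigma),
            ("k_max", self.model.k_max),
            ("d_max", self.model.d_max),
        ]
        if valid.any():
            rows += [
                ("md_median", float(np.median(self.md_map.values[valid]))),
                ("mk_median", float(np.median(self.mk_map.values[valid]))),
            ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def fit_volume(
    dwi: DWIVolume,
    brain_mask: Optional[SegmentationMask],
    sigma: float = SIGMA_DEFAULT,
    k_max: float = K_MAX_DEFAULT,
    d_max: float = D_MAX_DEFAULT,
) -> Tuple[ParametricMap, ParametricMap]:
    """Smooth, fit every masked voxel, and return the (MD, MK) maps."""
    res = DiffusionKurtosisModel(
        dwi, brain_mask, sigma=sigma, k_max=k_max, d_max=d_max
    ).fit()
    return res.md_map, res.mk_map
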