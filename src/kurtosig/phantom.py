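"""Digital head phantom and multi-shell DWI forward simulation.

The phantom is a nested-ellipsoid "head": a brain ellipsoid whose outer shell
is gray matter and interior is white matter, two ellipsoidal CSF ventricles,
and (optionally) a spherical tumor consisting of a core and a surrounding
infiltrative rim. Every compartment is defined in world millimetres, so the
same geometry can be rendered on the coarse DKI grid and on a finer
anatomical (FLAIR-like) grid without resampling.

Each voxel carries isotropic ground-truth diffusivity MD [1e-3 mm^2/s] and
kurtosis MK [dimensionless]: class mean plus seeded Gaussian jitter truncated
at +/-3 sd (keeps each tissue cloud compact in the MK-MD plane and free of
unphysical outliers). The forward model per volume is the kurtosis signal
representation

    S(b) = S0 * exp(-b*MD + (1/6) * b^2 * MD^2 * MK),

isotropic, so every gradient direction sees the same decay. Noise is Rician:
independent Gaussian noise of width sigma on two quadrature channels,
sigma = S0_wm / SNR.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .grids import DWIVolume, Grid, SegmentationMask
from .scheme import AcquisitionScheme, B_SCALE

__all__ = [
    "TissueClass",
    "PhantomGeometry",
    "PhantomSpec",
    "PhantomTruth",
    "DEFAULT_TISSUES",
    "LABELS",
    "build_phantom",
    "simulate_dwi",
    "kurtosis_signal",
]

#: integer codes in PhantomTruth.label_volume
LABELS: Dict[str, int] = {
    "background": 0,
    "csf": 1,
    "gm": 2,
    "wm": 3,
    "tumor_rim": 4,
    "tumor_core": 5,
}
TUMOR_LABELS = (LABELS["tumor_rim"], LABELS["tumor_core"])
HEALTHY_LABELS = (LABELS["csf"], LABELS["gm"], LABELS["wm"])

#: normalisation scales used for the tumor/healthy separation check,
#: matching the default MK-MD histogram extent.
_MD_SCALE = 3.5
_MK_SCALE = 3.0


@dataclass(frozen=True)
class TissueClass:
    """Per-class ground-truth parameters. MD in 1e-3 mm^2/s, S0 arbitrary units."""

    name: str
    md: float
    mk: float
    md_sd: float = 0.03
    mk_sd: float = 0.02
    s0: float = 1000.0

    def __post_init__(self) -> None:
        if self.md <= 0:
            raise ValueError(f"{self.name}: MD mean must be > 0")
        if self.mk < 0:
            raise ValueError(f"{self.name}: MK mean must be >= 0")
        if self.md_sd < 0 or self.mk_sd < 0 or self.s0 <= 0:
            raise ValueError(f"{self.name}: invalid sd or S0")


# Healthy values are typical literature DKI figures for 3T brain; the tumor
# core/rim values sit on the extension of the healthy inverse MK-MD trend,
# far enough from the gray-matter cloud that smoothing-induced boundary
# mixtures leave the healthy occupancy region only close to the true tumor
# margin (see docs/methods.md for the derivation).
DEFAULT_TISSUES: Tuple[TissueClass, ...] = (
    TissueClass("csf", md=3.00, mk=0.15, s0=2000.0),
    TissueClass("gm", md=1.00, mk=0.70, s0=900.0),
    TissueClass("wm", md=0.80, mk=1.00, s0=800.0),
    TissueClass("tumor_rim", md=1.24, mk=0.34, s0=1000.0),
    TissueClass("tumor_core", md=1.45, mk=0.25, s0=1100.0),
)


@dataclass(frozen=True)
class PhantomGeometry:
    """Nested compartments in world mm (origin at the field-of-view centre)."""

    brain_semiaxes: Tuple[float, float, float] = (55.0, 55.0, 50.0)
    gm_thickness: float = 6.0
    ventricle_semiaxes: Tuple[float, float, float] = (6.0, 14.0, 8.0)
    ventricle_centers: Tuple[Tuple[float, float, float], ...] = (
        (10.0, 14.0, 0.0),
        (-10.0, 14.0, 0.0),
    )
    tumor_center: Tuple[float, float, float] = (18.0, -24.0, 0.0)
    tumor_core_radius: float = 16.0
    rim_thickness: float = 4.0
    include_tumor: bool = True

    @property
    def tumor_radius(self) -> float:
        """Total tumor radius (core + infiltrative rim) in mm."""
        return self.tumor_core_radius + self.rim_thickness


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to build a phantom deterministically."""

    grid_shape: Tuple[int, int, int] = (64, 64, 24)
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 5.0)
    anat_voxel_size: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    tissues: Tuple[TissueClass, ...] = DEFAULT_TISSUES
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    snr: float = 40.0
    seed: int = 0
    min_separation: float = 0.05

    def __post_init__(self) -> None:
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tissue class names")
        missing = set(LABELS) - {"background"} - set(names)
        if self.geometry.include_tumor and missing:
            raise ValueError(f"tissue table missing classes: {sorted(missing)}")
        if not (self.snr > 0 or np.isinf(self.snr)):
            raise ValueError("snr must be positive (or inf for noiseless)")
        self._check_separation()

    def tissue(self, name: str) -> TissueClass:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    def _check_separation(self) -> None:
        """Tumor classes must sit away from every healthy class in the
        normalised MK-MD plane by at least ``min_separation``."""
        if not self.geometry.include_tumor:
            return
        healthy = [t for t in self.tissues if t.name in ("csf", "gm", "wm")]
        tumor = [t for t in self.tissues if t.name in ("tumor_rim", "tumor_core")]
        for tt in tumor:
            for ht in healthy:
                d = np.hypot(
                    (tt.md - ht.md) / _MD_SCALE, (tt.mk - ht.mk) / _MK_SCALE
                )
                if d < self.min_separation:
                    raise ValueError(
                        f"tumor class {tt.name!r} lies within {self.min_separation} "
                        f"of healthy class {ht.name!r} in normalised MK-MD space"
                    )

    def healthy(self) -> "PhantomSpec":
        """The same phantom without the tumor compartment."""
        return dataclasses.replace(
            self, geometry=dataclasses.replace(self.geometry, include_tumor=False)
        )

    @property
    def anat_grid_shape(self) -> Tuple[int, int, int]:
        fov = np.array(self.grid_shape) * np.array(self.voxel_size)
        shape = np.round(fov / np.array(self.anat_voxel_size)).astype(int)
        return tuple(int(n) for n in shape)


@dataclass
class PhantomTruth:
    """Ground truth rendered on the DKI grid (plus the anatomical tumor mask)."""

    label_volume: np.ndarray
    md_truth: np.ndarray
    mk_truth: np.ndarray
    s0_truth: np.ndarray
    brain_mask: SegmentationMask
    tumor_mask_dki: SegmentationMask
    tumor_mask_anat: SegmentationMask
    grid: Grid
    spec: PhantomSpec


def _render_labels(grid: Grid, geo: PhantomGeometry) -> np.ndarray:
    """Rasterise the nested geometry by voxel-centre membership."""
    xyz = grid.voxel_centers_world()
    labels = np.zeros(grid.shape, dtype=np.int8)

    def inside_ellipsoid(center, semiaxes):
        rel = (xyz - np.asarray(center)) / np.asarray(semiaxes)
        return np.einsum("...i,...i->...", rel, rel) <= 1.0

    brain = inside_ellipsoid((0.0, 0.0, 0.0), geo.brain_semiaxes)
    inner = inside_ellipsoid(
        (0.0, 0.0, 0.0), np.asarray(geo.brain_semiaxes) - geo.gm_thickness
    )
    labels[brain] = LABELS["gm"]
    labels[inner] = LABELS["wm"]
    for c in geo.ventricle_centers:
        labels[inside_ellipsoid(c, geo.ventricle_semiaxes) & brain] = LABELS["csf"]
    if geo.include_tumor:
        dist = np.linalg.norm(xyz - np.asarray(geo.tumor_center), axis=-1)
        labels[(dist <= geo.tumor_radius) & brain] = LABELS["tumor_rim"]
        labels[(dist <= geo.tumor_core_radius) & brain] = LABELS["tumor_core"]
    return labels


def build_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render geometry and draw per-voxel ground-truth MD/MK.

    Jitter is Gaussian with the per-class sd, truncated at +/-3 sd, then
    clamped to MD > 0 and MK >= 0. The anatomical-grid tumor mask is rendered
    from the same world geometry at the finer voxel size — never resampled —
    standing in for a manual FLAIR delineation.
    """
    grid = Grid.centered(spec.grid_shape, spec.voxel_size)
    labels = _render_labels(grid, spec.geometry)

    md = np.zeros(grid.shape)
    mk = np.zeros(grid.shape)
    s0 = np.zeros(grid.shape)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    # iterate classes in fixed label order for seed-stable draws
    for name, code in sorted(LABELS.items(), key=lambda kv: kv[1]):
        if name == "background":
            continue
        sel = labels == code
        n = int(sel.sum())
        if n == 0:
            if name not in ("tumor_rim", "tumor_core"):
                continue
            if spec.geometry.include_tumor:
                raise ValueError(f"tumor compartment {name!r} rendered 0 voxels")
            continue
        t = spec.tissue(name)
        z_md = np.clip(rng.standard_normal(n), -3.0, 3.0)
        z_mk = np.clip(rng.standard_normal(n), -3.0, 3.0)
        md[sel] = np.maximum(t.md + t.md_sd * z_md, 1e-6)
        mk[sel] = np.maximum(t.mk + t.mk_sd * z_mk, 0.0)
        s0[sel] = t.s0

    if spec.geometry.include_tumor and not np.isin(labels, TUMOR_LABELS).any():
        raise ValueError("tumor volume is 0 voxels")

    anat_grid = Grid.centered(spec.anat_grid_shape, spec.anat_voxel_size)
    anat_labels = _render_labels(anat_grid, spec.geometry)

    return PhantomTruth(
        label_volume=labels,
        md_truth=md,
        mk_truth=mk,
        s0_truth=s0,
        brain_mask=SegmentationMask(labels > 0, grid, provenance="truth"),
        tumor_mask_dki=SegmentationMask(
            np.isin(labels, TUMOR_LABELS), grid, provenance="truth"
        ),
        tumor_mask_anat=SegmentationMask(
            np.isin(anat_labels, TUMOR_LABELS), anat_grid, provenance="truth"
        ),
        grid=grid,
        spec=spec,
    )


def kurtosis_signal(
    s0: np.ndarray, md: np.ndarray, mk: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Noiseless kurtosis-representation signal, broadcasting over inputs."""
    beta = np.asarray(b, dtype=float) * B_SCALE
    return np.asarray(s0) * np.exp(
        -beta * np.asarray(md) + beta**2 * np.asarray(md) ** 2 * np.asarray(mk) / 6.0
    )


def simulate_dwi(
    truth: PhantomTruth,
    scheme: AcquisitionScheme,
    snr: float = np.inf,
    seed: int = 0,
) -> DWIVolume:
    """Forward-simulate the 4D DWI signal for a phantom.

    The kurtosis representation is only monotonically decreasing in b up to
    b = 3/(MD*MK); the simulator refuses schemes whose maximum b exceeds that
    validity limit for any brain voxel. Rician noise uses
    sigma = S0(white matter) / snr; ``snr=inf`` is noiseless (float64),
    noisy output is float32.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive")
    brain = truth.brain_mask.values
    b_max = float(np.max(scheme.bvals)) * B_SCALE
    mdmk = truth.md_truth[brain] * truth.mk_truth[brain]
    if mdmk.size and b_max * float(np.max(mdmk)) > 3.0:
        raise ValueError(
            "max b-value exceeds the kurtosis representation's validity range "
            "b <= 3/(MD*MK) for some brain voxel"
        )
    signal = kurtosis_signal(
        truth.s0_truth[..., None],
        truth.md_truth[..., None],
        truth.mk_truth[..., None],
        scheme.bvals[None, None, None, :],
    )
    if np.isinf(snr):
        return DWIVolume(signal, truth.grid, scheme)

    sigma = truth.spec.tissue("wm").s0 / float(snr)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(1,)))
    shape = signal.shape
    real = signal.astype(np.float32) + sigma * rng.standard_normal(
        shape, dtype=np.float32
    )
    imag = sigma * rng.standard_normal(shape, dtype=np.float32)
    noisy = np.sqrt(real**2 + imag**2)
    return DWIVolume(noisy, truth.grid, scheme)
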