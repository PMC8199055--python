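# Methods

This note documents the models, parameter choices and numerical conventions
behind `kurtosig`, and what the synthetic phantom does and does not establish.

## 1. Signal model and estimator

Per gradient direction the multi-shell signal follows the diffusion-kurtosis
representation

S(b) = S0 · exp(−b·D + (1/6)·b²·D²·K),

where D is the apparent diffusivity along that direction (carried in 10⁻³
mm²/s, so b·D is dimensionless with b in s/mm²) and K the apparent kurtosis
coefficient — the leading-order deviation of the diffusion-induced signal
decay from mono-exponential (Gaussian) behaviour. The representation is a
truncated cumulant expansion; the predicted signal is decreasing in b only for
b ≤ 3/(D·K). Both the simulator and `predict_signal` police this limit: the
simulator refuses protocols whose maximum b exceeds it for any voxel, and the
predictor warns.

**Estimator.** Taking logs gives a model linear in (ln S0, D, W) with
W = D²K/6. For each direction the b-series (the shared b=0 volume plus one
sample per shell) is solved by unweighted linear least squares via a
precomputed pseudoinverse — every direction shares the same design matrix, so
the whole brain is fitted with one einsum. Then K = 6W/D². This is
deliberately *not* a full diffusion/kurtosis tensor fit (21 + 1 parameters):
the downstream signature uses only direction-averaged MD and MK, defined as
the arithmetic means of D and K over directions, and the per-direction
log-linear route is exact on noiseless data (machine-precision roundtrip,
asserted to ≤ 1e-9 relative error in the tests).

**Constraints.** Fitted D is projected to (0, d_max], K to [0, k_max], with
defaults d_max = 5·10⁻³ mm²/s and k_max = 3 — generous physiological ranges
whose only purpose is to keep noise-driven outliers out of the MK–MD
histogram. Projections are counted and reported in `summary()`. Voxels with
nonpositive b=0 or shell signal are not fitted at all; they carry NaN and a
failure code (`nonpositive_b0`, `nonpositive_signal`, `insufficient_data`,
`out_of_mask`).

**Smoothing.** Maps are computed "after precedent smoothing": an isotropic
(in mm) Gaussian of width sigma, specified in in-plane voxels (default 1.25,
i.e. 2.5 mm on the default 2 mm grid) and scaled per axis by voxel size. The
vendor tool the original workflow used publishes neither kernel nor estimator,
so equivalence with any particular scanner product cannot be claimed — only
self-consistency of the representation, which the phantom tests establish.
Unweighted log-domain fitting is the default; signal-squared weighting is the
obvious variant but is intentionally not implemented to keep the estimator
single-path and deterministic.

## 2. The MK–MD signature

The joint feature space is a fixed bin lattice: MD ∈ [0, 3.5] step 0.05
(10⁻³ mm²/s), MK ∈ [0, 3.0] step 0.02. The steps are small against the
distance between the tumor cluster and the healthy crescent (≳ 10 MK bins in
the default phantom) but large enough that a healthy cohort populates its
crescent without empty-bin speckle.

* **Occupancy**: control subjects' histograms are pooled (not intersected —
  pooling is conservative: a larger occupancy can only reduce false
  positives). A bin is occupied iff its pooled relative frequency is ≥ τ
  (default 10⁻⁵) and nonzero, or lies within `dilate` bins (Chebyshev,
  default 1) of such a bin. At τ = 0, dilate = 0 this degrades exactly to
  "every combination ever seen in healthy brain".
* **Signature region**: the complement of occupancy intersected with
  physiological bounds MD ∈ (0.2, 3.0], MK ∈ (0.1, 2.0] (bin-centre test).
  The bounds remove the noise-dominated margins of the plane (near-zero MD/MK
  and free-water MD) that a finite healthy cohort cannot be expected to cover.
* **Labeling**: a voxel is labeled iff valid, inside the brain mask, and its
  (MD, MK) bin is in the region; 26-connected components smaller than
  `min_cluster` (default 10) voxels are removed as noise speckle.

The original workflow identified the anomalous scatter area by expert visual
delineation and published no numeric boundary; the occupancy-complement
construction is this package's operationalisation of "does not occur in
healthy brain". One fixed region is derived from controls and applied to every
case (the alternative reading — a region drawn per patient — is available as
`manual_gate_region`, an explicit MD/MK rectangle). Whether CSF should be
excluded from the control scatters is equally unstated; `kurtosig` includes
all intracranial voxels, which again only enlarges occupancy and so errs
toward specificity.

## 3. The phantom: what it emulates

Geometry is defined in world millimetres and rasterised by voxel-centre
membership on two grids covering the same field of view: the DKI grid
(64×64×24 at 2×2×5 mm) and a finer anatomical grid (1×1×3 mm), reproducing
the slice-thickness mismatch between EPI-DKI and FLAIR that makes margin
evaluation interesting. Compartments: brain ellipsoid (gray-matter shell over
white-matter interior), two ellipsoidal CSF ventricles, and a spherical tumor
(16 mm core + 4 mm infiltrative rim) placed fully inside the brain with ≥ 5 mm
clearance from the ventricles. The anatomical-grid tumor mask is rendered from
the same geometry, never resampled — it stands in for a manual FLAIR
delineation.

Default tissue values (MD in 10⁻³ mm²/s, MK, S0 a.u.):

| class      |   MD |   MK |   S0 |
|------------|-----:|-----:|-----:|
| CSF        | 3.00 | 0.15 | 2000 |
| gray matter| 1.00 | 0.70 |  900 |
| white matter|0.80 | 1.00 |  800 |
| tumor rim  | 1.24 | 0.34 | 1000 |
| tumor core | 1.45 | 0.25 | 1100 |

Healthy values are typical 3T literature figures and reproduce the inverse
MK–MD trend of healthy brain. The tumor values were *derived*, not tuned: WM,
GM and the tumor all lie along the healthy mixture line MK = 0.7 − 1.5(MD − 1),
because any partial-volume voxel at the tumor margin is a signal mixture of
tumor and WM/GM, and its fitted (MD, MK) travels along that line. Placing the
tumor on the line's extension guarantees that margin mixtures re-enter the
healthy occupancy (rather than wandering through unoccupied feature space and
creating a detached false-positive shell around the tumor), and placing it
*far* along the line controls how deep into the tumor the mixtures stay
occupied. With the default smoothing (2.5 mm) the mixture enters the dilated
gray-matter cloud at a WM fraction of ≈ 0.36, i.e. the effective labeling
boundary sits ≈ 0.35σ ≈ 0.9 mm inside the true margin — small against the
20 mm tumor radius, hence the observed noisy Dice ≈ 0.97 against a perfect
1.0 noiseless.

Per-voxel jitter is Gaussian (sd 0.03 MD, 0.02 MK), truncated at ±3 sd and
clamped to MD > 0, MK ≥ 0. Truncation keeps every tissue cloud inside a known
box, which makes the tumor/healthy separation invariant (no tumor voxel inside
the convex hull of healthy 3-sd clouds) deterministic rather than
probabilistic. S0 is not jittered. A spec-level validator rejects tissue
tables whose tumor classes come within a configurable distance (default 0.05)
of any healthy class in the normalised MK–MD plane.

Noise is Rician — Gaussian noise of width σ = S0_WM/SNR on two quadrature
channels of the magnitude signal — with SNR defaulting to 40 at b=0 in white
matter, a typical value for 3T EPI-DWI; the protocol section of the source
study states no control-group SNR, so this is an implementer choice. Gradient
directions come from a deterministic spherical Fibonacci lattice (no iterative
electrostatic optimisation; bit-reproducible). The b=0 volume is stored once,
not once per direction — "30 directions at b=0" is physically meaningless, and
a single S0 anchor simplifies the per-direction series.

**What the phantom does not emulate**: diffusion anisotropy (no tensors —
the pipeline consumes only direction-averaged quantities), realistic anatomy,
k-space artifacts (motion, eddy currents, ghosting), Rician bias correction,
or inter-subject anatomical variability in the control group (controls differ
only in jitter seed). A green phantom test therefore establishes algorithmic
correctness and self-consistency, not clinical performance; the published
patient-cohort Dice values (≈ 0.73–0.82 across molecular subgroups) require
the original 77-patient data, which is available only on request, and are not
reproduced here.

## 4. Resampling and evaluation

Resampling is voxel-centre pull-back: each target voxel centre is mapped
through both affines into source index space. Masks use nearest neighbour
(ties round towards +∞ and clip at the field edge; points within the outer
voxel boundary ±0.5 count as in-field), scalar maps nearest or trilinear;
out-of-field voxels become False/NaN. With the default grids the
coarse→fine→coarse roundtrip is exactly the identity (the 1×1×3 mm grid
resolves every 2×2×5 mm voxel), while the fine→coarse→fine direction loses
margin detail — Dice ≈ 0.92 for a 16 mm sphere — which is the direction that
reproduces the reported divergence of automatic and manual margins across
slice thicknesses.

Dice of two same-grid masks is 2|A∩B|/(|A|+|B|); grids are never resampled
implicitly, and the both-empty case returns 1.0 with an explicit warning
rather than crashing on degenerate synthetic cases. Evaluation defaults to the
anatomical (reference-mask) grid, matching the direction in which parametric
maps were transformed onto the FLAIR matrix in the original workflow; DKI-grid
evaluation is available as a config switch.

## 5. Determinism

One global seed drives everything; stage seeds (phantom jitter per subject,
noise per acquisition) derive from it via `numpy` `SeedSequence` spawn keys
and stay below 2³¹. Identical config + seed reproduces every NIfTI and CSV
artifact byte for byte (asserted in the tests). Configs are strict-schema
YAML (unknown keys rejected, ranges validated before any stage runs) and each
run embeds a SHA-256 config hash in its artifacts and run log.
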