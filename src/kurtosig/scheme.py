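"""Multi-shell acquisition schemes (b-values and gradient directions).

A scheme indexes the 4th dimension of a DWI volume: one logical b=0 volume
(zero gradient vector) plus, for each nonzero b-value shell, one volume per
diffusion-encoding direction. The kurtosis fit needs at least three distinct
nonzero b-values along every direction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["AcquisitionScheme", "make_scheme", "fibonacci_directions"]

#: b is carried in s/mm^2 and diffusivity in 1e-3 mm^2/s; their product picks
#: up this factor so that b=1000 with D=1.0 gives a unit exponent.
B_SCALE = 1e-3

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit vectors on the sphere.

    Spherical Fibonacci lattice: point ``i`` sits at height
    ``z = 1 - (2i+1)/n`` and azimuth ``i`` times the golden angle. No
    iterative optimisation, so the set is bit-reproducible.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    # normalise defensively; the construction is already unit-norm
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values [s/mm^2] and unit gradient directions.

    b=0 volumes carry the zero vector. ``shell_index`` maps each volume to its
    shell (0 = b=0 shell, then ascending nonzero b).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must have shape (n_volumes, 3)")
        if np.any(bvals < 0):
            raise ValueError("b-values must be nonnegative")
        b0 = bvals == 0
        if not np.any(b0):
            raise ValueError("scheme has no b=0 volume (S0 anchor required)")
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(np.abs(norms[~b0] - 1.0) > 1e-6):
            raise ValueError("nonzero-b gradient directions must be unit vectors")
        if np.any(norms[b0] > 1e-12):
            raise ValueError("b=0 volumes must carry a zero gradient vector")
        if np.unique(bvals[~b0]).size < 3:
            raise ValueError(
                "kurtosis fitting needs at least 3 distinct nonzero b-values"
            )
        bvals.setflags(write=False)
        bvecs = bvecs.copy()
        bvecs.setflags(write=False)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique b-values, including 0."""
        return np.unique(self.bvals)

    @property
    def shell_index(self) -> np.ndarray:
        """Per-volume shell number (0 = b=0, ascending b)."""
        return np.searchsorted(self.shells, self.bvals)

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals == 0)

    def direction_groups(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        """Group nonzero-b volumes by gradient direction.

        Returns ``[(unit_vector, volume_indices), ...]`` in order of first
        appearance. Each group, together with the shared b=0 volume, forms the
        b-series fitted per direction.
        """
        groups: dict = {}
        order: list = []
        for v in np.flatnonzero(self.bvals > 0):
            key = tuple(np.round(self.bvecs[v], 6))
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(v)
        return [
            (np.asarray(key, dtype=float), np.asarray(groups[key], dtype=int))
            for key in order
        ]

    @property
    def n_directions(self) -> int:
        return len(self.direction_groups())


def make_scheme(b_values: Sequence[float], n_directions: int) -> AcquisitionScheme:
    """Build the default multi-shell scheme.

    One b=0 volume first, then for each nonzero b-value in ascending order the
    same ``n_directions`` Fibonacci-lattice directions. With the 6-shell
    protocol (b = 0, 500, ..., 2500 s/mm^2; 30 directions) this yields
    1 + 5*30 = 151 volumes.
    """
    b_values = sorted(float(b) for b in b_values)
    if not b_values or b_values[0] != 0.0:
        raise ValueError("b_values must include 0 (S0 anchor required)")
    if any(b < 0 for b in b_values):
        raise ValueError("b-values must be nonnegative")
    if n_directions < 6:
        raise ValueError("need at least 6 directions")
    nonzero = [b for b in b_values if b > 0]
    dirs = fibonacci_directions(n_directions)
    bvals = [0.0]
    bvecs = [np.zeros(3)]
    for b in nonzero:
        bvals.extend([b] * n_directions)
        bvecs.extend(dirs)
    return AcquisitionScheme(np.asarray(bvals), np.asarray(bvecs))
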