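"""Core volumetric containers.

All spatial data in the package is carried by two light wrappers around
numpy arrays: :class:`Bold4D` for 4-D BOLD time series and
:class:`VoxelMask` for 3-D boolean masks (brain mask, epileptogenic-zone
seed, network map, control ROI).  World coordinates in millimetres come
only from the 4x4 affine; voxel indexing is 0-based and masks live on the
native grid of the image they belong to — no resampling is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bold4D",
    "VoxelMask",
    "CorrelationMap",
    "GeometryError",
    "check_same_geometry",
]


class GeometryError(ValueError):
    """Shapes or affines of two volumes do not match."""


def _as_affine(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {a.shape}")
    if abs(np.linalg.det(a[:3, :3])) < 1e-12:
        raise ValueError("affine is singular (non-invertible)")
    return a


@dataclass
class Bold4D:
    """A 4-D BOLD image: ``values[x, y, z, t]`` plus geometry and TR.

    Parameters
    ----------
    values : ndarray, shape (X, Y, Z, T)
        BOLD intensities.  T must be at least 2.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm mapping (invertible).
    tr_s : float
        Repetition time in seconds.
    """

    values: np.ndarray
    affine: np.ndarray
    tr_s: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(f"expected 4-D array, got {self.values.ndim}-D")
        if min(self.values.shape[:3]) < 1 or self.values.shape[3] < 2:
            raise ValueError(
                f"spatial dims must be >= 1 and time dim >= 2, got {self.values.shape}"
            )
        self.affine = _as_affine(self.affine)
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.values.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def copy_with(self, values: np.ndarray) -> "Bold4D":
        return Bold4D(values=values, affine=self.affine.copy(), tr_s=self.tr_s)


@dataclass
class VoxelMask:
    """A 3-D boolean mask sharing the geometry of a :class:`Bold4D`."""

    values: np.ndarray
    affine: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {self.values.ndim}-D")
        self.affine = _as_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of member voxels, C-order."""
        return np.argwhere(self.values)

    def world_coords(self) -> np.ndarray:
        """(n, 3) world-mm coordinates of member voxel centers."""
        idx = self.indices
        hom = np.c_[idx, np.ones(len(idx))]
        return (self.affine @ hom.T).T[:, :3]

    def centroid_mm(self) -> np.ndarray:
        """Unweighted mean of member voxel-center world coordinates."""
        if self.n_voxels == 0:
            raise ValueError("centroid of an empty mask is undefined")
        return self.world_coords().mean(axis=0)


@dataclass
class CorrelationMap:
    """Voxel-wise Pearson r against a seed series.

    ``values`` holds r in [-1, 1] where defined and NaN elsewhere
    (out-of-brain voxels and in-brain voxels with zero temporal variance).
    ``defined`` marks the voxels carrying a valid r and
    ``n_zero_variance`` counts in-brain voxels excluded for having a
    constant time series.
    """

    values: np.ndarray
    defined: VoxelMask
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.defined.shape:
            raise GeometryError(
                f"map shape {self.values.shape} != defined-mask shape {self.defined.shape}"
            )
        finite = self.values[self.defined.values]
        if finite.size and (np.nanmin(finite) < -1 - 1e-9 or np.nanmax(finite) > 1 + 1e-9):
            raise ValueError("defined correlation values must lie in [-1, 1]")

    @property
    def affine(self) -> np.ndarray:
        return self.defined.affine

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined.values]


def check_same_geometry(a, b, what: str = "volumes") -> None:
    """Raise :class:`GeometryError` unless the two volumes share grid and affine."""
    sa = a.shape[:3] if len(a.shape) == 4 else a.shape
    sb = b.shape[:3] if len(b.shape) == 4 else b.shape
    if tuple(sa) != tuple(sb):
        raise GeometryError(f"{what}: spatial shapes differ ({tuple(sa)} vs {tuple(sb)})")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise GeometryError(f"{what}: affines differ")
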