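"""Seed-based correlation mapping and network definition.

The epileptogenic-zone (EZ) seed series is the unweighted spatial mean of
the seed voxels' BOLD series.  Every in-brain voxel is then correlated
with that series (Pearson r), and the negatively correlated epilepsy
network is the set of voxels with r strictly below a fixed threshold,
-0.4 by default.  A positively correlated network uses r strictly above a
threshold, by default the mean of all defined r values in the map (the
patient-specific average correlation).  Seed voxels are excluded from
both networks.

A contiguous random control ROI of configurable size (907 voxels in the
reference analysis, matching the average EZ seed size) supports the
specificity control: rerunning the whole pipeline from a random seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .images import Bold4D, CorrelationMap, GeometryError, VoxelMask, check_same_geometry

__all__ = [
    "NetworkDefinition",
    "extract_seed_timeseries",
    "correlation_map",
    "threshold_network",
    "random_control_roi",
    "NEGATIVE_THRESHOLD_DEFAULT",
]

#: Default cut for the negatively correlated network (r < -0.4).
NEGATIVE_THRESHOLD_DEFAULT = -0.4


@dataclass
class NetworkDefinition:
    """A thresholded network: member voxels, sign, and the threshold used."""

    voxels: VoxelMask
    sign: str  # "negative" | "positive"
    threshold: float
    seed_excluded: bool = True
    is_empty: bool = False

    def __post_init__(self) -> None:
        if self.sign not in ("negative", "positive"):
            raise ValueError(f"sign must be 'negative' or 'positive', got {self.sign!r}")
        if self.sign == "negative" and self.threshold > 0:
            raise ValueError("negative network requires threshold <= 0")
        self.is_empty = self.voxels.n_voxels == 0

    @property
    def n_voxels(self) -> int:
        return self.voxels.n_voxels


def extract_seed_timeseries(img: Bold4D, seed: VoxelMask) -> np.ndarray:
    """Per-timepoint spatial mean of the seed voxels' series."""
    check_same_geometry(img, seed, "image vs seed")
    if seed.n_voxels < 1:
        raise ValueError("seed mask is empty")
    return img.values[seed.values].mean(axis=0)


def correlation_map(img: Bold4D, seed_ts: np.ndarray, brain: VoxelMask) -> CorrelationMap:
    """Pearson r of every in-brain voxel's series against ``seed_ts``.

    Voxels with zero temporal variance get no r; they are marked
    undefined and counted in ``n_zero_variance``.
    """
    check_same_geometry(img, brain, "image vs brain mask")
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.shape != (img.n_timepoints,):
        raise ValueError(
            f"seed series length {seed_ts.shape} != image time dimension ({img.n_timepoints},)"
        )
    s = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0.0:
        raise ValueError("seed series has zero variance; correlation map undefined")
    s /= s_norm

    series = img.values[brain.values]  # (n_vox, T)
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    nonzero = norms > 0
    r = np.full(len(series), np.nan)
    r[nonzero] = np.clip((centered[nonzero] / norms[nonzero, None]) @ s, -1.0, 1.0)

    values = np.full(brain.shape, np.nan)
    values[brain.values] = r
    defined_vals = np.zeros(brain.shape, dtype=bool)
    defined_vals[brain.values] = nonzero
    defined = VoxelMask(defined_vals, brain.affine, label="defined")
    return CorrelationMap(values, defined, n_zero_variance=int((~nonzero).sum()))


def threshold_network(
    cmap: CorrelationMap,
    sign: str = "negative",
    threshold: float | None = None,
    seed: VoxelMask | None = None,
) -> NetworkDefinition:
    """Threshold a correlation map into a network.

    Negative sign keeps defined voxels with r strictly below the
    threshold (default -0.4); positive sign keeps voxels strictly above
    it, defaulting to the mean of all defined r values.  Ties at the
    threshold are excluded.  Seed voxels, if given, are always removed.
    An empty result is not an error: the definition comes back flagged.
    """
    if sign not in ("negative", "positive"):
        raise ValueError(f"sign must be 'negative' or 'positive', got {sign!r}")
    if threshold is None:
        if sign == "negative":
            threshold = NEGATIVE_THRESHOLD_DEFAULT
        else:
            threshold = float(np.mean(cmap.defined_values()))
    threshold = float(threshold)
    if sign == "negative" and threshold > 0:
        raise ValueError("negative-network threshold must be <= 0")

    with np.errstate(invalid="ignore"):
        if sign == "negative":
            member = cmap.values < threshold
        else:
            member = cmap.values > threshold
    member &= cmap.defined.values
    if seed is not None:
        check_same_geometry(cmap.defined, seed, "correlation map vs seed")
        member &= ~seed.values

    mask = VoxelMask(member, cmap.affine, label=f"network_{sign[:3]}")
    net = NetworkDefinition(
        voxels=mask, sign=sign, threshold=threshold, seed_excluded=seed is not None
    )
    if net.is_empty:
        warnings.warn(
            f"{sign} network is empty at threshold {threshold:g}", stacklevel=2
        )
    return net


def random_control_roi(
    brain: VoxelMask,
    region: VoxelMask,
    n_voxels: int,
    rng_seed: int = 0,
) -> VoxelMask:
    """Grow a contiguous (face-connected) random ROI of exactly
    ``n_voxels`` voxels inside ``region`` ∩ ``brain``.

    Growth starts at a uniformly chosen in-region voxel and repeatedly
    absorbs a random voxel from the face-adjacent frontier, so the shape
    is irregular but connected — a stand-in for an anatomically placed
    control seed of matched size.  Deterministic under ``rng_seed``.
    """
    check_same_geometry(brain, region, "brain vs region")
    if n_voxels < 1:
        raise ValueError("n_voxels must be positive")
    allowed = brain.values & region.values
    available = int(allowed.sum())
    if available < n_voxels:
        raise ValueError(
            f"region too small: {available} voxels available, {n_voxels} requested"
        )
    rng = np.random.default_rng(rng_seed)
    candidates = np.argwhere(allowed)
    start = tuple(candidates[rng.integers(len(candidates))])

    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    selected = np.zeros(brain.shape, dtype=bool)
    selected[start] = True
    frontier: list[tuple[int, int, int]] = []
    in_frontier = np.zeros(brain.shape, dtype=bool)

    def push_neighbors(vox):
        for dx, dy, dz in offsets:
            p = (vox[0] + dx, vox[1] + dy, vox[2] + dz)
            if all(0 <= p[i] < brain.shape[i] for i in range(3)):
                if allowed[p] and not selected[p] and not in_frontier[p]:
                    frontier.append(p)
                    in_frontier[p] = True

    push_neighbors(start)
    count = 1
    while count < n_voxels:
        if not frontier:
            raise ValueError(
                f"connected component exhausted at {count} voxels; {n_voxels} requested"
            )
        i = int(rng.integers(len(frontier)))
        vox = frontier.pop(i)
        in_frontier[vox] = False
        selected[vox] = True
        count += 1
        push_neighbors(vox)

    return VoxelMask(selected, brain.affine, label="control_roi")
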