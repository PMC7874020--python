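"""Network summary statistics: intraconnectivity and spread.

Intraconnectivity is the mean of all pairwise Pearson correlations
between *distinct* voxels inside a network (self-pairs excluded, signed
correlations — no absolute value), and is never computed against the
seed.  With unit-normalised mean-centred voxel series :math:`z_i`, the
sum of the full correlation matrix is :math:`\\lVert\\sum_i z_i\\rVert^2`,
giving the closed form

.. math:: \\bar r = \\frac{\\lVert\\sum_i z_i\\rVert^2 - N}{N(N-1)},

which equals the brute-force average over all N(N-1)/2 pairs and is
bounded below by :math:`-1/(N-1)` (positive semidefiniteness of the
correlation matrix).

Spread is the median Euclidean distance, in world millimetres, of
network voxel centers from the centroid of the seed mask.  Distances use
the affine, not index units, because acquisition voxels are anisotropic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .images import Bold4D, VoxelMask, check_same_geometry
from .mapping import NetworkDefinition

__all__ = [
    "NetworkMetrics",
    "intraconnectivity",
    "network_spread",
    "postop_connectivity",
    "compute_network_metrics",
]


@dataclass
class NetworkMetrics:
    """Per-patient summary of one network."""

    intraconnectivity: Optional[float]
    spread_mm: Optional[float]
    n_voxels: int
    n_excluded_zero_variance: int
    sign: str
    threshold: float

    def __post_init__(self) -> None:
        if self.n_voxels < 2 and self.intraconnectivity is not None:
            raise ValueError("intraconnectivity must be missing when n_voxels < 2")
        if self.n_voxels == 0 and self.spread_mm is not None:
            raise ValueError("spread_mm must be missing when the network is empty")

    def to_dict(self) -> dict:
        return {
            "intraconnectivity": self.intraconnectivity,
            "spread_mm": self.spread_mm,
            "n_voxels": self.n_voxels,
            "n_excluded_zero_variance": self.n_excluded_zero_variance,
            "sign": self.sign,
            "threshold": self.threshold,
        }


def _mean_pairwise_correlation(series: np.ndarray) -> tuple[Optional[float], int]:
    """Closed-form mean pairwise r over rows of ``series`` (n_vox, T).

    Returns ``(value, n_excluded)`` where rows with zero variance are
    excluded and counted; value is None with fewer than two usable rows.
    """
    centered = series - series.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    usable = norms > 0
    n_excluded = int((~usable).sum())
    z = centered[usable] / norms[usable, None]
    n = len(z)
    if n < 2:
        return None, n_excluded
    total = float(np.linalg.norm(z.sum(axis=0)) ** 2)
    value = (total - n) / (n * (n - 1))
    lower = -1.0 / (n - 1)
    assert lower - 1e-9 <= value <= 1.0 + 1e-9, (
        f"mean pairwise correlation {value} outside [{lower}, 1]"
    )
    return float(np.clip(value, lower, 1.0)), n_excluded


def intraconnectivity(img: Bold4D, net: NetworkDefinition) -> tuple[Optional[float], int]:
    """Mean pairwise Pearson r between distinct network voxels.

    Returns ``(value, n_excluded_zero_variance)``.  Value is None (with a
    warning) when fewer than two member voxels have nonzero variance.
    """
    check_same_geometry(img, net.voxels, "image vs network")
    series = img.values[net.voxels.values]
    value, n_excluded = _mean_pairwise_correlation(series)
    if value is None:
        warnings.warn(
            "intraconnectivity undefined: fewer than 2 usable network voxels",
            stacklevel=2,
        )
    return value, n_excluded


def network_spread(net: NetworkDefinition, seed: VoxelMask) -> Optional[float]:
    """Median Euclidean distance (mm) of network voxels from the seed
    centroid; even counts take the midpoint of the two middle order
    statistics.  None with a warning if network or seed is empty."""
    if net.voxels.n_voxels == 0 or seed.n_voxels == 0:
        warnings.warn("spread undefined: empty network or seed", stacklevel=2)
        return None
    check_same_geometry(net.voxels, seed, "network vs seed")
    centroid = seed.centroid_mm()
    coords = net.voxels.world_coords()
    dists = np.linalg.norm(coords - centroid, axis=1)
    return float(np.median(dists))


def postop_connectivity(postop_img: Bold4D, net: NetworkDefinition) -> tuple[Optional[float], int]:
    """Intraconnectivity of the *pre-operatively defined* voxel set on a
    post-operative scan.

    Voxels that have become constant post-operatively (e.g. inside a
    resection cavity) are excluded and counted, mirroring
    :func:`intraconnectivity`.
    """
    return intraconnectivity(postop_img, net)


def compute_network_metrics(
    img: Bold4D, net: NetworkDefinition, seed: VoxelMask
) -> NetworkMetrics:
    """Bundle intraconnectivity + spread for one network on one scan."""
    value, n_excl = intraconnectivity(img, net) if net.n_voxels >= 2 else (None, 0)
    spread = network_spread(net, seed) if net.n_voxels >= 1 else None
    return NetworkMetrics(
        intraconnectivity=value,
        spread_mm=spread,
        n_voxels=net.n_voxels,
        n_excluded_zero_variance=n_excl,
        sign=net.sign,
        threshold=net.threshold,
    )
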