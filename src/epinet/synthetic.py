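"""Synthetic BOLD scans, synthetic cohorts, and the published demographics table.

Real resting-state acquisitions for this analysis are not publicly
deposited, so every downstream stage is exercised on simulated data with
known ground truth.  The scan generator plants three disjoint voxel sets
on a noisy background under a one-factor model: a latent signal
:math:`s(t)` (unit-variance white Gaussian noise by default, optionally
AR(1)) drives seed voxels with loading ``w_seed``, a positively
correlated network with loading ``w_pos`` and an anticorrelated network
with loading ``w_anti`` < 0:

.. math:: x_v(t) = w\\,s(t) + \\sqrt{1 - w^2}\\,\\varepsilon_v(t)

with :math:`\\varepsilon_v` i.i.d. unit-variance white noise.  Under this
model the expected Pearson correlation between two planted voxels with
loadings :math:`w_u, w_v` is exactly :math:`w_u w_v`, so the expected
intraconnectivity of the anticorrelated network is ``w_anti**2`` — the
recovery oracle carried in :class:`GroundTruth`.

Defaults mirror the study acquisition: 4 x 3.75 x 3.75 mm voxels, TR 3 s,
a single 5-minute run (100 volumes).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .images import Bold4D, VoxelMask

__all__ = [
    "ScanSpec",
    "GroundTruth",
    "CohortSpec",
    "box_mask",
    "sphere_mask",
    "default_scan_spec",
    "generate_scan",
    "generate_cohort",
    "table1_fixture",
    "NEUROPSYCH_TESTS",
]

#: Neuropsychological tests carried by cohort tables (pre/post columns
#: are named ``<test>_pre`` / ``<test>_post``).
NEUROPSYCH_TESTS = (
    "VR-I", "VR-II", "LM-I", "LM-II", "RAVLT-6", "RAVLT-7",
    "FAS", "Animals", "BNT", "RFFT", "WAIS-IV",
)


def _default_affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def box_mask(grid_shape, corner, size, affine=None, label: str = "") -> VoxelMask:
    """Axis-aligned box of voxels: ``corner <= idx < corner + size``."""
    vals = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    vals[sl] = True
    if affine is None:
        affine = np.eye(4)
    return VoxelMask(vals, affine, label=label)


def sphere_mask(grid_shape, center, radius_vox: float, affine=None, label: str = "") -> VoxelMask:
    """Sphere in index space: voxels within ``radius_vox`` of ``center``."""
    grids = np.indices(grid_shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    if affine is None:
        affine = np.eye(4)
    return VoxelMask(d2 <= radius_vox**2, affine, label=label)


@dataclass
class ScanSpec:
    """Full description of a synthetic scan.

    ``w_anti`` in [-1, 0) is the loading of anticorrelated-network voxels
    on the latent signal, ``w_pos`` in (0, 1] the positive-network
    loading, and ``w_seed`` in (0, 1] the seed loading.  ``noise_sd``
    scales the background noise; ``background_offset`` (default 100)
    keeps the global mean positive so grand-mean scaling is well-defined.
    """

    grid_shape: tuple[int, int, int]
    seed_region: VoxelMask
    anti_network_region: VoxelMask
    pos_network_region: VoxelMask
    voxel_size_mm: tuple[float, float, float] = (4.0, 3.75, 3.75)
    n_timepoints: int = 100
    tr_s: float = 3.0
    w_anti: float = -0.7
    w_pos: float = 0.5
    w_seed: float = 0.9
    noise_sd: float = 1.0
    background_offset: float = 100.0
    ar1_coef: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm entries must be positive")
        if self.n_timepoints < 2 or self.tr_s <= 0:
            raise ValueError("need n_timepoints >= 2 and tr_s > 0")
        if not (-1.0 <= self.w_anti < 0.0):
            raise ValueError("w_anti must lie in [-1, 0)")
        if not (0.0 < self.w_pos <= 1.0):
            raise ValueError("w_pos must lie in (0, 1]")
        if not (0.0 < self.w_seed <= 1.0):
            raise ValueError("w_seed must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (-1.0 < self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must lie in (-1, 1)")
        regions = {
            "seed_region": self.seed_region,
            "anti_network_region": self.anti_network_region,
            "pos_network_region": self.pos_network_region,
        }
        for name, m in regions.items():
            if m.shape != tuple(self.grid_shape):
                raise ValueError(f"{name} shape {m.shape} != grid_shape {self.grid_shape}")
        names = list(regions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if np.any(regions[a].values & regions[b].values):
                    raise ValueError(f"regions overlap: {a} and {b}")

    @property
    def affine(self) -> np.ndarray:
        return _default_affine(self.voxel_size_mm)


@dataclass
class GroundTruth:
    """What was planted: the latent series, the member masks, and the
    model-implied anti-network intraconnectivity (= ``w_anti**2``)."""

    latent_signal: np.ndarray
    anti_voxels: VoxelMask
    pos_voxels: VoxelMask
    seed_voxels: VoxelMask
    expected_anti_intraconnectivity: float


def default_scan_spec(
    grid_shape=(20, 20, 20),
    seed_corner=(2, 2, 2),
    seed_size=(3, 3, 3),
    anti_corner=(12, 8, 8),
    anti_size=(5, 5, 8),
    pos_corner=(2, 12, 12),
    pos_size=(4, 4, 4),
    **overrides,
) -> ScanSpec:
    """A ready-made spec: 27-voxel seed, 200-voxel anticorrelated network,
    64-voxel positive network on a 20^3 grid.  Keyword overrides are
    forwarded to :class:`ScanSpec`."""
    voxel_size = overrides.pop("voxel_size_mm", (4.0, 3.75, 3.75))
    aff = _default_affine(voxel_size)
    spec = ScanSpec(
        grid_shape=grid_shape,
        seed_region=box_mask(grid_shape, seed_corner, seed_size, aff, "seed"),
        anti_network_region=box_mask(grid_shape, anti_corner, anti_size, aff, "anti"),
        pos_network_region=box_mask(grid_shape, pos_corner, pos_size, aff, "pos"),
        voxel_size_mm=voxel_size,
        **overrides,
    )
    return spec


def _latent(rng: np.random.Generator, n: int, ar1: float) -> np.ndarray:
    s = rng.standard_normal(n)
    if ar1 != 0.0:
        out = np.empty(n)
        out[0] = s[0]
        for t in range(1, n):
            out[t] = ar1 * out[t - 1] + np.sqrt(1 - ar1**2) * s[t]
        s = out
    return s


def generate_scan(spec: ScanSpec) -> tuple[Bold4D, GroundTruth]:
    """Simulate a 4-D BOLD scan from ``spec``.

    Identical specs (including ``rng_seed``) produce bit-identical
    output.  Background voxels are ``background_offset + noise_sd * N(0,1)``
    white noise; planted voxels follow the one-factor model with their
    region's loading (on top of the same offset, which leaves all
    correlations untouched).
    """
    rng = np.random.default_rng(spec.rng_seed)
    T = spec.n_timepoints
    s = _latent(rng, T, spec.ar1_coef)

    data = spec.background_offset + spec.noise_sd * rng.standard_normal(
        (*spec.grid_shape, T)
    )
    for region, w in (
        (spec.seed_region, spec.w_seed),
        (spec.pos_network_region, spec.w_pos),
        (spec.anti_network_region, spec.w_anti),
    ):
        n = region.n_voxels
        if n == 0:
            continue
        eps = rng.standard_normal((n, T))
        series = w * s[None, :] + np.sqrt(max(0.0, 1.0 - w**2)) * eps
        data[region.values] = spec.background_offset + series

    aff = spec.affine
    img = Bold4D(data, aff, tr_s=spec.tr_s)
    truth = GroundTruth(
        latent_signal=s,
        anti_voxels=VoxelMask(spec.anti_network_region.values.copy(), aff, "anti_truth"),
        pos_voxels=VoxelMask(spec.pos_network_region.values.copy(), aff, "pos_truth"),
        seed_voxels=VoxelMask(spec.seed_region.values.copy(), aff, "seed_truth"),
        expected_anti_intraconnectivity=spec.w_anti**2,
    )
    return img, truth


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Synthetic cohort with outcome-dependent network connectivity.

    Connectivity is drawn per group from N(mean, conn_sd^2); one
    neuropsychological score (``VR-I_pre``) is a linear function of
    connectivity plus noise, so rank correlations have a known sign and,
    at zero noise, magnitude 1.  Defaults use the study's 12/7
    seizure-free split with a 2-SD group separation placed inside the
    connectivity range the analysis reports.
    """

    n_seizure_free: int = 12
    n_not_free: int = 7
    mean_conn_free: float = 0.37
    mean_conn_not_free: float = 0.21
    conn_sd: float = 0.08
    neuropsych_slope: float = 50.0
    neuropsych_noise_sd: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seizure_free < 0 or self.n_not_free < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_seizure_free + self.n_not_free < 2:
            raise ValueError("cohort must have at least 2 patients")
        if not self.conn_sd > 0:
            raise ValueError("conn_sd must be positive")
        if self.neuropsych_noise_sd < 0:
            raise ValueError("neuropsych_noise_sd must be nonnegative")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with columns id, seizure_free,
    intraconnectivity, VR-I_pre.  Reproducible under ``rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    n_free, n_not = spec.n_seizure_free, spec.n_not_free
    conn = np.concatenate([
        rng.normal(spec.mean_conn_free, spec.conn_sd, n_free),
        rng.normal(spec.mean_conn_not_free, spec.conn_sd, n_not),
    ])
    score = spec.neuropsych_slope * conn + spec.neuropsych_noise_sd * rng.standard_normal(
        n_free + n_not
    )
    return pd.DataFrame(
        {
            "id": [f"P{i + 1:02d}" for i in range(n_free + n_not)],
            "seizure_free": [True] * n_free + [False] * n_not,
            "intraconnectivity": conn,
            "VR-I_pre": score,
        }
    )


# ---------------------------------------------------------------------------
# Published demographics (19 patients with unilateral temporal lobe
# epilepsy).  Transcribed verbatim from the demographics table; the
# dominant hemisphere of patient 17 was not established (Wada not
# available) and is stored as missing.

_TABLE1_TSV = """\
id\tgender\tage\tmedications\tsurgery_side\tdominant_hemisphere\tseizure_free
1\tMale\t26\tLevetiracetam, Lamotrigine\tLeft\tLeft\tNo
2\tMale\t17\tLamotrigine\tLeft\tRight\tNo
3\tFemale\t26\tVimpat, Aptiom\tRight\tLeft\tNo
4\tFemale\t35\tCarbamazepine, Lamotrigine\tLeft\tLeft\tNo
5\tFemale\t32\tLevetiracetam, Topiramate\tLeft\tRight\tNo
6\tFemale\t40\tZonisamide\tRight\tLeft\tNo
7\tFemale\t36\tLamotrigine\tLeft\tLeft\tNo
8\tFemale\t47\tGabapentin\tLeft\tLeft\tYes
9\tMale\t23\tLevetiracetam\tLeft\tLeft\tYes
10\tFemale\t34\tLacosamide, Levetiracetam\tLeft\tRight\tYes
11\tFemale\t19\tLamotrigine, Levetiracetam, Topiramate\tRight\tLeft\tYes
12\tFemale\t40\tOxcarbazepine\tRight\tLeft\tYes
13\tMale\t26\tLacosamide, Levetiracetam, Topiramate\tLeft\tLeft\tYes
14\tFemale\t33\tBrivaracetam, Lacosamide, Lamotrigine\tLeft\tLeft\tYes
15\tMale\t32\tLacosamide\tLeft\tLeft\tYes
16\tFemale\t28\tLamotrigine, Levetiracetam, Perampanel, Zonisamide\tLeft\tLeft\tYes
17\tFemale\t24\tLevetiracetam\tLeft\tN/A\tYes
18\tMale\t25\tPerampanel, Oxcarbazepine\tLeft\tLeft\tYes
19\tFemale\t53\tLamotrigine\tLeft\tLeft\tYes
"""


def table1_fixture() -> pd.DataFrame:
    """The 19-patient demographics table as a DataFrame.

    ``seizure_free`` is parsed to boolean; a missing dominant hemisphere
    (recorded as "N/A" in print) becomes NaN.
    """
    df = pd.read_csv(
        io.StringIO(_TABLE1_TSV), sep="\t", dtype={"id": str},
        na_values=["N/A"], keep_default_na=False,
    )
    df["seizure_free"] = df["seizure_free"].map({"Yes": True, "No": False})
    df["age"] = df["age"].astype(int)
    return df
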