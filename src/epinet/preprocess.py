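"""Signal conditioning: volumetric smoothing, grand-mean scaling, EEG filters.

Motion correction and MNI normalisation are deliberately not implemented:
inputs are assumed co-registered, and the pipeline only asserts that
pre/post volumes share grid and affine.  Pearson correlation is invariant
to the grand-mean scaling step, so the scaling exists to standardise
intensities across scans, not to change any connectivity number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .images import Bold4D, VoxelMask, check_same_geometry

__all__ = [
    "EegRecording",
    "gaussian_smooth",
    "grand_mean_scale",
    "bandpass_eeg",
    "notch_eeg",
    "fwhm_to_sigma",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian kernel.
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm / _FWHM_FACTOR


def gaussian_smooth(img: Bold4D, fwhm_mm: float) -> Bold4D:
    """Smooth each volume with an isotropic-in-mm Gaussian kernel.

    The kernel standard deviation is ``fwhm_mm / (2 sqrt(2 ln 2))``,
    converted per axis to voxel units, so anisotropic voxels (e.g. the
    4 x 3.75 x 3.75 mm acquisition) still receive an isotropic smooth in
    world space.  Boundary handling is reflect padding; the kernel is
    truncated at 4 sigma.
    """
    if not fwhm_mm > 0:
        raise ValueError("fwhm_mm must be positive")
    if not np.all(np.isfinite(img.values)):
        bad = np.argwhere(~np.isfinite(img.values))[0]
        raise ValueError(f"non-finite value at voxel (x,y,z,t)={tuple(int(i) for i in bad)}")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / img.voxel_size_mm
    out = ndimage.gaussian_filter(
        img.values, sigma=(*sigma_vox, 0.0), mode="reflect", truncate=4.0
    )
    return img.copy_with(out)


def grand_mean_scale(img: Bold4D, brain: VoxelMask, target: float = 100.0) -> Bold4D:
    """Rescale so the mean over in-brain voxels and all timepoints equals
    ``target``.  Idempotent; leaves every Pearson correlation unchanged."""
    if not target > 0:
        raise ValueError("target must be positive")
    check_same_geometry(img, brain, "image vs brain mask")
    if brain.n_voxels < 1:
        raise ValueError("brain mask is empty")
    in_mask = img.values[brain.values]
    grand_mean = float(in_mask.mean())
    # mean indistinguishable from zero at float precision => undefined scale
    if abs(grand_mean) <= 1e-12 * max(1.0, float(np.abs(in_mask).max())):
        raise ValueError("global in-mask mean is zero; grand-mean scaling undefined")
    return img.copy_with(img.values * (target / grand_mean))


# ---------------------------------------------------------------------------
# EEG


@dataclass
class EegRecording:
    """Multichannel EEG: ``data[sample, channel]`` at ``sampling_rate_hz``."""

    data: np.ndarray
    sampling_rate_hz: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (samples x channels)")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[1]))
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match number of channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def bandpass_eeg(rec: EegRecording, low_hz: float = 1.0, high_hz: float = 100.0) -> EegRecording:
    """Zero-phase Butterworth band-pass (4th-order recursive, applied
    forward-backward), default 1-100 Hz."""
    nyq = rec.sampling_rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(2, [low_hz, high_hz], btype="bandpass",
                        fs=rec.sampling_rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=0)
    return EegRecording(out, rec.sampling_rate_hz, rec.channel_names)


def notch_eeg(rec: EegRecording, freq_hz: float = 60.0, quality: float = 30.0) -> EegRecording:
    """Zero-phase IIR notch (quality factor 30) at mains frequency."""
    nyq = rec.sampling_rate_hz / 2.0
    if not (0 < freq_hz < nyq):
        raise ValueError(f"notch frequency {freq_hz} Hz must lie below Nyquist ({nyq} Hz)")
    b, a = signal.iirnotch(freq_hz, quality, fs=rec.sampling_rate_hz)
    out = signal.filtfilt(b, a, rec.data, axis=0)
    return EegRecording(out, rec.sampling_rate_hz, rec.channel_names)
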