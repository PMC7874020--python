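"""File I/O: NIfTI-1 volumes and masks, tab-delimited cohort tables,
JSON sidecars, and delimited EEG text.

EEG is accepted as delimited text with one channel per column and a
``# sampling_rate_hz: <value>`` header line; no clinical EEG dialect is
required because everything past filtering is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .images import Bold4D, VoxelMask
from .preprocess import EegRecording

__all__ = [
    "load_bold", "save_bold",
    "load_mask", "save_mask",
    "save_correlation_map",
    "load_cohort_table", "save_cohort_table",
    "load_eeg_text", "save_eeg_text",
    "save_json", "load_json",
]


def load_bold(path, tr_s: float | None = None) -> Bold4D:
    """Read a 4-D NIfTI; TR comes from the header zooms unless given."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D BOLD image, got {data.ndim}-D")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 3.0
    return Bold4D(data, img.affine, tr_s=tr_s)


def save_bold(img: Bold4D, path) -> None:
    nii = nib.Nifti1Image(img.values.astype(np.float32), img.affine)
    nii.header.set_zooms((*img.voxel_size_mm, img.tr_s))
    nii.to_filename(str(path))


def load_mask(path, label: str = "") -> VoxelMask:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    return VoxelMask(data > 0.5, img.affine, label=label)


def save_mask(mask: VoxelMask, path) -> None:
    nib.Nifti1Image(mask.values.astype(np.uint8), mask.affine).to_filename(str(path))


def save_correlation_map(cmap, path) -> None:
    """Correlation map as NIfTI with undefined voxels stored as NaN."""
    nib.Nifti1Image(cmap.values.astype(np.float32), cmap.affine).to_filename(str(path))


def load_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})


def save_cohort_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


def save_eeg_text(rec: EegRecording, path) -> None:
    header = (
        f"# sampling_rate_hz: {rec.sampling_rate_hz}\n"
        + "\t".join(rec.channel_names)
    )
    np.savetxt(str(path), rec.data, delimiter="\t", header=header, comments="")


def load_eeg_text(path) -> EegRecording:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# sampling_rate_hz:"):
            raise ValueError(f"{path}: missing '# sampling_rate_hz:' header line")
        fs = float(first.split(":", 1)[1])
        names = tuple(fh.readline().strip().split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return EegRecording(data, fs, names)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")
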