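"""Volume and label-volume I/O, resampling, and feature-table serialization.

Volumes are carried as plain dataclasses holding a 3D array, voxel spacing
in mm, and the 4x4 voxel-to-world affine.  All images are reoriented to the
closest canonical (RAS) axis order on load so that the plane names used by
the texture encoder (xy, xz, yz) mean the same thing for every input file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Finite scalar intensities (arbitrary units) or probabilities.
    spacing : ndarray, shape (3,)
        Voxel edge lengths in mm, strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-coordinate transform.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default=None)
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 3:
            raise ValueError(f"every axis needs >= 3 voxels, got shape {self.data.shape}")
        if self.spacing is None:
            self.spacing = np.ones(3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self):
        return self.data.shape

    def is_isotropic(self, rtol: float = 1e-6) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=rtol))


@dataclass
class LabelVolume:
    """A 3D integer label image; 0 is background, positive values are regions."""

    labels: np.ndarray
    spacing: np.ndarray = field(default=None)
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got {arr.ndim}D")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.all(np.abs(arr - rounded) <= 1e-6):
                raise ValueError("label volume has non-integer values beyond tolerance 1e-6")
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if arr.min() < 0:
            raise ValueError("label volume has negative labels")
        self.labels = arr
        if self.spacing is None:
            self.spacing = np.ones(3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def region_labels(self) -> np.ndarray:
        """Sorted distinct positive labels (never renumbered)."""
        labs = np.unique(self.labels)
        return labs[labs > 0]


def check_aligned(volume: Volume, atlas: LabelVolume) -> None:
    """Raise if a volume and label volume do not share shape/spacing/affine."""
    if volume.shape != atlas.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs labels {atlas.shape}")
    if not np.allclose(volume.spacing, atlas.spacing, rtol=1e-6):
        raise ValueError(f"spacing mismatch: {volume.spacing} vs {atlas.spacing}")
    if not np.allclose(volume.affine, atlas.affine, atol=1e-4):
        raise ValueError("affine mismatch between volume and label volume")


def _load_canonical(path):
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, file has {data.ndim} dimensions")
    affine = img.affine
    spacing = nib.affines.voxel_sizes(affine)
    return data, spacing, affine


def read_volume(path, on_non_finite: str = "error") -> Volume:
    """Load a 3D NIfTI scalar image into canonical (RAS) orientation.

    ``on_non_finite`` is ``"error"`` (default) or ``"zero"``: replace NaN/Inf
    voxels with 0 and emit a warning with the count.
    """
    data, spacing, affine = _load_canonical(path)
    data = np.asarray(data, dtype=np.float64)
    bad = ~np.isfinite(data)
    if bad.any():
        if on_non_finite == "zero":
            warnings.warn(f"{path}: zero-filled {int(bad.sum())} non-finite voxels")
            data = np.where(bad, 0.0, data)
        else:
            raise ValueError(f"{path}: {int(bad.sum())} non-finite voxels (set on_non_finite='zero' to fill)")
    return Volume(data, spacing, affine)


def read_label_volume(path) -> LabelVolume:
    """Load a NIfTI parcellation/mask; values must be (nearly) integer."""
    data, spacing, affine = _load_canonical(path)
    return LabelVolume(np.asarray(data), spacing, affine)


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


def write_label_volume(atlas: LabelVolume, path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), atlas.affine)
    img.header.set_zooms(tuple(atlas.spacing))
    nib.save(img, str(path))


def _resample_grid(shape, spacing, target_spacing):
    target_spacing = np.asarray(target_spacing, dtype=np.float64).reshape(3)
    if np.any(target_spacing <= 0):
        raise ValueError("target spacing must be strictly positive")
    scale = target_spacing / np.asarray(spacing, dtype=np.float64)
    # cover the same world extent; trailing partial voxels are dropped
    new_shape = np.maximum(np.floor(np.asarray(shape) / scale + 1e-9).astype(int), 1)
    return new_shape, scale, target_spacing


def _lerp_axis(arr: np.ndarray, coords: np.ndarray, axis: int) -> np.ndarray:
    """1D linear interpolation along one axis at the given fractional coords.

    Uses the a + f*(b - a) form, which is exact (no rounding drift) wherever
    the two bracketing samples are equal — so constant volumes survive
    resampling bit-for-bit.
    """
    n = arr.shape[axis]
    idx = np.floor(coords).astype(int)
    frac = coords - idx
    idx0 = np.clip(idx, 0, n - 1)
    idx1 = np.clip(idx + 1, 0, n - 1)
    a = np.take(arr, idx0, axis=axis)
    b = np.take(arr, idx1, axis=axis)
    shape = [1, 1, 1]
    shape[axis] = len(coords)
    f = frac.reshape(shape)
    return a + f * (b - a)


def resample_volume(volume: Volume, target_spacing_mm, mode: str = "linear") -> Volume:
    """Resample onto an axis-aligned grid with the requested spacing.

    ``linear`` interpolates trilinearly (separable per-axis lerp);
    ``nearest`` takes the closest source voxel (mandatory for label
    payloads).  Output voxel (0,0,0) keeps the world position of the input
    voxel (0,0,0); the grid drops any trailing partial voxel rather than
    padding.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    new_shape, scale, target_spacing = _resample_grid(volume.shape, volume.spacing, target_spacing_mm)
    data = volume.data
    if mode == "linear":
        for axis in range(3):
            data = _lerp_axis(data, np.arange(new_shape[axis]) * scale[axis], axis)
    else:
        for axis in range(3):
            idx = np.clip(np.rint(np.arange(new_shape[axis]) * scale[axis]).astype(int),
                          0, data.shape[axis] - 1)
            data = np.take(data, idx, axis=axis)
    new_affine = volume.affine @ np.diag([*scale, 1.0])
    return Volume(data, target_spacing, new_affine)


def resample_label_volume(atlas: LabelVolume, target_spacing_mm) -> LabelVolume:
    """Nearest-neighbor resampling of a label volume (labels never blended)."""
    new_shape, scale, target_spacing = _resample_grid(atlas.shape, atlas.spacing, target_spacing_mm)
    labels = atlas.labels
    for axis in range(3):
        idx = np.clip(np.rint(np.arange(new_shape[axis]) * scale[axis]).astype(int),
                      0, labels.shape[axis] - 1)
        labels = np.take(labels, idx, axis=axis)
    new_affine = atlas.affine @ np.diag([*scale, 1.0])
    return LabelVolume(labels, target_spacing, new_affine)


def _column_name(region, plane, bin_idx) -> str:
    return f"r{int(region)}|{plane}|b{int(bin_idx)}"


def _parse_column(name: str):
    region, plane, bin_idx = name.split("|")
    return int(region[1:]), plane, int(bin_idx[1:])


def write_feature_table(features: np.ndarray, index, subject_ids, path) -> None:
    """Write a subjects x features matrix as TSV.

    ``index`` is the ordered list of (region_label, plane, bin) triples for
    the columns; the header encodes each triple as ``r<label>|<plane>|b<bin>``.
    Full float precision (shortest round-trip repr), so read/write is lossless.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != len(index):
        raise ValueError(f"feature matrix shape {features.shape} does not match {len(index)} column labels")
    cols = [_column_name(*triple) for triple in index]
    df = pd.DataFrame(features, columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path):
    """Read a feature TSV back; returns (matrix, index triples, subject ids)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    subject_ids = df["subject_id"].tolist()
    cols = [c for c in df.columns if c != "subject_id"]
    index = [_parse_column(c) for c in cols]
    return df[cols].to_numpy(dtype=np.float64), index, subject_ids


def read_subject_labels(path) -> pd.DataFrame:
    """Read a subject-label TSV with columns subject_id, class (0/1)."""
    df = pd.read_csv(path, sep="\t")
    if not {"subject_id", "class"}.issubset(df.columns):
        raise ValueError("label file needs columns 'subject_id' and 'class'")
    return df


def write_subject_labels(subject_ids, classes, path) -> None:
    pd.DataFrame({"subject_id": list(subject_ids), "class": list(classes)}).to_csv(
        path, sep="\t", index=False
    )
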