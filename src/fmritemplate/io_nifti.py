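"""NIfTI I/O: 4D fMRI loading, slice-sequence decomposition, template output.

Axis convention used throughout the package: NIfTI order (x, y, z, t).  A
"slice" is ``data[:, :, k, i]`` treated as a 2D array indexed (x, y) with
0-based pixel coordinates; x is the first array axis.  All registration and
fusion happen in this pixel grid — world-space (mm) coordinates are carried
through unchanged in the affine and never used for resampling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List

import nibabel as nib
import numpy as np
from PIL import Image


@dataclass
class FmriSequence:
    """A 4D fMRI time series with its spatial metadata.

    ``frame_ids`` records the original time indices of the retained frames so
    that preprocessing (leading-frame discard, motion scrubbing) keeps an
    audit trail back to the acquisition.
    """

    data: np.ndarray
    affine: np.ndarray
    frame_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected 4D (x, y, z, t) data, got {self.data.ndim}D"
            )
        if self.data.shape[3] < 2:
            raise ValueError("a time series needs at least 2 frames")
        if self.data.shape[2] < 1:
            raise ValueError("need at least one z-layer")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite intensities in 4D data")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.data.shape[3])
        else:
            self.frame_ids = np.asarray(self.frame_ids, dtype=int)
            if self.frame_ids.shape != (self.data.shape[3],):
                raise ValueError("frame_ids must have one entry per frame")
            if np.any(np.diff(self.frame_ids) <= 0):
                raise ValueError("frame_ids must be strictly increasing")

    @property
    def frame_count(self) -> int:
        return self.data.shape[3]

    @property
    def layer_count(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine's column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class SliceSequence:
    """All time points of one z-layer, as an ordered list of 2D frames."""

    layer_index: int
    frames: List[np.ndarray]
    frame_ids: np.ndarray

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames of layer {self.layer_index} differ in shape")
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        if len(self.frame_ids) != len(self.frames):
            raise ValueError("frame_ids must align with frames")
        if np.any(np.diff(self.frame_ids) <= 0):
            raise ValueError("frame_ids must be strictly increasing")

    @property
    def frame_count(self) -> int:
        return len(self.frames)


@dataclass
class TemplateVolume:
    """The fused 3D template plus the metadata needed to reuse it."""

    data: np.ndarray
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("template data must be 3D")
        self.affine = np.asarray(self.affine, dtype=float)


def load_4d(path: str, nan: str = "error") -> FmriSequence:
    """Load a 4D NIfTI file as an :class:`FmriSequence`.

    Parameters
    ----------
    path:
        A ``.nii`` / ``.nii.gz`` file with exactly 4 dimensions.
    nan:
        ``"error"`` (default) fails on NaN/Inf voxels; ``"zero"`` replaces
        them with 0.  Silent NaNs would poison the image gradients used by
        feature detection, so there is no pass-through option.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error wording varies
        raise ValueError(f"unreadable NIfTI header in {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"expected 4D fMRI data in {path}, got {data.ndim}D image"
        )
    bad = ~np.isfinite(data)
    if bad.any():
        if nan == "zero":
            data = np.where(bad, 0.0, data)
        else:
            raise ValueError(
                f"{bad.sum()} non-finite voxels in {path}; "
                "pass nan='zero' to zero-fill"
            )
    return FmriSequence(data=data, affine=np.asarray(img.affine))


def extract_slice_sequences(seq: FmriSequence) -> List[SliceSequence]:
    """Decompose a 4D series into one :class:`SliceSequence` per z-layer.

    Restacking the outputs reconstructs ``seq.data`` exactly.
    """
    out = []
    for k in range(seq.layer_count):
        frames = [seq.data[:, :, k, i] for i in range(seq.frame_count)]
        out.append(SliceSequence(layer_index=k, frames=frames,
                                 frame_ids=seq.frame_ids.copy()))
    return out


def save_template(tpl: TemplateVolume, path: str) -> None:
    """Write a template as a 3D NIfTI file (float32 storage)."""
    img = nib.Nifti1Image(tpl.data.astype(np.float32), tpl.affine)
    nib.save(img, path)


def load_template(path: str) -> TemplateVolume:
    """Load a 3D NIfTI file written by :func:`save_template`."""
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected 3D template in {path}, got {data.ndim}D")
    return TemplateVolume(data=data, affine=np.asarray(img.affine))


def export_slices_png(tpl: TemplateVolume, out_dir: str) -> List[str]:
    """Write one 8-bit grayscale PNG per z-layer, min-max scaled per volume.

    A constant-intensity volume has zero dynamic range and exports as
    all-zero images.
    """
    os.makedirs(out_dir, exist_ok=True)
    lo, hi = float(tpl.data.min()), float(tpl.data.max())
    span = hi - lo
    paths = []
    for k in range(tpl.data.shape[2]):
        sl = tpl.data[:, :, k]
        if span > 0:
            scaled = np.round((sl - lo) / span * 255.0)
        else:
            scaled = np.zeros_like(sl)
        path = os.path.join(out_dir, f"layer_{k:03d}.png")
        Image.fromarray(scaled.astype(np.uint8), mode="L").save(path)
        paths.append(path)
    return paths


def normalize_slice(slice2d: np.ndarray) -> np.ndarray:
    """Min-max scale a slice to [0, 1] for the feature pipeline.

    Fusion operates on original intensities; only detection/description use
    this bounded scale (the contrast and edge thresholds assume it).
    A constant slice maps to all zeros.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    lo, hi = slice2d.min(), slice2d.max()
    if hi > lo:
        return (slice2d - lo) / (hi - lo)
    return np.zeros_like(slice2d)


def load_motion_table(path: str) -> np.ndarray:
    """Read a whitespace-delimited motion-parameter table.

    One row per frame, 6 columns: 3 translations (mm), 3 rotations (deg).
    """
    table = np.loadtxt(path, dtype=float)
    table = np.atleast_2d(table)
    if table.shape[1] != 6:
        raise ValueError(
            f"motion table must have 6 columns, got {table.shape[1]}"
        )
    return table
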