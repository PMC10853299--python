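"""Volume and mask containers, NIfTI round-trip IO, grid compatibility checks.

All analysis downstream is purely voxel-based (intensities and lattice
connectivity), so the affine is carried losslessly but never used to
reorient or resample; co-registered inputs on a shared grid are assumed
and enforced by :func:`check_compatible`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "binarize",
    "check_compatible",
]

AFFINE_TOL = 1e-5


@dataclass
class Volume:
    """A 3D scalar image with its voxel-to-world affine.

    Attributes
    ----------
    data : ndarray
        3D array of finite intensities.
    affine : ndarray
        4x4 voxel-to-world transform (stored as given; orientation never
        affects any computation here).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN or infinite voxels")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel spacings must be strictly positive")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis spacing in mm, derived from the affine column norms."""
        return np.asarray(nib.affines.voxel_sizes(self.affine), dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class BinaryMask(Volume):
    """A Volume whose values are exactly {0, 1}, stored as uint8."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        uniq = np.unique(self.data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        self.data = self.data.astype(np.uint8)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def read_volume(path) -> Volume:
    """Load a 3D NIfTI image; rejects non-3D shapes and NaN voxels."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume(data=data, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(volume.data.astype(np.float64), volume.affine), str(path))


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(data=vol.data, affine=vol.affine)


def write_mask(mask: BinaryMask, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def binarize(prob_map: Volume, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map: voxel = 1 iff value >= threshold.

    The bound is inclusive ("lower threshold" semantics): a voxel whose
    probability equals the threshold is kept.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryMask(data=(prob_map.data >= threshold).astype(np.uint8),
                      affine=prob_map.affine)


def check_compatible(*volumes: Volume) -> None:
    """Raise unless all volumes share shape and affine (tolerance 1e-5)."""
    if len(volumes) < 2:
        raise ValueError("need at least two volumes to compare")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if v.shape != ref.shape:
            raise ValueError(
                f"grid mismatch between volume 0 and volume {i}: "
                f"shapes {ref.shape} vs {v.shape}"
            )
        if not np.allclose(v.affine, ref.affine, atol=AFFINE_TOL):
            raise ValueError(
                f"affine mismatch between volume 0 and volume {i} "
                f"(tolerance {AFFINE_TOL})"
            )
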