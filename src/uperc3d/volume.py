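"""Volumetric image container and I/O.

All modules in the package operate on :class:`Volume3D`: a single-channel 3D
intensity array in (z, y, x) axis order (0-based), stored as float32, with
voxel spacing in mm per axis.  NIfTI-1 (.nii/.nii.gz) is the primary on-disk
container; 3D multi-page TIFF is accepted for phantoms.

NIfTI stores data (x, y, z); arrays are transposed on read/write so the
in-memory convention is always (z, y, x) and round trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Volume3D", "read_volume", "write_volume", "normalize_intensity"]


@dataclass
class Volume3D:
    """A single-channel 3D intensity volume.

    Parameters
    ----------
    data : ndarray
        3D array, axis order (z, y, x).  Stored as float32.
    spacing : tuple of float
        Voxel size in mm per (z, y, x) axis.  Default isotropic 1.0 mm.
    meta : dict
        Free-form metadata (e.g. phantom foreground fraction).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got rank {arr.ndim}")
        if any(s < 1 for s in arr.shape):
            raise ValueError(f"every axis must have size >= 1, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("Volume3D intensities must be finite")
        self.data = arr.astype(np.float32, copy=False)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have 3 entries (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def max(self) -> float:
        return float(self.data.max())

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing, dict(self.meta))


def read_volume(path) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) or 3D TIFF volume.

    Spacing is taken from the file header (NIfTI zooms; 1.0 mm for TIFF);
    intensities are returned unmodified.  A file whose content is not rank 3
    raises ``ValueError`` naming the observed rank.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # unreadable / wrong magic
            raise ValueError(f"not a readable NIfTI file: {path}") from exc
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, file has rank {arr.ndim}")
        zooms = img.header.get_zooms()[:3]  # (x, y, z)
        return Volume3D(np.ascontiguousarray(arr.T), spacing=tuple(reversed(zooms)))
    if name.endswith((".tif", ".tiff")):
        import tifffile

        try:
            arr = tifffile.imread(str(path))
        except Exception as exc:
            raise ValueError(f"not a readable TIFF file: {path}") from exc
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, file has rank {arr.ndim}")
        return Volume3D(arr)
    raise ValueError(f"unsupported volume format: {path} (expected .nii, .nii.gz, .tif)")


def write_volume(vol: Volume3D, path) -> None:
    """Write ``vol`` to NIfTI or TIFF; header spacing equals ``vol.spacing``."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(reversed(vol.spacing)) + [1.0])
        img = nib.Nifti1Image(vol.data.T, affine)
        img.header.set_zooms(tuple(reversed(vol.spacing)))
        nib.save(img, str(path))
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), vol.data, photometric="minisblack")
    else:
        raise ValueError(f"unsupported volume format: {path}")


def normalize_intensity(vol: Volume3D) -> Volume3D:
    """Scale intensities so the maximum equals 1.0 (per-volume max normalization).

    All-zero volumes are returned unchanged; negative intensities raise
    ``ValueError`` (MR magnitude images are nonnegative).  Idempotent.
    """
    if vol.data.min() < 0:
        raise ValueError("negative intensities: magnitude images must be nonnegative")
    m = vol.data.max()
    if m == 0:
        return vol.copy()
    return Volume3D(vol.data / m, vol.spacing, dict(vol.meta))
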