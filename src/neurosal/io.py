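"""NIfTI-1 volume I/O helpers (thin wrappers over nibabel)."""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume"]


def save_volume(data: np.ndarray, path: Path, voxel_mm: float = 1.0,
                integer: bool = False) -> Path:
    """Write a 3D array as NIfTI-1 with an isotropic diagonal affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data, dtype=np.int16 if integer else np.float32)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return path


def load_volume(path: Path) -> Tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (array, isotropic voxel size in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    return data, float(zooms[0])
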