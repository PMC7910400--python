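"""NIfTI-1 read/write for petquant images (via nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InvalidSpecError
from .phantom_sim import GridSpec, Image3D, Image4D


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def write_nifti(img: Image3D | Image4D, path: str | Path) -> Path:
    """Write an image as NIfTI-1 with correct pixdim and origin."""
    path = Path(path)
    nii = nib.Nifti1Image(np.asarray(img.values, dtype=np.float32), _affine(img.grid))
    nii.header.set_xyzt_units("mm", "sec")
    nib.save(nii, str(path))
    return path


def read_nifti(path: str | Path, schedule=None) -> Image3D | Image4D:
    """Read a NIfTI file into an Image3D (or Image4D when a frame
    schedule is supplied for 4-D data).

    Requires an axis-aligned affine (no rotation/shear), matching the
    package's world-mm voxel-center convention.
    """
    nii = nib.load(str(path))
    aff = nii.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise InvalidSpecError(f"{path}: only axis-aligned affines are supported")
    voxel = np.diag(aff[:3, :3])
    if np.any(voxel <= 0):
        raise InvalidSpecError(f"{path}: voxel sizes must be positive")
    data = np.asanyarray(nii.dataobj).astype(float)
    shape = data.shape[:3]
    grid = GridSpec(
        matrix=tuple(int(n) for n in shape),
        in_plane_fov=float(voxel[0] * shape[0]),
        slice_thickness=float(voxel[2]),
        origin=tuple(float(v) for v in aff[:3, 3]),
    )
    if not np.isclose(grid.voxel_size[1], voxel[1], rtol=1e-6):
        raise InvalidSpecError(f"{path}: anisotropic in-plane voxels are not supported")
    if data.ndim == 3:
        return Image3D(data, grid)
    if data.ndim == 4:
        if schedule is None:
            raise InvalidSpecError("4-D NIfTI requires a frame schedule")
        return Image4D(data, grid, schedule)
    raise InvalidSpecError(f"{path}: unsupported dimensionality {data.ndim}")
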