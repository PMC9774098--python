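"""Interpolate per-contact SOZ probabilities onto a voxel grid.

The rendering convention: brain-boundary voxels take the lowest predicted
probability; voxels within a small neighborhood of a contact take that
contact's probability (nearest contact wins on overlap); every other
in-brain voxel is a Gaussian-kernel weighted convex combination of the
contact probabilities and the boundary value, so the map never overshoots
the range spanned by those anchors.  Output is written as NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelMap",
    "scores_to_voxelmap",
    "write_volume",
    "read_volume",
    "ellipsoid_mask",
]


@dataclass
class VoxelMap:
    """A scalar probability volume with its voxel-to-mm affine."""

    grid: np.ndarray  # 3-D float
    affine: np.ndarray  # 4x4
    mask: np.ndarray  # 3-D bool brain mask

    def __post_init__(self):
        if self.grid.ndim != 3 or self.affine.shape != (4, 4):
            raise ValueError("grid must be 3-D and affine 4x4")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def ellipsoid_mask(shape: tuple[int, int, int], fraction: float = 0.9) -> np.ndarray:
    """Synthetic ellipsoidal brain mask for tests and demonstrations."""
    zz = [np.linspace(-1, 1, s) for s in shape]
    I, J, K = np.meshgrid(*zz, indexing="ij")
    return (I**2 + J**2 + K**2) <= fraction**2


def _voxel_coords_mm(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1)
    hom = np.vstack([idx, np.ones((1, idx.shape[1]))])
    return (affine @ hom)[:3].T  # (n_vox, 3)


def scores_to_voxelmap(
    contact_coords: np.ndarray,
    probabilities: np.ndarray,
    brain_mask: np.ndarray,
    affine: np.ndarray | None = None,
    kernel_sigma: float = 5.0,
    neighborhood_voxels: float = 2.0,
) -> VoxelMap:
    """Render contact probabilities as a volume.

    Parameters
    ----------
    contact_coords : (n, 3) mm coordinates (must lie inside the mask)
    probabilities : (n,) values in [0, 1]
    brain_mask : 3-D bool array
    affine : voxel-to-mm affine; identity (1 mm isotropic) by default
    kernel_sigma : Gaussian kernel width in mm for the interpolation
    neighborhood_voxels : radius (voxels) of the contact neighborhoods
    """
    coords = np.atleast_2d(np.asarray(contact_coords, dtype=float))
    probs = np.asarray(probabilities, dtype=float)
    if coords.shape[0] != probs.size:
        raise ValueError("one probability per contact required")
    if probs.size == 0:
        raise ValueError("need at least one contact")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must be in [0, 1]")
    mask = np.asarray(brain_mask, dtype=bool)
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)

    inv = np.linalg.inv(affine)
    vox = (inv @ np.hstack([coords, np.ones((coords.shape[0], 1))]).T)[:3].T
    ivox = np.round(vox).astype(int)
    for c, v in zip(ivox, coords):
        if np.any(c < 0) or np.any(c >= mask.shape) or not mask[tuple(c)]:
            raise ValueError(f"contact at {v.tolist()} mm lies outside the brain mask")

    floor = float(probs.min())
    grid = np.full(mask.shape, floor, dtype=float)

    # boundary voxels: in-mask voxels touching the outside
    interior = ndimage.binary_erosion(mask)
    boundary = mask & ~interior

    vox_mm = _voxel_coords_mm(mask.shape, affine)
    flat_mask = mask.ravel()
    pts = vox_mm[flat_mask]
    # distance of each in-mask voxel to every contact (n_vox, n_contacts)
    d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    # Gaussian-weighted convex combination of contacts and boundary anchor
    w_contacts = np.exp(-d2 / (2.0 * kernel_sigma**2))
    dist_to_boundary = ndimage.distance_transform_edt(
        ~boundary, sampling=VoxelMap(grid, affine, mask).voxel_size
    ).ravel()[flat_mask]
    w_floor = np.exp(-(dist_to_boundary**2) / (2.0 * kernel_sigma**2))
    values = (w_contacts @ probs + w_floor * floor) / (
        w_contacts.sum(axis=1) + w_floor + 1e-300
    )
    grid.ravel()[np.flatnonzero(flat_mask)] = values

    # contact neighborhoods override (nearest contact wins)
    radius_mm = neighborhood_voxels * VoxelMap(grid, affine, mask).voxel_size.max()
    near = d2.min(axis=1) <= radius_mm**2
    nearest = d2.argmin(axis=1)
    vals = grid.ravel()[np.flatnonzero(flat_mask)]
    vals[near] = probs[nearest[near]]
    grid.ravel()[np.flatnonzero(flat_mask)] = vals

    grid[boundary] = floor
    grid[~mask] = floor
    return VoxelMap(grid=grid, affine=affine, mask=mask)


def write_volume(voxelmap: VoxelMap, path) -> None:
    """Write the map as a float32 NIfTI volume."""
    img = nib.Nifti1Image(voxelmap.grid.astype(np.float32), voxelmap.affine)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a NIfTI volume: (grid, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj, dtype=float), img.affine
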