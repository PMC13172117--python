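"""Prostate-mask preparation: grid alignment and boundary erosion.

Segmentation masks carry boundary uncertainty (automatic segmentation plus
coregistration to the ADC grid).  Before inference the mask is eroded by one
in-plane voxel, but only on slices whose upper and lower neighbours also
contain prostate, so apex/base edge slices are left untouched.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import ProstateMask

__all__ = ["erode_mask", "resample_mask_to_grid"]

# in-plane structuring elements (cylinder of height 1 voxel, radius 1 voxel)
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_SQUARE = np.ones((3, 3), dtype=bool)


def erode_mask(
    mask: ProstateMask,
    element: str = "cross",
    restricted: str = "keep",
) -> ProstateMask:
    """Remove one boundary voxel in-plane on slices with segmented neighbours.

    A slice at index ``z`` is eroded with a 2-D radius-1 structuring element
    only when both adjacent slices ``z - 1`` and ``z + 1`` contain at least
    one mask voxel; the first and last slices of the volume therefore never
    erode.  Slices failing the adjacency condition are returned unchanged
    (``restricted="keep"``) or emptied (``restricted="drop"``).

    The operation is anti-extensive (output is a subset of the input) but not
    idempotent: repeated calls keep eroding interior slices.
    """
    if element not in ("cross", "square"):
        raise ValueError("element must be 'cross' or 'square'")
    if restricted not in ("keep", "drop"):
        raise ValueError("restricted must be 'keep' or 'drop'")
    selem = _CROSS if element == "cross" else _SQUARE

    grid = mask.data
    out = grid.copy()
    nz = grid.shape[2]
    has_voxels = grid.any(axis=(0, 1))
    for z in range(nz):
        eligible = 0 < z < nz - 1 and has_voxels[z - 1] and has_voxels[z + 1]
        if eligible:
            out[:, :, z] = ndimage.binary_erosion(grid[:, :, z], structure=selem)
        elif restricted == "drop":
            out[:, :, z] = False
    return ProstateMask(out, mask.spacing)


def resample_mask_to_grid(
    mask: ProstateMask,
    target_shape,
    target_spacing,
) -> ProstateMask:
    """Nearest-neighbour resample of a binary mask onto another grid.

    Grids are assumed axis-aligned with a shared physical origin at the
    centre of voxel (0, 0, 0).  Raises if the resampled mask is empty, which
    almost always signals disjoint physical extents (misalignment).
    """
    target_shape = tuple(int(n) for n in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_shape) != 3 or any(n <= 0 for n in target_shape):
        raise ValueError("target shape must be 3 positive counts")

    if target_shape == mask.shape and np.allclose(target_spacing, mask.spacing):
        return ProstateMask(mask.data.copy(), mask.spacing)

    src = mask.data
    coords = []
    for axis in range(3):
        # physical position of each target voxel centre, mapped to source index
        pos = np.arange(target_shape[axis]) * target_spacing[axis]
        idx = np.round(pos / mask.spacing[axis]).astype(int)
        coords.append(idx)
    ix, iy, iz = np.meshgrid(*coords, indexing="ij")
    inside = (
        (ix >= 0) & (ix < src.shape[0])
        & (iy >= 0) & (iy < src.shape[1])
        & (iz >= 0) & (iz < src.shape[2])
    )
    out = np.zeros(target_shape, dtype=bool)
    out[inside] = src[ix[inside], iy[inside], iz[inside]]
    if not out.any():
        raise ValueError(
            "resampled mask is empty; source and target grids do not overlap "
            "on any prostate voxel (check spacing/origin)"
        )
    return ProstateMask(out, target_spacing)
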