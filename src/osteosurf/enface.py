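"""En face projection imaging of the cartilage-bone-interface slab.

The volume is first *flattened*: every lateral column is resampled along
depth so the extracted tidemark sits at a common depth index 0.  A slab of
configurable thickness measured downward from the tidemark (into the
calcified side) is then collapsed into a 2D image by maximum intensity
projection (MIP) or average intensity projection (AIP), viewed along the
depth axis.  Thicker slabs make the MIP monotonically brighter; perforation
channels through the calcified plate appear as dark holes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import SurfaceGrid, Volume

__all__ = ["EnFaceImage", "flatten_volume", "project"]


@dataclass
class EnFaceImage:
    """2D lateral projection of a slab relative to the tidemark."""

    values: np.ndarray
    mode: str  # "mip" or "aip"
    slab_thickness_um: float
    slab_offset_um: float
    spacing: tuple[float, float]  # (elevational, lateral), µm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("en face image must be 2D")
        if self.mode not in ("mip", "aip"):
            raise ValueError("mode must be 'mip' or 'aip'")


def flatten_volume(vol: Volume, surface: SurfaceGrid) -> Volume:
    """Resample each lateral column so the tidemark lies at depth index 0.

    Depth sample ``k`` of the output holds the input intensity at physical
    depth ``z_surface(i, j) + k * dz`` (linear interpolation).  Samples past
    the bottom of the data are filled with 0 and marked invalid in the
    returned volume's ``valid`` mask, so averaging projections can exclude
    them.
    """
    ny, nz, nx = vol.shape
    if surface.heights.shape != (ny, nx):
        raise ValueError("surface lateral shape must match the volume")
    dz = vol.spacing[1]
    rows0 = (surface.heights - vol.origin[1]) / dz  # fractional surface row
    if rows0.min() < 0 or rows0.max() > nz - 1:
        raise ValueError("surface lies outside the volume depth range")
    k = np.arange(nz)
    # coordinates (frame, depth_row, lateral) for map_coordinates
    depth_coords = rows0[:, None, :] + k[None, :, None]  # (ny, nz, nx)
    frame_idx = np.broadcast_to(np.arange(ny)[:, None, None], depth_coords.shape)
    lat_idx = np.broadcast_to(np.arange(nx)[None, None, :], depth_coords.shape)
    out = ndimage.map_coordinates(
        vol.intensities.astype(float),
        [frame_idx, depth_coords, lat_idx],
        order=1,
        mode="constant",
        cval=0.0,
    )
    valid = (depth_coords >= 0) & (depth_coords <= nz - 1)
    return Volume(out, vol.spacing, vol.origin, valid=valid)


def project(
    flat: Volume,
    mode: str = "mip",
    thickness_um: float = 100.0,
    offset_um: float = 0.0,
) -> EnFaceImage:
    """Collapse a slab of a flattened volume into an en face image.

    The slab spans depth ``[offset, offset + thickness)`` below the
    tidemark; ``mode`` is ``"mip"`` (per-column maximum) or ``"aip"``
    (per-column mean, excluding fill voxels introduced by flattening).
    """
    if mode not in ("mip", "aip"):
        raise ValueError("mode must be 'mip' or 'aip'")
    dz = flat.spacing[1]
    if thickness_um < dz:
        raise ValueError("slab thickness must be at least one voxel deep")
    nz = flat.shape[1]
    i0 = int(round(offset_um / dz))
    n = max(1, int(round(thickness_um / dz)))
    i1 = i0 + n
    if i0 >= nz or i1 <= 0:
        raise ValueError("slab lies entirely outside the flattened volume")
    i0c, i1c = max(0, i0), min(nz, i1)
    slab = flat.intensities[:, i0c:i1c, :]
    valid = flat.valid[:, i0c:i1c, :] if flat.valid is not None else np.ones(slab.shape, bool)
    any_valid = valid.any(axis=1)
    if mode == "mip":
        masked = np.where(valid, slab, -np.inf)
        img = masked.max(axis=1)
        img = np.where(any_valid, img, 0.0)
    else:
        ssum = np.where(valid, slab, 0.0).sum(axis=1)
        cnt = valid.sum(axis=1)
        img = np.where(any_valid, ssum / np.maximum(cnt, 1), 0.0)
    return EnFaceImage(
        values=img,
        mode=mode,
        slab_thickness_um=float(thickness_um),
        slab_offset_um=float(offset_um),
        spacing=(flat.spacing[0], flat.spacing[2]),
    )
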