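"""Tidemark surface extraction from micro-CT volumes.

Pipeline: (1) estimate the small global tilt of the disk from the
volumetrically averaged frame and level it by an in-plane rotation;
(2) binarize with a global Otsu threshold to isolate calcified tissue;
(3) per vertical line, take the first abrupt soft-to-calcified transition
as the tidemark point, with a minimum run length guarding against isolated
bright noise voxels; (4) columns with no transition inside the expected
interface window (perforation holes) are filled by lateral interpolation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import BinaryVolume, SurfaceGrid, Volume
from .us_extraction import interpolate_gaps

__all__ = [
    "estimate_tilt",
    "rotate_volume",
    "otsu_threshold",
    "binarize",
    "extract_surface_3d_ct",
    "extract_surface_ct_pipeline",
]


def _first_run_start(binary: np.ndarray, min_run: int) -> np.ndarray:
    """Per column, the depth index starting the first run of ``min_run``
    consecutive True voxels; -1 where none exists.

    ``binary`` has the depth axis first: (n_depth, ...).
    """
    b = binary.astype(np.int32)
    if min_run > 1:
        # sliding-window sum along depth
        cs = np.cumsum(b, axis=0)
        pad = np.zeros((1,) + b.shape[1:], dtype=np.int32)
        cs = np.concatenate([pad, cs], axis=0)
        win = cs[min_run:] - cs[:-min_run]
        hit = win == min_run
    else:
        hit = b.astype(bool)
    any_hit = hit.any(axis=0)
    first = np.argmax(hit, axis=0)
    return np.where(any_hit, first, -1)


def estimate_tilt(vol: Volume, min_run: int = 2) -> float:
    """Global tilt angle (degrees) of the calcified interface.

    The stack is averaged into one 2D image, the per-column interface level
    is found by Otsu binarization plus first-transition detection, and a
    least-squares line through (lateral position, interface depth) gives the
    tilt as ``arctan(slope)`` in physical units.  Positive angle means the
    interface deepens with increasing lateral coordinate.
    """
    avg = vol.intensities.mean(axis=0)  # (n_depth, n_lateral)
    if avg.max() == avg.min():
        raise ValueError("constant volume: no interface to estimate tilt from")
    thr = threshold_otsu(avg)
    rows = _first_run_start(avg > thr, min_run)
    ok = rows >= 0
    if ok.mean() <= 0.5:
        raise ValueError("no interface transition in more than half of the columns")
    x_um = np.flatnonzero(ok) * vol.spacing[2]
    z_um = rows[ok] * vol.spacing[1]
    slope = np.polyfit(x_um, z_um, 1)[0]
    return float(np.degrees(np.arctan(slope)))


def rotate_volume(vol: Volume, angle_deg: float) -> Volume:
    """Rotate every frame in its (depth, lateral) plane about the frame
    centre by ``angle_deg`` with bilinear resampling.

    The rotation sign matches :func:`estimate_tilt`:
    ``rotate_volume(vol, -estimate_tilt(vol))`` levels the interface.
    Out-of-field voxels are filled with the volume minimum.
    """
    if abs(angle_deg) >= 15:
        raise ValueError("tilt correction is meant for small angles (< 15 degrees)")
    if angle_deg == 0:
        return Volume(vol.intensities.copy(), vol.spacing, vol.origin)
    fill = float(vol.intensities.min())
    out = ndimage.rotate(
        vol.intensities,
        -angle_deg,
        axes=(1, 2),
        reshape=False,
        order=1,
        mode="constant",
        cval=fill,
    )
    return Volume(out, vol.spacing, vol.origin)


def otsu_threshold(vol: Volume | np.ndarray, n_bins: int = 256) -> float:
    """Global Otsu threshold of a volume's intensity histogram.

    Maximizes the between-class variance over an ``n_bins`` histogram; ties
    resolve to the lowest qualifying threshold.
    """
    values = vol.intensities if isinstance(vol, Volume) else np.asarray(vol)
    if values.max() == values.min():
        raise ValueError("Otsu threshold undefined for a constant volume")
    return float(threshold_otsu(values.ravel(), nbins=n_bins))


def binarize(vol: Volume, threshold: float) -> BinaryVolume:
    """Calcified-tissue mask: strictly above-threshold voxels are True."""
    return BinaryVolume(vol.intensities > threshold, vol.spacing, vol.origin)


def extract_surface_3d_ct(
    binvol: BinaryVolume,
    min_run: int = 2,
    interface_window_um: float = 500.0,
    local_outlier_um: float | None = 150.0,
) -> SurfaceGrid:
    """Assemble the tidemark heightmap from a binarized CT volume.

    Per column the first soft-to-calcified transition (first run of
    ``min_run`` True voxels, scanning from shallow) marks the interface.
    Two guards keep non-tidemark structure from masquerading as the
    surface: columns whose transition falls outside
    ``± interface_window_um`` of the median interface depth — or that have
    none at all — are holes; and, when ``local_outlier_um`` is set, columns
    deviating more than that from the median-filtered surface (a scan down
    the *wall* of a perforation channel produces such locally implausible
    depths) are flagged as well.  Flagged columns are filled per frame by
    lateral linear interpolation.
    """
    ny, nz, nx = binvol.values.shape
    dz = binvol.spacing[1]
    rows = np.empty((ny, nx), dtype=np.int64)
    for i in range(ny):
        rows[i] = _first_run_start(binvol.values[i], min_run)
    found = rows >= 0
    if not found.any():
        raise ValueError("no calcified interface found in any column")
    depth = rows * dz
    median_depth = np.median(depth[found])
    hole = ~found | (np.abs(depth - median_depth) > interface_window_um)
    if hole.all():
        raise ValueError("every column flagged as hole; no interface within window")

    def _fill(flags: np.ndarray) -> np.ndarray:
        out = np.empty((ny, nx))
        for i in range(ny):
            if flags[i].all():
                out[i] = median_depth  # frame with no valid column
            else:
                out[i] = interpolate_gaps(depth[i].astype(float), flags[i])
        return out

    heights = _fill(hole)
    if local_outlier_um is not None and min(ny, nx) >= 3:
        smooth = ndimage.median_filter(heights, size=(min(ny, 3), min(nx, 5)), mode="nearest")
        hole |= np.abs(heights - smooth) > local_outlier_um
        if hole.all():
            raise ValueError("every column flagged as hole; no interface within window")
        heights = _fill(hole)
    heights += binvol.origin[1]
    return SurfaceGrid(heights, (binvol.spacing[0], binvol.spacing[2]), valid_mask=~hole)


def extract_surface_ct_pipeline(
    vol: Volume,
    tilt_correct: bool = True,
    n_bins: int = 256,
    min_run: int = 2,
    interface_window_um: float = 500.0,
) -> tuple[SurfaceGrid, float]:
    """Full CT extraction: tilt estimation/correction, Otsu binarization,
    first-transition surface assembly.  Returns the surface (in the levelled
    frame when ``tilt_correct``) and the estimated tilt in degrees.

    The in-plane rotation fills a wedge at each lateral frame edge with
    out-of-field values; columns inside that wedge carry no genuine
    interface, so a margin of ``tan(tilt) * nz / 2`` columns (plus two) is
    cropped from both lateral sides of the returned grid.
    """
    tilt = 0.0
    work = vol
    if tilt_correct:
        tilt = estimate_tilt(vol)
        work = rotate_volume(vol, -tilt)
    thr = otsu_threshold(work, n_bins=n_bins)
    surface = extract_surface_3d_ct(binarize(work, thr), min_run, interface_window_um)
    if tilt_correct and tilt != 0.0:
        nz = vol.intensities.shape[1]
        w = int(np.ceil(np.tan(np.radians(abs(tilt))) * nz / 2)) + 2
        if surface.heights.shape[1] > 2 * w + 2:
            surface = SurfaceGrid(
                surface.heights[:, w:-w],
                surface.spacing,
                valid_mask=surface.valid_mask[:, w:-w],
            )
    return surface, tilt
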