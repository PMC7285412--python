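"""Tidemark surface extraction from B-mode ultrasound stacks.

The procedure is semiautomatic: a coarse, manually drawn (or surrogate)
profile seeds a per-column search window of 20 pixels (~0.30 mm at 15 µm
axial pixels), and within each window the *first* echo peak above a noise
threshold — the shallowest strict local maximum — is taken as the tidemark.
The noise threshold comes from the dark saline region above the cartilage
surface.  Columns with no qualifying peak are treated as tidemark cracks
and filled by 1D linear interpolation from their lateral neighbours.
"""

from __future__ import annotations

import numpy as np

from .geometry import SurfaceGrid, Volume
from .synthetic import ApproxProfile

__all__ = [
    "estimate_noise_level",
    "extract_profile_2d",
    "interpolate_gaps",
    "extract_surface_3d",
]


def estimate_noise_level(vol: Volume, saline_rows: tuple[int, int], k: float = 3.0) -> float:
    """Noise threshold from the saline reference region.

    Parameters
    ----------
    vol : Volume
    saline_rows : (start, stop) half-open depth-row range lying in the dark
        saline region above the cartilage surface.
    k : number of standard deviations above the mean (default 3).

    Returns
    -------
    float
        ``mean + k * SD`` of the region's intensities.
    """
    lo, hi = int(saline_rows[0]), int(saline_rows[1])
    nz = vol.intensities.shape[1]
    if not (0 <= lo < hi <= nz):
        raise ValueError(f"saline row range ({lo}, {hi}) outside volume depth [0, {nz})")
    region = vol.intensities[:, lo:hi, :]
    if region.size == 0:
        raise ValueError("empty saline region")
    return float(region.mean() + k * region.std())


def _first_peak(window: np.ndarray, threshold: float) -> int | None:
    """Index (within ``window``) of the shallowest strict local maximum
    above ``threshold``; plateaus resolve to their shallowest sample.
    Window-boundary samples never qualify (a monotone rise into the window
    edge is not a verified peak).  Returns None if no peak qualifies."""
    n = window.size
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and window[j + 1] == window[i]:
            j += 1
        if j >= n - 1:
            break
        if window[i] > threshold and window[i] > window[i - 1] and window[i] > window[j + 1]:
            return i
        i = j + 1
    return None


def extract_profile_2d(
    frame: np.ndarray,
    approx_rows: np.ndarray,
    threshold: float,
    window_px: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column first-peak depth in one B-scan frame.

    Parameters
    ----------
    frame : (n_depth, n_lateral) image.
    approx_rows : per-column coarse depth row (float or int), the window
        centre.
    threshold : noise level; only samples strictly above it can be peaks.
    window_px : full window size in pixels, clipped at frame edges.

    Returns
    -------
    rows : float array, detected peak row per column (NaN where flagged).
    crack : bool array, True where no qualifying peak was found.
    """
    if window_px < 3:
        raise ValueError("window_px must be at least 3")
    frame = np.asarray(frame)
    nz, nx = frame.shape
    approx_rows = np.asarray(approx_rows)
    if approx_rows.shape != (nx,):
        raise ValueError("approx_rows must have one entry per lateral column")
    half = window_px // 2
    rows = np.full(nx, np.nan)
    crack = np.zeros(nx, dtype=bool)
    centers = np.clip(np.round(approx_rows).astype(int), 0, nz - 1)
    for j in range(nx):
        lo = max(0, centers[j] - half)
        hi = min(nz, centers[j] + half + 1)
        idx = _first_peak(frame[lo:hi, j], threshold)
        if idx is None:
            crack[j] = True
        else:
            rows[j] = lo + idx
    return rows, crack


def interpolate_gaps(profile: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Fill flagged entries of a 1D profile by linear interpolation between
    the nearest valid neighbours; leading/trailing gaps take the nearest
    valid value."""
    profile = np.asarray(profile, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if profile.shape != flags.shape or profile.ndim != 1:
        raise ValueError("profile and flags must be matching 1D arrays")
    valid = ~flags
    if not valid.any():
        raise ValueError("cannot interpolate: every column is flagged")
    if valid.all():
        return profile.copy()
    x = np.arange(profile.size)
    return np.interp(x, x[valid], profile[valid])


def extract_surface_3d(
    vol: Volume,
    approx: ApproxProfile,
    threshold: float,
    window_px: int = 20,
    refine_subpixel: bool = False,
) -> SurfaceGrid:
    """Frame-by-frame tidemark extraction over the whole stack.

    Applies :func:`extract_profile_2d` and :func:`interpolate_gaps` to each
    frame, converts peak rows to physical depth via the axial spacing and
    assembles the heightmap; ``valid_mask`` is False at crack columns.

    With ``refine_subpixel`` a three-point parabolic fit around each integer
    peak refines the depth to sub-pixel precision.
    """
    ny, nz, nx = vol.shape
    if approx.depths_um.shape != (ny, nx):
        raise ValueError("approximate profile must cover every frame and column")
    dz = vol.spacing[1]
    z0 = vol.origin[1]
    heights = np.empty((ny, nx))
    valid = np.empty((ny, nx), dtype=bool)
    approx_rows = (approx.depths_um - z0) / dz
    for i in range(ny):
        frame = vol.intensities[i]
        rows, crack = extract_profile_2d(frame, approx_rows[i], threshold, window_px)
        if refine_subpixel:
            rows = _parabolic_refine(frame, rows)
        rows = interpolate_gaps(rows, crack)
        heights[i] = z0 + rows * dz
        valid[i] = ~crack
    return SurfaceGrid(heights, (vol.spacing[0], vol.spacing[2]), valid_mask=valid)


def _parabolic_refine(frame: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Three-point parabolic sub-pixel peak refinement (NaNs pass through)."""
    out = rows.copy()
    nz = frame.shape[0]
    for j, r in enumerate(rows):
        if not np.isfinite(r):
            continue
        r = int(r)
        if r <= 0 or r >= nz - 1:
            continue
        a, b, c = frame[r - 1, j], frame[r, j], frame[r + 1, j]
        denom = a - 2 * b + c
        if denom != 0:
            delta = 0.5 * (a - c) / denom
            if abs(delta) <= 0.5:
                out[j] = r + delta
    return out
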