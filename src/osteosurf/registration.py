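"""Rigid ICP registration of tidemark surfaces and the mean surface
discrepancy statistic.

The ultrasound-extracted surface (as a point cloud) is registered onto the
micro-CT reference surface by iterative closest point with a closed-form
SVD (Kabsch) rigid fit per iteration.  Iteration stops when the RMS
correspondence distance changes by less than 0.01 µm.  After registration
the discrepancy between the modalities is the mean unsigned Euclidean
distance from each ultrasound point to the nearest point of the triangulated
CT surface:

    D_diff = (1/N) * sum_i d(p_US_i, s_mCT)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    RigidTransform,
    SurfaceGrid,
    TriMesh,
    point_mesh_distance,
    rotation_about_axis,
)

__all__ = [
    "RegistrationResult",
    "surface_to_pointcloud",
    "surface_to_mesh",
    "best_fit_rigid",
    "icp_register",
    "mean_surface_discrepancy",
]


@dataclass
class RegistrationResult:
    """Outcome of an ICP run.

    ``d_diff`` is the arithmetic mean of ``per_point_distances`` (µm) and
    ``d_sd`` their standard deviation; ``rms_history`` records the RMS
    correspondence distance at each iteration.
    """

    transform: RigidTransform
    per_point_distances: np.ndarray
    d_diff: float
    d_sd: float
    iterations: int
    converged: bool
    rms_history: np.ndarray


def surface_to_pointcloud(s: SurfaceGrid, exclude_invalid: bool = False) -> np.ndarray:
    """One (x, y, z) point per grid node: (j*dx, i*dy, z(i, j)), µm.

    With ``exclude_invalid`` the nodes whose height was interpolated over a
    crack or hole are dropped.
    """
    if s.heights.size == 0:
        raise ValueError("empty surface grid")
    ycoords, xcoords = s.lateral_coords()
    Y, X = np.meshgrid(ycoords, xcoords, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), s.heights.ravel()])
    if exclude_invalid:
        pts = pts[s.valid_mask.ravel()]
    return pts


def surface_to_mesh(s: SurfaceGrid) -> TriMesh:
    """Triangulate a heightmap: two consistently wound triangles per cell."""
    ny, nx = s.heights.shape
    if ny < 2 or nx < 2:
        raise ValueError("need at least a 2x2 grid to triangulate")
    vertices = surface_to_pointcloud(s)
    idx = np.arange(ny * nx).reshape(ny, nx)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate([np.column_stack([a, b, c]), np.column_stack([b, d, c])])
    return TriMesh(vertices, faces)


def best_fit_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping ``source`` onto
    ``target`` (paired points) via the cross-covariance SVD construction,
    with the reflection case corrected to a proper rotation."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must be matching (N, 3) arrays")
    cs = source.mean(axis=0)
    ct = target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cs
    return RigidTransform(R, t)


def _check_nondegenerate(points: np.ndarray) -> None:
    if len(points) < 3:
        raise ValueError("need at least 3 points for rigid registration")
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate point cloud (collinear or coincident points)")


def principal_axes_init(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Coarse initialization: align centroids and principal axes.

    Axis sign ambiguity is resolved by trying the four proper-rotation sign
    combinations and keeping the one with the smallest nearest-neighbour
    RMS.  A stand-in for the manual coarse alignment that precedes ICP.
    """
    cs = source.mean(axis=0)
    ct = target.mean(axis=0)
    _, _, Vs = np.linalg.svd(source - cs, full_matrices=False)
    _, _, Vt_ = np.linalg.svd(target - ct, full_matrices=False)
    tree = cKDTree(target)
    best = None
    best_rms = np.inf
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            S = np.diag([s1, s2, s1 * s2])  # keeps det = +1
            R = Vt_.T @ S @ Vs
            if np.linalg.det(R) < 0:
                continue
            cand = RigidTransform(R, ct - R @ cs)
            d, _ = tree.query(cand.apply(source))
            rms = float(np.sqrt(np.mean(d**2)))
            if rms < best_rms:
                best_rms = rms
                best = cand
    return best


def _icp_single(
    source: np.ndarray,
    target_pts: np.ndarray,
    tree: cKDTree,
    init: RigidTransform,
    tol_um: float,
    max_iter: int,
    trim_fraction: float,
) -> tuple[RigidTransform, list, bool, int]:
    current = init
    x = current.apply(source)
    rms_history: list[float] = []
    converged = False
    iterations = 0
    prev_rms = np.inf
    for iterations in range(1, max_iter + 1):
        d, idx = tree.query(x)
        rms = float(np.sqrt(np.mean(d**2)))
        rms_history.append(rms)
        if abs(prev_rms - rms) < tol_um:
            converged = True
            break
        prev_rms = rms
        if trim_fraction > 0:
            keep = d <= np.quantile(d, 1.0 - trim_fraction)
            step = best_fit_rigid(x[keep], target_pts[idx[keep]])
        else:
            step = best_fit_rigid(x, target_pts[idx])
        x = step.apply(x)
        current = step.compose(current)
    return current, rms_history, converged, iterations


def icp_register(
    source: np.ndarray,
    target: TriMesh | np.ndarray,
    init: RigidTransform | str | None = "centroid",
    tol_um: float = 0.01,
    max_iter: int = 200,
    trim_fraction: float = 0.0,
    rotation_starts_deg: tuple[float, ...] = (0.0,),
) -> RegistrationResult:
    """Point-to-point ICP of ``source`` onto ``target``.

    Parameters
    ----------
    source : (N, 3) point cloud, µm.
    target : reference point cloud or :class:`TriMesh` (its vertices drive
        the correspondences; final distances are point-to-mesh).
    init : starting transform.  ``"centroid"`` (default) aligns centroids —
        the stand-in for the manual coarse alignment that precedes ICP —
        ``"principal_axes"`` additionally aligns principal axes, ``None``
        starts from identity, or pass an explicit :class:`RigidTransform`.
    tol_um : stop when the RMS correspondence distance changes by less than
        this between consecutive iterations (default 0.01 µm).
    max_iter : iteration cap; exceeding it sets ``converged=False``.
    trim_fraction : optionally ignore this fraction of the worst
        correspondences in each rigid fit (0 = plain ICP).
    rotation_starts_deg : in-plane (about the depth axis through the source
        centroid) rotation offsets tried as additional starting poses; the
        run with the lowest final RMS wins.  Near-flat lattices can lock
        ICP into a laterally slipped local minimum, and a small rotation
        sweep — the automated counterpart of a manual coarse alignment —
        escapes it.  The default single 0° start is plain ICP.

    Notes
    -----
    Each iteration matches every source point to its nearest target point
    (KD-tree), solves the closed-form SVD rigid fit on the matches and
    applies it; the per-iteration RMS is recorded and is non-increasing.
    """
    source = np.asarray(source, dtype=float)
    _check_nondegenerate(source)
    mesh = target if isinstance(target, TriMesh) else None
    target_pts = target.vertices if mesh is not None else np.asarray(target, dtype=float)
    if len(target_pts) == 0:
        raise ValueError("empty target")
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must lie in [0, 1)")

    if init is None:
        base = RigidTransform.identity()
    elif isinstance(init, str):
        if init == "centroid":
            base = RigidTransform(
                np.eye(3), target_pts.mean(axis=0) - source.mean(axis=0)
            )
        elif init == "principal_axes":
            base = principal_axes_init(source, target_pts)
        else:
            raise ValueError(f"unknown init strategy {init!r}")
    else:
        base = init

    tree = cKDTree(target_pts)
    centroid = base.apply(source).mean(axis=0)
    best = None
    for offset in rotation_starts_deg:
        if offset == 0.0:
            start = base
        else:
            R = rotation_about_axis("z", offset)
            spin = RigidTransform(R, centroid - R @ centroid)
            start = spin.compose(base)
        run = _icp_single(source, target_pts, tree, start, tol_um, max_iter, trim_fraction)
        if best is None or run[1][-1] < best[1][-1]:
            best = run
        if best[1][-1] < tol_um:  # essentially exact overlap reached
            break
    current, rms_history, converged, iterations = best

    if mesh is not None:
        distances = point_mesh_distance(current.apply(source), mesh)
    else:
        distances, _ = tree.query(current.apply(source))
    return RegistrationResult(
        transform=current,
        per_point_distances=distances,
        d_diff=float(np.mean(distances)),
        d_sd=float(np.std(distances)),
        iterations=iterations,
        converged=converged,
        rms_history=np.asarray(rms_history),
    )


def mean_surface_discrepancy(points: np.ndarray, reference: TriMesh) -> tuple[float, float, np.ndarray]:
    """Mean unsigned point-to-surface distance (µm) and its SD.

    Every point is measured to the nearest point on any triangle of the
    reference mesh — interior, edge or vertex.  Returns
    ``(mean, sd, per_point_distances)``.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty point cloud")
    d = point_mesh_distance(points, reference)
    return float(np.mean(d)), float(np.std(d)), d
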