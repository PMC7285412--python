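"""Core geometric containers shared by every pipeline stage.

Conventions
-----------
* All physical lengths are micrometres (µm) unless a name says otherwise.
* Indices are 0-based.  A voxel/grid-node index ``k`` along an axis with
  spacing ``d`` sits at physical coordinate ``origin + k * d`` (node-centred
  model).
* Volumes are indexed ``(frame, depth_row, lateral_column)``; the depth axis
  (z) increases downward, i.e. away from the transducer / X-ray source side.
* Point clouds are ``(N, 3)`` arrays with columns ``(x, y, z)`` where x is
  the lateral (in-frame) axis, y the elevational (frame/scan) axis and z the
  depth axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class Volume:
    """A 3D grayscale image stack with anisotropic physical spacing.

    Parameters
    ----------
    intensities : ndarray, shape (n_frames, n_depth, n_lateral)
        Non-negative scalar intensities.
    spacing : tuple of float
        ``(elevational, axial, lateral)`` step sizes in µm, matching axis
        order of ``intensities``.
    origin : tuple of float, optional
        Physical offset of voxel (0, 0, 0) along the same axes, µm.
    valid : ndarray of bool or None
        Optional voxel validity mask (same shape); used by flattening to
        mark fill voxels that carry no data.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("Volume intensities must be 3D (frame, depth, lateral)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("Volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive components (elev, axial, lateral)")
        self.origin = tuple(float(o) for o in self.origin)
        if self.valid is not None and self.valid.shape != self.intensities.shape:
            raise ValueError("valid mask shape must match intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def depth_um(self) -> float:
        """Physical depth extent (first to last row centre), µm."""
        return (self.intensities.shape[1] - 1) * self.spacing[1]

    def depth_coords(self) -> np.ndarray:
        """Physical depth (µm) of every row centre."""
        return self.origin[1] + np.arange(self.intensities.shape[1]) * self.spacing[1]


@dataclass
class BinaryVolume:
    """Binarized volume; ``True`` marks calcified (above-threshold) voxels."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("BinaryVolume must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")


@dataclass
class SurfaceGrid:
    """Heightmap z(i, j) on a regular lateral grid.

    ``heights[i, j]`` is the surface depth (µm) at elevational index ``i``
    and lateral index ``j``.  ``valid_mask`` is ``False`` where the height
    was filled by interpolation across a crack or hole rather than detected.
    """

    heights: np.ndarray
    spacing: tuple[float, float]  # (elevational dy, lateral dx), µm
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite everywhere")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("lateral spacings must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.heights.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.heights.shape:
                raise ValueError("valid_mask shape must match heights")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def lateral_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinates of grid nodes as 1D arrays, µm."""
        ny, nx = self.heights.shape
        return np.arange(ny) * self.spacing[0], np.arange(nx) * self.spacing[1]


@dataclass
class TriMesh:
    """Triangle mesh: ``vertices`` (V, 3) in µm, ``faces`` (F, 3) int indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]


@dataclass
class RigidTransform:
    """Proper rigid transform ``p -> R @ p + t`` (rotation + translation, µm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rotation=rot_inv, translation=-rot_inv @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_about_axis(axis: str, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about a coordinate axis ('x', 'y' or 'z')."""
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r}")


# ---------------------------------------------------------------------------
# Point-to-triangle / point-to-mesh distance
# ---------------------------------------------------------------------------

def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    Parameters
    ----------
    points : (N, 3)
    triangles : (N, K, 3, 3)
        Per-point candidate triangles (vertex coordinates).

    Returns
    -------
    (N, K, 3) closest points.

    Notes
    -----
    Vertex/edge/face regions are resolved with the standard Voronoi-region
    case analysis (Ericson-style), fully vectorised.
    """
    p = np.asarray(points, dtype=float)[:, None, :]  # (N,1,3)
    a = triangles[..., 0, :]
    b = triangles[..., 1, :]
    c = triangles[..., 2, :]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...k,...k->...", ab, ap)
    d2 = np.einsum("...k,...k->...", ac, ap)

    bp = p - b
    d3 = np.einsum("...k,...k->...", ab, bp)
    d4 = np.einsum("...k,...k->...", ac, bp)

    cp = p - c
    d5 = np.einsum("...k,...k->...", ab, cp)
    d6 = np.einsum("...k,...k->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        # interior (barycentric) candidate
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)
        closest = a + ab * v_in[..., None] + ac * w_in[..., None]

        # edge BC
        t_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        closest = np.where(on_bc[..., None], b + (c - b) * t_bc[..., None], closest)

        # edge AC
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        closest = np.where(on_ac[..., None], a + ac * t_ac[..., None], closest)

        # edge AB
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        closest = np.where(on_ab[..., None], a + ab * t_ab[..., None], closest)

    # vertex regions last: they override any edge/face candidate
    closest = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, closest)
    closest = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, closest)
    return closest


def point_mesh_distance(points: np.ndarray, mesh: TriMesh, k: int = 32) -> np.ndarray:
    """Unsigned Euclidean distance from each point to the nearest point on a
    triangle mesh (interior, edge or vertex).

    A KD-tree over triangle centroids supplies ``k`` candidate triangles per
    point; exactness is guaranteed by checking the candidate radius against
    the largest triangle circumradius-like bound and re-scanning outliers
    against all triangles.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if len(points) == 0:
        raise ValueError("empty point cloud")
    tris = mesh.triangles
    n_tri = len(tris)
    if n_tri == 0:
        raise ValueError("empty mesh")

    centroids = tris.mean(axis=1)
    # max distance from a centroid to its own triangle's vertices
    r_max = float(np.sqrt(((tris - centroids[:, None, :]) ** 2).sum(-1)).max())

    k_eff = min(k, n_tri)
    tree = cKDTree(centroids)
    cd, ci = tree.query(points, k=k_eff)
    if k_eff == 1:
        cd = cd[:, None]
        ci = ci[:, None]

    cand = tris[ci]  # (N, k, 3, 3)
    cp = closest_point_on_triangles(points, cand)
    d = np.sqrt(((cp - points[:, None, :]) ** 2).sum(-1))
    dmin = d.min(axis=1)

    if k_eff < n_tri:
        # a triangle outside the candidate set could be closer only if its
        # centroid lies within dmin + r_max; the k-th candidate centroid
        # distance bounds what was searched
        unsure = dmin + r_max > cd[:, -1]
        for pi in np.flatnonzero(unsure):
            ball = tree.query_ball_point(points[pi], dmin[pi] + r_max + 1e-9)
            extra = np.setdiff1d(np.asarray(ball, dtype=np.int64), ci[pi], assume_unique=False)
            if extra.size == 0:
                continue
            cp_e = closest_point_on_triangles(points[pi : pi + 1], tris[extra][None])
            d_e = np.sqrt(((cp_e - points[pi]) ** 2).sum(-1))
            dmin[pi] = min(dmin[pi], float(d_e.min()))
    return dmin
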