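"""Readers, writers and the shared pipeline configuration.

Volumes travel as multi-page TIFF (one page per frame) or as sorted
PNG/TIFF series in a directory, always accompanied by a JSON sidecar
carrying the physical spacing (µm) — spacing is never guessed.  Surfaces
are written as STL meshes (millimetre units, matching common mesh-viewer
conventions), PLY point clouds, or gridded CSV height tables (µm).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import trimesh as _trimesh
import yaml

from .geometry import SurfaceGrid, Volume
from .registration import surface_to_mesh, surface_to_pointcloud

__all__ = [
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "write_surface",
    "read_surface_csv",
]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with its working default.

    window_px : full size of the per-column first-peak search window in the
        ultrasound frames (20 pixels ≈ 0.30 mm at 15 µm).
    noise_k : the noise threshold is saline mean + ``noise_k`` * SD.
    icp_tol_um : ICP stops when the RMS correspondence distance changes by
        less than this between iterations (0.01 µm).
    icp_max_iter : ICP iteration cap.
    waviness_order / roughness_order : polynomial reference surface orders
        for the SW and SR indices (1 and 5).
    slab_thicknesses_um : en face volume-of-interest thicknesses to render.
    us_spacing_um / ct_spacing_um : (elevational, axial, lateral) voxel
        spacing of the two modalities.
    ct_min_run : minimum consecutive calcified voxels accepted as the first
        abrupt transition in CT columns.
    ct_interface_window_um : half-width of the accepted interface depth
        window around the median CT interface depth.
    ct_tilt_correct : whether the end-to-end pipeline levels the CT volume
        before extraction.  Off by default: at the small tilts handled here
        the per-column transition scan needs no leveling, the rigid
        registration absorbs the tilt, and rotation resampling degrades the
        surface around perforation channels.
    """

    window_px: int = 20
    noise_k: float = 3.0
    icp_tol_um: float = 0.01
    icp_max_iter: int = 200
    waviness_order: int = 1
    roughness_order: int = 5
    slab_thicknesses_um: tuple[float, ...] = (15.0, 45.0, 105.0, 150.0)
    us_spacing_um: tuple[float, float, float] = (32.0, 15.0, 15.0)
    ct_spacing_um: tuple[float, float, float] = (21.0, 21.0, 21.0)
    ct_min_run: int = 2
    ct_interface_window_um: float = 500.0
    ct_tilt_correct: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("slab_thicknesses_um", "us_spacing_um", "ct_spacing_um"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("slab_thicknesses_um", "us_spacing_um", "ct_spacing_um"):
            d[key] = list(d[key])
        return d

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def hash(self) -> str:
        """Short provenance hash recorded in output sidecars."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: Volume, path: str | Path, config: PipelineConfig | None = None) -> None:
    """Multi-page TIFF (one page per frame) plus a JSON spacing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(vol.intensities, dtype=np.float32), photometric="minisblack")
    meta = {
        "spacing_um": list(vol.spacing),
        "origin_um": list(vol.origin),
        "axes": ["frame(elevational)", "depth(axial)", "lateral"],
    }
    if config is not None:
        meta["config_hash"] = config.hash()
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_volume(path: str | Path, spacing: tuple[float, float, float] | None = None) -> Volume:
    """Read a volume from a multi-page TIFF, a directory of PNG/TIFF frames,
    or a headerless ``.raw`` file (its JSON sidecar must carry shape/dtype).

    ``spacing`` (elevational, axial, lateral µm) may be omitted only when a
    JSON sidecar written by :func:`write_volume` sits next to the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    origin = (0.0, 0.0, 0.0)
    if spacing is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError("spacing not given and no sidecar found; spacing is required")
        meta = json.loads(sidecar.read_text())
        spacing = tuple(meta["spacing_um"])
        origin = tuple(meta.get("origin_um", origin))
    if path.suffix.lower() == ".raw":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError("raw volumes need a sidecar with shape and dtype")
        meta = json.loads(sidecar.read_text())
        if "shape" not in meta or "dtype" not in meta:
            raise ValueError("raw sidecar must carry 'shape' and 'dtype'")
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    elif path.is_dir():
        import imageio.v3 as iio

        frames = []
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValueError(f"no PNG/TIFF frames in {path}")
        for f in files:
            frames.append(np.asarray(iio.imread(f)))
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame shapes in series: {sorted(shapes)}")
        data = np.stack(frames)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 2D/3D TIFF, got shape {data.shape}")
    return Volume(data, spacing, origin)


def write_surface(
    s: SurfaceGrid,
    path: str | Path,
    format: str | None = None,
    config: PipelineConfig | None = None,
) -> None:
    """Write a surface as STL (mm units), PLY point cloud or gridded CSV.

    The format is inferred from the extension when not given.  STL/PLY get
    a JSON sidecar recording units, spacing and (optionally) the config
    hash; the CSV carries spacing in comment headers and round-trips via
    :func:`read_surface_csv`.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if s.heights.size == 0:
        raise ValueError("empty surface grid")
    if fmt == "stl":
        mesh = surface_to_mesh(s)
        tm = _trimesh.Trimesh(vertices=mesh.vertices / 1000.0, faces=mesh.faces, process=False)
        tm.export(path, file_type="stl")
    elif fmt == "ply":
        pts = surface_to_pointcloud(s)
        _trimesh.PointCloud(pts / 1000.0).export(path, file_type="ply")
    elif fmt == "csv":
        dy, dx = s.spacing
        header = (
            f"# tidemark heightmap, µm; rows = elevational index, columns = lateral index\n"
            f"# dy_um={dy!r} dx_um={dx!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, s.heights, delimiter=",", fmt="%.6f")
        return
    else:
        raise ValueError(f"unsupported surface format: {fmt!r} (use stl, ply or csv)")
    meta = {"units": "mm", "spacing_um": list(s.spacing)}
    if config is not None:
        meta["config_hash"] = config.hash()
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_surface_csv(path: str | Path) -> SurfaceGrid:
    """Read back a gridded CSV height table written by :func:`write_surface`."""
    path = Path(path)
    dy = dx = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "dy_um=" in line:
                parts = dict(tok.split("=") for tok in line.lstrip("# ").split())
                dy = float(parts["dy_um"])
                dx = float(parts["dx_um"])
                break
    if dy is None:
        raise ValueError("missing spacing header in surface CSV")
    heights = np.loadtxt(path, delimiter=",", comments="#")
    if heights.ndim == 1:
        heights = heights[None]
    return SurfaceGrid(heights, (dy, dx))
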