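"""Synthetic paired ultrasound / micro-CT phantoms of an osteochondral disk.

The generator emulates the imaging situation of a 3D high-frequency
ultrasound scan and a micro-CT scan of the same osteochondral disk: a single
ground-truth tidemark surface (the cartilage-bone interface) is shared by
both modalities, the CT volume lives in its own coordinate frame related to
the ultrasound frame by a known small rigid transform, and each modality
adds its characteristic structure — echo bands, speckle and crack shadows
for ultrasound; a calcified half-space, perforation channels and additive
noise for CT.

The ground-truth surface is decomposed into three retained components:

* a gently tilted plane,
* a low-frequency *waviness* component (two long-wavelength cosines),
* a band-limited random *roughness* field with a stated correlation length.

Keeping the components separate lets downstream metrology (waviness Sa/Sq
against an order-1 reference, roughness Sa/Sq against an order-5 reference)
be tested against how the surface was actually built.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .geometry import RigidTransform, SurfaceGrid, Volume, rotation_about_axis

__all__ = [
    "SynthParams",
    "GroundTruth",
    "ApproxProfile",
    "generate_ground_truth",
    "generate_ground_truth_surface",
    "simulate_us_volume",
    "simulate_ct_volume",
]


@dataclass
class SynthParams:
    """Parameters of the synthetic osteochondral disk pair.

    Geometry defaults follow the acquisition used throughout: a 7 x 7 mm
    scanned field, ultrasound B-scan pixels of 15 x 15 µm with a 32 µm
    elevational step, and isotropic 21 µm micro-CT voxels.

    Attributes
    ----------
    field_size_mm : lateral extent of the scanned square field.
    depth_mm : depth coverage of the simulated volumes.
    us_spacing_um : (elevational, axial, lateral) ultrasound spacing, µm.
    ct_spacing_um : (elevational, axial, lateral) micro-CT spacing, µm.
    waviness_amplitude_um : peak amplitude of the low-frequency surface
        undulation (µm); 0 disables it.
    roughness_amplitude_um : RMS amplitude of the band-limited random
        texture (µm); 0 disables it.
    roughness_correlation_um : Gaussian correlation length of the roughness
        field (µm).
    plane_slope : dimensionless slope (dz per unit lateral length) of the
        base plane in the ultrasound frame.
    cartilage_offset_um : depth separation between the cartilage-surface
        echo and the tidemark echo.
    tidemark_depth_um : mean tidemark depth below the transducer, µm.
    us_echo_cartilage, us_echo_tidemark : peak echo amplitudes of the two
        bright bands (arbitrary grayscale units, 8-bit-like scale).
    us_noise_floor : upper bound of the uniform background noise in the
        saline region.
    axial_resolution_um : FWHM of the axial point-spread function used to
        blur the echo bands.
    speckle_strength : 0..1 blend of correlated Rayleigh speckle
        multiplying the echo bands (0 = noise-free bands).
    ct_bone_level, ct_soft_level : CT intensities of calcified tissue and
        of the soft tissue above the tidemark.
    ct_noise_sd : standard deviation of additive Gaussian CT noise.
    crack_fraction : approximate fraction of ultrasound columns whose
        tidemark echo is suppressed (cracks).
    hole_fraction : approximate fraction of CT columns perforated by
        soft-tissue channels.
    tilt_deg : global tilt of the disk in the CT frame (rotation about the
        elevational axis).
    rot_z_deg : additional inter-modality rotation about the depth axis.
    translation_um : inter-modality translation (x, y, z), µm.
    margin_um : lateral margin over which the surface model extends beyond
        the field, so the rigidly offset CT field stays covered.
    seed : integer seed controlling every stochastic draw.
    """

    field_size_mm: float = 7.0
    depth_mm: float = 2.0
    us_spacing_um: tuple[float, float, float] = (32.0, 15.0, 15.0)
    ct_spacing_um: tuple[float, float, float] = (21.0, 21.0, 21.0)
    waviness_amplitude_um: float = 110.0
    # dominant undulation wavelength: an anatomical length scale of the
    # specimen (≈ 5.4 mm), deliberately NOT tied to the simulated field size
    waviness_wavelength_um: float = 5400.0
    roughness_amplitude_um: float = 30.0
    roughness_correlation_um: float = 150.0
    plane_slope: float = 0.01
    cartilage_offset_um: float = 600.0
    tidemark_depth_um: float = 1100.0
    us_echo_cartilage: float = 120.0
    us_echo_tidemark: float = 220.0
    us_noise_floor: float = 8.0
    axial_resolution_um: float = 40.0
    speckle_strength: float = 0.6
    ct_bone_level: float = 200.0
    ct_soft_level: float = 40.0
    ct_noise_sd: float = 5.0
    crack_fraction: float = 0.05
    hole_fraction: float = 0.05
    tilt_deg: float = 2.0
    rot_z_deg: float = 1.0
    translation_um: tuple[float, float, float] = (300.0, -200.0, 150.0)
    margin_um: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("us_spacing_um", "ct_spacing_um"):
            sp = getattr(self, name)
            if len(sp) != 3 or any(s <= 0 for s in sp):
                raise ValueError(f"{name} must be three positive components")
        if self.field_size_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("field and depth extents must be positive")
        if self.waviness_amplitude_um < 0 or self.roughness_amplitude_um < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.roughness_correlation_um <= 0:
            raise ValueError("roughness correlation length must be positive")
        if not 0 <= self.crack_fraction < 0.2 or not 0 <= self.hole_fraction < 0.2:
            raise ValueError("crack/hole fractions must lie in [0, 0.2)")
        if not 0 <= self.speckle_strength <= 1:
            raise ValueError("speckle_strength must lie in [0, 1]")
        depth_um = self.depth_mm * 1000.0
        worst = self.waviness_amplitude_um + 5 * self.roughness_amplitude_um
        worst += abs(self.plane_slope) * self.field_size_mm * 1000.0 / 2
        if self.tidemark_depth_um + worst >= depth_um or self.tidemark_depth_um - worst <= self.cartilage_offset_um / 2:
            raise ValueError("surface amplitudes exceed the simulated depth range")

    @property
    def field_um(self) -> float:
        return self.field_size_mm * 1000.0

    @property
    def depth_um(self) -> float:
        return self.depth_mm * 1000.0


class _SurfaceModel:
    """Continuous tidemark model z(x, y) in the ultrasound frame.

    Evaluable at arbitrary lateral coordinates inside
    ``[-margin, field + margin]``; the three components are retained.
    """

    def __init__(self, params: SynthParams, rng: np.random.Generator):
        f = params.field_um
        m = params.margin_um
        self.z0 = params.tidemark_depth_um
        half = f / 2.0
        # base plane through the field centre
        slope_dir = rng.uniform(0, 2 * np.pi)
        self.gx = params.plane_slope * np.cos(slope_dir)
        self.gy = params.plane_slope * np.sin(slope_dir)
        self.cx = half
        self.cy = half

        lam = params.waviness_wavelength_um
        amp = params.waviness_amplitude_um
        self._waves = []
        if amp > 0:
            phi1 = rng.uniform(0, 2 * np.pi)
            phi2 = rng.uniform(0, 2 * np.pi)
            th1 = rng.uniform(0, np.pi)
            th2 = th1 + np.pi / 2
            self._waves = [
                (0.7 * amp, lam, th1, phi1),
                (0.3 * amp, lam / 2.1, th2, phi2),
            ]

        # band-limited roughness on a fine grid, linear interpolation between
        self._rough_interp = None
        if params.roughness_amplitude_um > 0:
            h = min(15.0, params.roughness_correlation_um / 4.0)
            coords = np.arange(-m, f + m + h, h)
            white = rng.standard_normal((coords.size, coords.size))
            sigma = params.roughness_correlation_um / h
            smooth = ndimage.gaussian_filter(white, sigma, mode="wrap")
            smooth -= smooth.mean()
            smooth *= params.roughness_amplitude_um / smooth.std()
            self._rough_interp = RegularGridInterpolator(
                (coords, coords), smooth, method="linear", bounds_error=False, fill_value=0.0
            )

    def plane(self, x, y):
        return self.z0 + self.gx * (np.asarray(x) - self.cx) + self.gy * (np.asarray(y) - self.cy)

    def waviness(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast_shapes(x.shape, y.shape))
        for amp, lam, theta, phase in self._waves:
            u = x * np.cos(theta) + y * np.sin(theta)
            out = out + amp * np.cos(2 * np.pi * u / lam + phase)
        return out

    def roughness(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self._rough_interp is None:
            return np.zeros(np.broadcast_shapes(x.shape, y.shape))
        pts = np.stack(np.broadcast_arrays(y, x), axis=-1)
        return self._rough_interp(pts)

    def __call__(self, x, y):
        return self.plane(x, y) + self.waviness(x, y) + self.roughness(x, y)


@dataclass
class ApproxProfile:
    """Coarse per-(frame, column) tidemark depth estimate, µm.

    Stands in for the manually drawn profile of a semiautomatic
    segmentation; bounded within ±0.1 mm of the true surface so a 20-pixel
    search window centred on it always contains the true echo peak.
    """

    depths_um: np.ndarray

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        if self.depths_um.ndim != 2:
            raise ValueError("ApproxProfile must be (n_frames, n_lateral)")


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream stages must recover."""

    true_surface: SurfaceGrid  # on the US lateral grid, US frame
    true_transform: RigidTransform  # CT frame -> US frame
    crack_mask: np.ndarray  # (n_frames, n_lateral) bool, US grid
    hole_mask: np.ndarray  # (n_frames_ct, n_lateral_ct) bool, CT grid
    tilt_deg: float
    seed: int
    components: dict = field(default_factory=dict)  # plane / waviness / roughness on US grid
    model: _SurfaceModel | None = None

    def surface_ct_frame(self, params: SynthParams) -> SurfaceGrid:
        """True tidemark heightmap on the CT lateral grid, in the CT frame."""
        return _ct_frame_surface(self, params)


def _grid_1d(extent_um: float, step_um: float) -> np.ndarray:
    n = int(round(extent_um / step_um)) + 1
    return np.arange(n) * step_um


def _blob_mask(shape: tuple[int, int], spacing: tuple[float, float], fraction: float,
               radius_range_um: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Random union of elliptical blobs covering approximately ``fraction``
    of the lateral grid (never more than 20 %)."""
    mask = np.zeros(shape, dtype=bool)
    if fraction <= 0:
        return mask
    ny, nx = shape
    dy, dx = spacing
    yy = np.arange(ny)[:, None] * dy
    xx = np.arange(nx)[None, :] * dx
    target = fraction * ny * nx
    for _ in range(1000):
        if mask.sum() >= target:
            break
        cy = rng.uniform(0, (ny - 1) * dy)
        cx = rng.uniform(0, (nx - 1) * dx)
        ry = rng.uniform(*radius_range_um)
        rx = rng.uniform(*radius_range_um)
        mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if mask.mean() >= 0.2:  # safety: trim by eroding
        while mask.mean() >= 0.2:
            mask = ndimage.binary_erosion(mask)
    return mask


def generate_ground_truth(params: SynthParams) -> GroundTruth:
    """Draw the shared tidemark surface, defect masks and the true
    inter-modality rigid transform for one synthetic disk."""
    rng = np.random.default_rng(params.seed)
    model = _SurfaceModel(params, rng)

    ys = _grid_1d(params.field_um, params.us_spacing_um[0])
    xs = _grid_1d(params.field_um, params.us_spacing_um[2])
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    plane = model.plane(X, Y)
    wav = model.waviness(X, Y)
    rough = model.roughness(X, Y)
    heights = plane + wav + rough
    if heights.min() <= 0 or heights.max() >= params.depth_um:
        raise ValueError("generated surface leaves the simulated depth range")
    surface = SurfaceGrid(heights, (params.us_spacing_um[0], params.us_spacing_um[2]))

    crack = _blob_mask(heights.shape, surface.spacing, params.crack_fraction,
                       (60.0, 200.0), rng)

    ys_ct = _grid_1d(params.field_um, params.ct_spacing_um[0])
    xs_ct = _grid_1d(params.field_um, params.ct_spacing_um[2])
    hole = _blob_mask((ys_ct.size, xs_ct.size),
                      (params.ct_spacing_um[0], params.ct_spacing_um[2]),
                      params.hole_fraction, (40.0, 110.0), rng)

    rot = rotation_about_axis("z", params.rot_z_deg) @ rotation_about_axis("y", params.tilt_deg)
    transform = RigidTransform(rot, np.asarray(params.translation_um, dtype=float))

    return GroundTruth(
        true_surface=surface,
        true_transform=transform,
        crack_mask=crack,
        hole_mask=hole,
        tilt_deg=params.tilt_deg,
        seed=params.seed,
        components={"plane": plane, "waviness": wav, "roughness": rough},
        model=model,
    )


def generate_ground_truth_surface(params: SynthParams) -> SurfaceGrid:
    """Convenience: just the ground-truth heightmap on the US grid."""
    return generate_ground_truth(params).true_surface


def _ct_frame_surface(gt: GroundTruth, params: SynthParams) -> SurfaceGrid:
    """Solve per CT column for the depth z_ct with T(x, y, z_ct) on the
    US-frame surface; fixed-point iteration (rotations are small)."""
    if gt.model is None:
        raise ValueError("ground truth lacks its continuous surface model")
    ys = _grid_1d(params.field_um, params.ct_spacing_um[0])
    xs = _grid_1d(params.field_um, params.ct_spacing_um[2])
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    R = gt.true_transform.rotation
    t = gt.true_transform.translation
    z = np.full(X.shape, params.tidemark_depth_um)
    rzz = R[2, 2]
    for _ in range(30):
        px = R[0, 0] * X + R[0, 1] * Y + R[0, 2] * z + t[0]
        py = R[1, 0] * X + R[1, 1] * Y + R[1, 2] * z + t[1]
        pz = R[2, 0] * X + R[2, 1] * Y + R[2, 2] * z + t[2]
        resid = gt.model(px, py) - pz
        z = z + resid / rzz
        if np.max(np.abs(resid)) < 1e-9:
            break
    return SurfaceGrid(z, (params.ct_spacing_um[0], params.ct_spacing_um[2]))


def _correlated_speckle(shape: tuple[int, int, int], sigmas: tuple[float, float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-mean Rayleigh-distributed texture with resolution-cell-sized
    correlation, built as the envelope of a filtered complex Gaussian."""
    re = ndimage.gaussian_filter(rng.standard_normal(shape), sigmas, mode="nearest")
    im = ndimage.gaussian_filter(rng.standard_normal(shape), sigmas, mode="nearest")
    env = np.sqrt(re * re + im * im)
    return env / env.mean()


def simulate_us_volume(gt: GroundTruth, params: SynthParams) -> tuple[Volume, ApproxProfile]:
    """Render the B-scan stack for one disk.

    Layout per column, top to bottom: a dark saline region whose noise never
    exceeds ``us_noise_floor``; a bright cartilage-surface echo band; a
    brighter tidemark echo band centred on the true surface and blurred to
    the stated axial resolution; near-zero signal below (strong interface
    reflection shadows the deeper bone).  Crack columns carry no tidemark
    echo.  Also returns the surrogate manually-drawn profile.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    dy, dz, dx = params.us_spacing_um
    surf = gt.true_surface.heights
    ny, nx = surf.shape
    nz = int(round(params.depth_um / dz)) + 1
    zc = np.arange(nz) * dz  # row centre depths

    sigma_ax = params.axial_resolution_um / 2.355  # FWHM -> Gaussian sigma

    zgrid = zc[None, :, None]
    tide = surf[:, None, :]
    cart = tide - params.cartilage_offset_um

    band_tide = np.exp(-0.5 * ((zgrid - tide) / sigma_ax) ** 2).astype(np.float32)
    band_cart = np.exp(-0.5 * ((zgrid - cart) / sigma_ax) ** 2).astype(np.float32)
    band_tide[np.broadcast_to(gt.crack_mask[:, None, :], band_tide.shape)] = 0.0

    signal = params.us_echo_tidemark * band_tide + params.us_echo_cartilage * band_cart
    if params.speckle_strength > 0:
        sig_vox = (
            2 * 32.0 / dy,  # elevational beam width spans > one step
            sigma_ax / dz,
            80.0 / 2.355 / dx,  # lateral resolution ~80 µm
        )
        tex = _correlated_speckle(signal.shape, sig_vox, rng).astype(np.float32)
        w = params.speckle_strength
        signal *= (1.0 - w) + w * tex

    noise = rng.uniform(0.0, params.us_noise_floor, size=signal.shape).astype(np.float32)
    vol = np.maximum(signal, noise)

    volume = Volume(vol, (dy, dz, dx))

    # surrogate manual profile: smooth bounded perturbation of the truth
    pert = ndimage.gaussian_filter(rng.standard_normal(surf.shape), (3, 12), mode="nearest")
    mx = np.abs(pert).max()
    if mx > 0:
        pert *= 80.0 / mx  # |Δz| ≤ 80 µm < 0.1 mm
    approx = ApproxProfile(surf + pert)
    return volume, approx


def simulate_ct_volume(gt: GroundTruth, params: SynthParams) -> Volume:
    """Render the micro-CT volume in the CT frame.

    Calcified (high-intensity) tissue fills the half-space below the true
    surface, which in the CT frame carries the global tilt and the rigid
    inter-modality offset; perforation columns are soft-tissue channels
    through the calcified plate; additive Gaussian noise throughout.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    dy, dz, dx = params.ct_spacing_um
    surf_ct = gt.surface_ct_frame(params).heights
    ny, nx = surf_ct.shape
    nz = int(round(params.depth_um / dz)) + 1
    zc = np.arange(nz) * dz

    # partial-volume blend at the interface: fraction of voxel below surface
    frac = np.clip((zc[None, :, None] - surf_ct[:, None, :]) / dz + 0.5, 0.0, 1.0)
    vol = params.ct_soft_level + (params.ct_bone_level - params.ct_soft_level) * frac
    vol = vol.astype(np.float32)

    if gt.hole_mask.any():
        # channels through the plate: no calcified tissue from just above the
        # interface down to 800 µm below it
        hole = gt.hole_mask[:, None, :]
        depth_rel = zc[None, :, None] - surf_ct[:, None, :]
        in_channel = hole & (depth_rel > -2 * dz) & (depth_rel < 800.0)
        vol[np.broadcast_to(in_channel, vol.shape)] = params.ct_soft_level

    if params.ct_noise_sd > 0:
        vol += rng.normal(0.0, params.ct_noise_sd, size=vol.shape).astype(np.float32)
        np.clip(vol, 0.0, None, out=vol)
    return Volume(vol, (dy, dz, dx))


def disk_params(seed: int, waviness_um: float = 110.0, roughness_um: float = 30.0,
                field_size_mm: float = 7.0, **overrides) -> SynthParams:
    """Parameters for one disk of a cohort, with per-disk seed-derived
    rigid offset (rotation ≤ 3°, translation ≤ 500 µm per axis)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    # lateral offsets scale with the simulated field so the two modality
    # windows keep the overlap fraction of the full-size geometry
    t_lat = 500.0 * field_size_mm / 7.0
    base = SynthParams(
        field_size_mm=field_size_mm,
        waviness_amplitude_um=waviness_um,
        roughness_amplitude_um=roughness_um,
        tilt_deg=float(rng.uniform(-3, 3)),
        rot_z_deg=float(rng.uniform(-2, 2)),
        translation_um=(
            float(rng.uniform(-t_lat, t_lat)),
            float(rng.uniform(-t_lat, t_lat)),
            float(rng.uniform(-500, 500)),
        ),
        seed=int(seed),
    )
    return replace(base, **overrides) if overrides else base
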