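# Methods

`osteosurf` quantifies the 3D morphology of the tidemark — the interface
between noncalcified cartilage and the calcified cartilage zone — from two
volumetric modalities imaging the same osteochondral disk: a stack of
high-frequency B-mode ultrasound frames and a micro-CT volume.  This note
records the models, the tunable parameters, the numerical choices, and what
the synthetic phantoms do and do not establish about real data.

## Coordinate and unit conventions

All physical lengths are micrometres.  Volumes are indexed
`(frame, depth_row, lateral_column)`; the depth axis `z` increases downward
(away from the transducer / source).  A node or voxel at index `k` along an
axis with spacing `d` sits at `origin + k·d` (node-centred model).  Point
clouds are `(N, 3)` arrays with columns `(x lateral, y elevational, z depth)`.
The default geometry follows the acquisition this pipeline targets: a
7 × 7 mm scanned field, ultrasound pixels of 15 × 15 µm in-frame with a
32 µm elevational step (220 frames over 7 mm), and isotropic 21 µm CT
voxels.  STL export converts to millimetres (recorded in the sidecar);
everything internal stays in µm.

## Ultrasound surface extraction

The tidemark produces the second bright echo band in each B-scan (the first
is the cartilage surface).  Extraction is semiautomatic: a coarse profile —
manually drawn in practice, a surrogate in the phantoms — centres a
20-pixel (~0.30 mm) search window per image column, and the *first peak*
above a noise threshold inside that window is the tidemark point.

Design choices the procedure leaves open, fixed here:

* **Noise threshold** — mean + `k`·SD of the saline region above the
  cartilage echo, `k = 3` by default (`noise_k` in `PipelineConfig`).
* **"First peak"** — the shallowest strict local maximum above threshold;
  plateaus resolve to their shallowest sample; window-boundary samples
  never qualify (a monotone rise into the window edge is not a verified
  peak).
* **Sub-pixel refinement** — off by default; an optional three-point
  parabolic fit is available (`refine_subpixel`).
* **Cracks** — a column with no qualifying peak is a crack: flagged in the
  surface validity mask and filled by 1D linear interpolation along the
  lateral axis of its own frame (nearest-valid extension at frame edges),
  matching the per-image processing structure.  No 2D inpainting.

## Micro-CT surface extraction

The calcified tissue is segmented by a global Otsu threshold (256-bin
histogram, ties toward the lower threshold; a per-frame option exists), and
the tidemark is the first abrupt soft-to-calcified transition per vertical
line, operationalised as the first run of at least `ct_min_run = 2`
above-threshold voxels so isolated bright noise voxels cannot fire the
detector.  Two guards reject non-tidemark structure:

* transitions farther than `ct_interface_window_um = 500` from the median
  interface depth (deep trabecular surfaces, perforation channel floors);
* transitions deviating more than 150 µm from the median-filtered surface
  (`local_outlier_um`) — a vertical scan down the *wall* of a slanted
  perforation channel yields a locally implausible depth that can
  nevertheless pass the global window.

Rejected and missing columns are holes: flagged and filled per frame
exactly as ultrasound cracks.

Tilt handling: `estimate_tilt` averages all frames, finds the interface of
the averaged image per column, and fits a least-squares line; its angle is
defined so that `rotate_volume(vol, -estimate_tilt(vol))` levels the
interface (per-frame in-plane rotation, bilinear, out-of-field voxels take
the volume minimum).  The standalone CT operator levels by default, and
crops the lateral margin of `tan(tilt)·n_depth/2` columns that the rotation
fills with out-of-field values.  The *end-to-end pipeline* leaves the
volume unrotated (`ct_tilt_correct = False`): at the tilts handled here
(≤ ~3°) the per-column transition scan needs no levelling, the subsequent
rigid registration absorbs the tilt exactly, and rotation resampling
measurably degrades the extracted surface around perforation channels
(their walls become slanted, producing the outlier class described above).

## Registration and the discrepancy statistic

The ultrasound surface, as a point cloud with one point per grid node, is
registered onto the triangulated CT surface (two triangles per grid cell)
by point-to-point ICP: nearest-neighbour correspondences from a KD-tree,
closed-form rigid fit per iteration via the cross-covariance SVD
construction (reflection case corrected), stopping when the RMS
correspondence distance changes by less than `icp_tol_um = 0.01` between
iterations, with a 200-iteration cap.  The recorded RMS sequence is
monotonically non-increasing.

Initialisation stands in for the manual coarse alignment that precedes ICP
in interactive tools: the default aligns centroids; a principal-axes option
exists but is *not* the default because the principal axes of a near-square
heightmap field are ambiguous and can lock the registration into a ~180°
flipped minimum.  Because a nearly flat lattice can also lock into a
laterally slipped minimum under in-plane rotation error, `icp_register`
optionally sweeps a small set of in-plane rotation starting offsets
(`rotation_starts_deg`) and keeps the run with the lowest final RMS; the
pipeline uses offsets (0, ±2.5°, ±5°).

After registration the discrepancy is

    D_diff = (1/N) Σ_i d(p_US,i, s_mCT),

the mean *unsigned* Euclidean distance from each ultrasound point to the
nearest point on any CT triangle (interior, edge or vertex; exact
Voronoi-region closest-point computation with KD-tree candidate pruning
and a certified fallback).  The standard deviation is reported alongside.
Two pipeline-level adjustments handle the partial overlap of the two
fields: ICP trims the worst 15 % of correspondences per iteration, and the
statistic is evaluated only over points whose registered position falls
inside the CT grid's lateral extent — a point carried past the mesh edge
would otherwise measure its lateral overhang to the mesh rim, which is not
a surface discrepancy.

## Waviness and roughness

Two areal indices are computed against a least-squares polynomial reference
surface SR fitted to the heightmap `s(i, j)` (coordinates centred and
scaled to [-1, 1] for conditioning):

    Sa = (1/MN) Σ |s − SR|          Sq = sqrt((1/MN) Σ (s − SR)²)

With an order-1 reference (basis {1, x, y}: a tilted plane) they are the
waviness SWa/SWq; with an order-5 reference (all 21 monomials of total
degree ≤ 5) they are the roughness SRa/SRq.  Sa ≤ Sq always (power-mean
inequality) and SRq ≤ SWq (nested bases).  Fits use equal weights on all
grid nodes including interpolated ones, matching a workflow that
interpolates defects before computing indices; `exclude_invalid` drops
flagged nodes from the fit.  Cohort-level agreement between modalities is
summarised by the sample Pearson correlation with a two-sided t-test
(n − 2 degrees of freedom), significant at p < 0.05.

## En face imaging

`flatten_volume` resamples every lateral column (1D linear interpolation
along depth) so the extracted tidemark sits at depth index 0; samples past
the data are zero-filled and masked.  `project` collapses the slab
`[offset, offset + thickness)` — measured *downward* from the tidemark,
into the calcified side — by per-column maximum (MIP) or mean (AIP).  AIP
averages only unmasked samples, avoiding edge darkening from fill values.
MIP is pointwise ≥ AIP and monotone non-decreasing in slab thickness;
perforation channels appear as dark holes.

## The synthetic phantom

Real paired scans of osteochondral disks are not redistributable, so the
package carries a generator whose output exercises every stage against a
known truth.  One continuous surface model per disk is shared by both
modalities:

* a base plane through the field centre (slope 0.01, random azimuth);
* a *waviness* component: two cosines (70 % / 30 % amplitude split,
  orthogonal azimuths) with a dominant wavelength of 5.4 mm.  This is an
  anatomical length scale of the specimen and deliberately does **not**
  shrink with the simulated field size — cropping a window out of a disk
  does not steepen its undulation;
* a *roughness* component: a Gaussian random field with 150 µm correlation
  length, scaled to a stated RMS amplitude, linearly interpolated from a
  fine lattice.

Defaults: waviness amplitude 110 µm, roughness RMS 30 µm, tidemark at
1.1 mm depth, 2 mm simulated depth.  The ultrasound rendering places a
uniform noise floor (≤ 8 grey levels) over everything, a cartilage echo
band 0.6 mm above the tidemark (peak 120), and the tidemark band
(peak 220) blurred axially to the 40 µm resolution, multiplied by
correlated Rayleigh speckle (envelope of a PSF-filtered complex Gaussian,
blended at strength 0.6); crack columns (~5 % of the grid, elliptical
blobs) carry no tidemark echo.  The surrogate manual profile is the true
surface plus a smooth perturbation bounded at 80 µm (< 0.1 mm, so the
20-pixel window always contains the peak).  The CT rendering fills the
half-space below the surface with intensity 200 over a soft background of
40 (partial-volume blending at the interface), adds Gaussian noise
(SD 5), and carves perforation channels (~5 % of columns) from just above
the interface to 800 µm below it.  The CT frame is offset from the
ultrasound frame by a known rigid transform: tilt about the elevational
axis (≤ 3°), in-plane rotation (≤ 2°) and translation; lateral translation
bounds scale with the field size (500 µm at the 7 mm field) so the overlap
*fraction* of the two windows matches the full-size geometry.  A single
integer seed determines every draw.

What the phantom does not emulate: acoustic refraction, attenuation and
speed-of-sound errors; angle-dependent echo amplitude; real trabecular
micro-architecture; CT beam hardening.  Passing tests therefore establish
the correctness of the *computational* pipeline under controlled
conditions, not the accuracy of either imaging modality on tissue.

## Problem sizes and verification

The test suite and the acceptance script verify, among others:

* analytic limits Sa → 2A/π and Sq → A/√2 on a dense full-period cosine
  after order-1 detrending (1 % tolerance), and the Sa ≤ Sq / SRq ≤ SWq
  inequalities on random surfaces;
* exhaustive-scan oracle equivalence for the Otsu threshold (evaluated on
  the binned objective: exact ties on empty-valley plateaus are resolved
  arbitrarily but induce identical partitions), for point-to-mesh distance
  (all-triangle scan with an independently formulated point-triangle
  routine) and for Sa/Sq (double-loop summation);
* ICP recovery of 20 random rigid perturbations (rotation ≤ 5°,
  translation ≤ 1 mm) of a 10,000-point surface-like cloud to < 1 µm and
  < 0.01°, with monotone RMS and the 0.01 µm stopping rule;
* per-column recovery of the true surface within one axial voxel on
  noise-free phantoms at the full 7 × 7 mm acquisition geometry;
* a 15-disk study at a 2 mm field (chosen so the whole cohort runs in
  about a minute) spanning waviness 50–180 µm and roughness 20–40 µm, with
  per-disk mean discrepancy within the coarsest sampling step (32 µm) and
  ultrasound-vs-CT panel correlations r ≥ 0.9 (p < 0.05).

`scripts/acceptance.py` re-runs the 15-disk study from scratch for a given
seed and writes the summary numbers (mean ± SD discrepancy, per-index
correlations, panel means) as JSON.

## Known limitations

* The discrepancy statistic depends on the overlap convention; whole-cloud
  values (CLI `register` on two bare surfaces) include rim overhang and
  run higher than the pipeline's overlap-restricted values.
* Waviness measured on a window much smaller than the undulation
  wavelength is largely absorbed by the order-1 reference; small-field
  SWa values are therefore not comparable across field sizes.
* The CT intensity scale is arbitrary; no densitometric calibration is
  modelled, and no distance-scale cross-calibration between modalities is
  attempted (none is defined for the real instruments either).
* `estimate_tilt` conflates specimen tilt with the apparent linear trend
  of the waviness inside the scanned window; this is inherent to defining
  tilt from the image content alone.
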