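"""Micro-CT surface extraction: tilt estimation/correction, Otsu threshold
against a brute-force oracle, first-transition detection and hole filling."""

import numpy as np
import pytest

from osteosurf.ct_extraction import (
    binarize,
    estimate_tilt,
    extract_surface_3d_ct,
    extract_surface_ct_pipeline,
    otsu_threshold,
    rotate_volume,
)
from osteosurf.geometry import BinaryVolume, Volume

ISO = (21.0, 21.0, 21.0)


def _halfspace_volume(nz=80, nx=60, ny=4, surface_rows=None, lo=10.0, hi=200.0):
    """Soft tissue above ``surface_rows`` per column, calcified below."""
    if surface_rows is None:
        surface_rows = np.full(nx, nz // 2)
    data = np.full((ny, nz, nx), lo)
    for j, r in enumerate(np.asarray(surface_rows, dtype=int)):
        data[:, r:, j] = hi
    return Volume(data, ISO)


def brute_force_otsu(values, n_bins=256):
    """Independent oracle: exhaustive between-class-variance maximization
    over all histogram cut points.  Returns (threshold, variance-at-cut
    evaluator) because empty valley bins create exact ties: any threshold
    on such a plateau induces the same partition of the data."""
    counts, edges = np.histogram(values, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()

    def var_at(threshold):
        lo = centers <= threshold
        w0 = counts[lo].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            return -np.inf
        mu0 = (counts[lo] * centers[lo]).sum() / w0
        mu1 = (counts[~lo] * centers[~lo]).sum() / w1
        return w0 * w1 * (mu0 - mu1) ** 2

    best_t, best_var = None, -1.0
    for cut in range(1, n_bins):
        w0 = counts[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:cut] * centers[:cut]).sum() / w0
        mu1 = (counts[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = centers[cut - 1]
    return best_t, var_at


class TestTilt:
    def test_horizontal_interface_gives_zero(self):
        vol = _halfspace_volume()
        assert estimate_tilt(vol) == pytest.approx(0.0, abs=1e-6)

    def test_known_tilt_recovered(self):
        # enough columns that the one-voxel staircase averages out
        nz, nx = 200, 400
        x = np.arange(nx)
        slope = np.tan(np.radians(2.0))
        rows = np.round(60 + slope * x).astype(int)  # isotropic voxels
        vol = _halfspace_volume(nz=nz, nx=nx, surface_rows=rows)
        assert estimate_tilt(vol) == pytest.approx(2.0, abs=0.1)

    def test_correction_is_a_fixed_point(self):
        nz, nx = 200, 400
        rows = np.round(60 + np.tan(np.radians(3.0)) * np.arange(nx)).astype(int)
        vol = _halfspace_volume(nz=nz, nx=nx, surface_rows=rows)
        tilt = estimate_tilt(vol)
        levelled = rotate_volume(vol, -tilt)
        assert abs(estimate_tilt(levelled)) < 0.3

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            estimate_tilt(Volume(np.ones((2, 10, 10)), ISO))


class TestRotate:
    def test_zero_angle_is_identity(self):
        vol = _halfspace_volume()
        out = rotate_volume(vol, 0.0)
        assert np.array_equal(out.intensities, vol.intensities)

    def test_round_trip_within_resampling_tolerance(self, rng):
        # smooth content: bilinear resampling cannot round-trip white noise
        from scipy.ndimage import gaussian_filter

        data = gaussian_filter(rng.uniform(0, 255, size=(3, 60, 60)), (0, 3, 3))
        data *= 255 / data.max()
        vol = Volume(data, ISO)
        back = rotate_volume(rotate_volume(vol, 4.0), -4.0)
        interior = (slice(None), slice(10, 50), slice(10, 50))
        mad = np.abs(back.intensities[interior] - data[interior]).mean()
        assert mad < 0.02 * 255

    def test_constant_volume_stays_constant(self):
        vol = Volume(np.full((2, 40, 40), 7.0), ISO)
        out = rotate_volume(vol, 5.0)
        assert np.allclose(out.intensities, 7.0)

    def test_large_angle_rejected(self):
        with pytest.raises(ValueError):
            rotate_volume(_halfspace_volume(), 20.0)


class TestOtsu:
    def test_two_point_histogram_separates_masses(self):
        data = np.concatenate([np.zeros(50), np.full(50, 255.0)])
        vol = Volume(data.reshape(1, 10, 10), ISO)
        thr = otsu_threshold(vol)
        assert 0 < thr < 255
        assert (vol.intensities > thr).sum() == 50

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        n = 4000
        mix = np.concatenate(
            [
                rng.normal(rng.uniform(20, 80), rng.uniform(3, 15), n // 2),
                rng.normal(rng.uniform(120, 220), rng.uniform(5, 25), n - n // 2),
            ]
        )
        vol = Volume(np.clip(mix, 0, 255).reshape(1, 40, 100), ISO)
        t_impl = otsu_threshold(vol)
        t_oracle, var_at = brute_force_otsu(vol.intensities.ravel())
        # the implementation must achieve the exhaustive-scan maximum of the
        # between-class variance (thresholds themselves may sit anywhere on
        # an exact-tie plateau of the discrete objective)
        assert var_at(t_impl) >= var_at(t_oracle) * (1 - 1e-10)

    def test_affine_intensity_map_shifts_threshold(self, rng):
        base = np.concatenate([rng.normal(50, 5, 500), rng.normal(150, 10, 500)])
        vol = Volume(base.reshape(1, 20, 50), ISO)
        t0 = otsu_threshold(vol)
        a, b = 2.0, 31.0
        mapped = Volume(a * vol.intensities + b, ISO)
        t1 = otsu_threshold(mapped)
        assert t1 == pytest.approx(a * t0 + b, abs=a * (base.max() - base.min()) / 256)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(Volume(np.full((1, 5, 5), 9.0), ISO))

    def test_binarization_monotone_in_threshold(self, rng):
        vol = Volume(rng.uniform(0, 100, size=(2, 20, 20)), ISO)
        counts = [binarize(vol, t).values.sum() for t in (10, 30, 50, 70)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSurfaceFromBinary:
    def test_flat_interface_forced_heights(self):
        vol = _halfspace_volume(surface_rows=np.full(60, 50))
        binv = binarize(vol, 100.0)
        surf = extract_surface_3d_ct(binv)
        assert np.allclose(surf.heights, 50 * 21.0)

    def test_hole_column_filled_by_linear_midpoint(self):
        nx = 21
        rows = np.full(nx, 50)
        rows[:10] = 50  # z = 1050
        rows[11:] = 52  # z = 1092
        vol = _halfspace_volume(nx=nx, surface_rows=rows)
        data = vol.intensities.copy()
        data[:, :, 10] = 10.0  # no calcified tissue in the hole column
        surf = extract_surface_3d_ct(binarize(Volume(data, ISO), 100.0))
        assert surf.heights[0, 10] == pytest.approx((1050 + 1092) / 2)
        assert not surf.valid_mask[0, 10]

    def test_stepped_interface_reproduced_exactly(self):
        rows = np.r_[np.full(30, 40), np.full(30, 60)]
        vol = _halfspace_volume(nz=100, nx=60, surface_rows=rows)
        surf = extract_surface_3d_ct(binarize(vol, 100.0))
        assert np.array_equal(surf.heights[0] / 21.0, rows)

    def test_empty_volume_rejected(self):
        binv = BinaryVolume(np.zeros((2, 10, 10), dtype=bool), ISO)
        with pytest.raises(ValueError):
            extract_surface_3d_ct(binv)

    def test_isolated_noise_voxel_above_interface_ignored(self):
        vol = _halfspace_volume(surface_rows=np.full(60, 50))
        data = vol.intensities.copy()
        data[0, 20, 5] = 250.0  # single bright voxel well above the interface
        surf = extract_surface_3d_ct(binarize(Volume(data, ISO), 100.0), min_run=2)
        assert surf.heights[0, 5] == pytest.approx(50 * 21.0)


class TestRecovery:
    def test_noise_free_recovery_within_one_voxel(self, clean_params, clean_gt, clean_ct):
        surf, _ = extract_surface_ct_pipeline(clean_ct, tilt_correct=False)
        truth = clean_gt.surface_ct_frame(clean_params)
        err = surf.heights - truth.heights
        assert np.sqrt((err**2).mean()) <= clean_params.ct_spacing_um[1]

    def test_hole_columns_flagged_and_filled(self, noisy_params, noisy_gt, noisy_ct):
        surf, _ = extract_surface_ct_pipeline(noisy_ct, tilt_correct=False)
        assert np.isfinite(surf.heights).all()
        frac_flagged = (~surf.valid_mask[noisy_gt.hole_mask]).mean()
        assert frac_flagged > 0.9
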