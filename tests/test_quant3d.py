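import numpy as np
import pytest
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

import liquidstem as ls
from liquidstem import virtual_scope as vs
from liquidstem.quant3d import (
    Volume,
    csr_envelope,
    detect_beads,
    fsc,
    local_thickness,
    pair_correlation,
    pore_size_distribution,
    projection_residual_norm,
    reconstruct_sart,
    resolution_at,
    volume_change,
)


def _sphere_mask(shape, center, radius):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius**2


def brute_force_pcf(points, box, r_max, n_bins):
    """O(n^2) oracle with explicit pair loop and translational weights."""
    box = np.asarray(box, dtype=float)
    volume = float(np.prod(box))
    n = len(points)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    acc = np.zeros(n_bins)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = points[i] - points[j]
            r = np.sqrt(np.sum(d * d))
            if r >= r_max:
                continue
            k = int(np.searchsorted(edges, r, side="right")) - 1
            if 0 <= k < n_bins:
                acc[k] += volume / np.prod(box - np.abs(d))
    lam2 = n * (n - 1) / volume**2
    return acc / (lam2 * volume * shell_vol)


class TestSART:
    def test_zero_projections_give_zero_volume(self):
        beam = vs.BeamConfig(pixel_size_nm=2.0, frame_shape=(16, 16))
        frames = [
            vs.Frame(np.zeros((16, 16), np.float32), a, beam, beam.dose_per_image, i)
            for i, a in enumerate((-30.0, 0.0, 30.0))
        ]
        series = vs.TiltSeries(frames=frames, plan=ls.make_tilt_plan(-30, 30, 30))
        vol = reconstruct_sart(series, n_iter=3)
        assert np.all(vol.grid == 0)

    def test_recovers_bead_phantom(self, clean_series, slab_bead_phantom):
        vol = reconstruct_sart(clean_series, n_iter=8)
        ncc = np.corrcoef(vol.grid.ravel(), slab_bead_phantom.density.ravel())[0, 1]
        assert ncc > 0.8

    def test_residual_non_increasing_on_consistent_data(self, slab_bead_phantom):
        plan = ls.make_tilt_plan(-60, 60, 10)
        series = vs.acquire_series(slab_bead_phantom, plan, controller=None)
        norms = [
            projection_residual_norm(reconstruct_sart(series, n_iter=k), series)
            for k in (1, 3, 6)
        ]
        assert norms[1] <= norms[0] * 1.01
        assert norms[2] <= norms[1] * 1.01

    def test_momentum_variant_also_converges(self, clean_series, slab_bead_phantom):
        vol = reconstruct_sart(clean_series, n_iter=6, momentum=True)
        ncc = np.corrcoef(vol.grid.ravel(), slab_bead_phantom.density.ravel())[0, 1]
        assert ncc > 0.75

    def test_mismatched_frame_shapes_raise(self):
        beam = vs.BeamConfig(pixel_size_nm=2.0, frame_shape=(16, 16))
        frames = [
            vs.Frame(np.zeros((16, 16), np.float32), -10.0, beam, 1.0, 0),
            vs.Frame(np.zeros((8, 8), np.float32), 0.0, beam, 1.0, 1),
            vs.Frame(np.zeros((16, 16), np.float32), 10.0, beam, 1.0, 2),
        ]
        series = vs.TiltSeries(frames=frames, plan=ls.make_tilt_plan(-10, 10, 10))
        with pytest.raises(ValueError):
            reconstruct_sart(series, n_iter=1)


class TestFSC:
    def test_identity_correlation_is_one(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(32, 32, 32)), 1.0)
        curve = fsc(v, v)
        assert np.allclose(curve.correlation[curve.shell_counts > 0], 1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = Volume(rng.normal(size=(24, 24, 24)), 1.0)
        b = Volume(rng.normal(size=(24, 24, 24)), 1.0)
        assert np.array_equal(fsc(a, b).correlation, fsc(b, a).correlation)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(2)
        a = Volume(rng.normal(size=(64, 64, 64)), 1.0)
        b = Volume(rng.normal(size=(64, 64, 64)), 1.0)
        curve = fsc(a, b)
        assert np.all(np.abs(curve.correlation[1:]) < 0.2)

    def test_band_limited_signal_crosses_near_band_limit(self):
        rng = np.random.default_rng(3)
        signal = ndi.gaussian_filter(rng.normal(size=(48, 48, 48)), 3.0)
        signal /= signal.std()
        a = Volume(signal + 0.4 * rng.normal(size=signal.shape), 1.0)
        b = Volume(signal + 0.4 * rng.normal(size=signal.shape), 1.0)
        curve = fsc(a, b)
        # high correlation at low frequency, none near Nyquist
        assert curve.correlation[1] > 0.9
        assert abs(curve.correlation[-2]) < 0.3

    def test_shape_mismatch_raises(self):
        a = Volume(np.zeros((8, 8, 8)), 1.0)
        b = Volume(np.zeros((16, 16, 16)), 1.0)
        with pytest.raises(ValueError):
            fsc(a, b)


class TestResolutionAt:
    def test_identity_curve_is_nyquist_limited(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(32, 32, 32)), 2.0)
        est = resolution_at(fsc(v, v), 0.5)
        assert est.nyquist_limited
        assert est.resolution_nm == pytest.approx(2 * 2.0)

    def test_linear_interpolation_of_crossing(self):
        from liquidstem.quant3d import FSCCurve

        # crosses 0.5 exactly at 0.05 cycles/nm -> 20 nm
        curve = FSCCurve(
            shell_freq=np.array([0.0, 0.02, 0.04, 0.06, 0.08]),
            correlation=np.array([1.0, 1.0, 0.75, 0.25, 0.0]),
            shell_counts=np.ones(5, dtype=int),
            nyquist=0.1,
        )
        est = resolution_at(curve, 0.5)
        assert est.resolution_nm == pytest.approx(20.0)

    def test_criterion_ordering_for_monotone_curves(self):
        from liquidstem.quant3d import FSCCurve

        rng = np.random.default_rng(4)
        for _ in range(10):
            corr = np.sort(rng.uniform(-0.1, 1.0, 12))[::-1]
            curve = FSCCurve(
                shell_freq=np.linspace(0, 0.11, 12), correlation=corr,
                shell_counts=np.ones(12, dtype=int), nyquist=0.12,
            )
            r143 = resolution_at(curve, 0.143).resolution_nm
            r500 = resolution_at(curve, 0.5).resolution_nm
            assert r143 <= r500 + 1e-9


class TestDetectBeads:
    def test_empty_volume(self):
        vol = Volume(np.zeros((16, 16, 16)), 2.0)
        assert len(detect_beads(vol, 8.0)) == 0

    def test_two_bead_recovery(self):
        grid = np.zeros((32, 32, 32))
        grid[_sphere_mask(grid.shape, (10, 16, 10), 3)] = 1.0
        grid[_sphere_mask(grid.shape, (22, 16, 24), 3)] = 1.0
        centers = detect_beads(Volume(grid, 1.0), 6.0, threshold=0.2)
        assert len(centers) == 2
        d, _ = cKDTree(centers).query([[10, 16, 10], [22, 16, 24]])
        assert np.all(d < 0.5)

    def test_phantom_density_recovery(self):
        ph = ls.make_bead_phantom(30, box_nm=(200, 200, 200), bead_radius_nm=8,
                                  seed=5, voxel_size_nm=2)
        det = detect_beads(Volume(ph.density.astype(float), 2.0), 16.0, threshold=0.2)
        gt = ph.ground_truth["bead_centers_nm"]
        d, _ = cKDTree(det).query(gt)
        assert (d < 8.0).mean() >= 0.95
        spurious, _ = cKDTree(gt).query(det)
        assert (spurious > 8.0).mean() <= 0.05


class TestPairCorrelation:
    def test_two_point_pattern(self):
        pts = np.array([[10.0, 50.0, 50.0], [40.0, 50.0, 50.0]])  # distance 30
        res = pair_correlation(pts, (100.0, 100.0, 100.0), 50.0, 10)
        nonzero = np.flatnonzero(res.g)
        assert list(nonzero) == [6]  # 30 nm falls in bin [30, 35)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for n in (10, 50, 100):
            pts = rng.uniform(0, 100, (n, 3))
            res = pair_correlation(pts, (100.0, 100.0, 100.0), 40.0, 16)
            oracle = brute_force_pcf(pts, (100.0, 100.0, 100.0), 40.0, 16)
            assert np.allclose(res.g, oracle, atol=1e-10)

    def test_csr_tends_to_unity(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 300, (1000, 3))
        res = pair_correlation(pts, (300.0, 300.0, 300.0), 100.0, 25)
        mean_spacing = 300.0 / 10.0  # (V/n)^(1/3)
        far = res.r_bins > 2 * mean_spacing
        assert np.mean(np.abs(res.g[far] - 1.0)) < 0.1

    def test_periodic_equals_translational_for_csr_mean(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 200, (400, 3))
        g_t = pair_correlation(pts, (200.0,) * 3, 60.0, 12).g
        g_p = pair_correlation(pts, (200.0,) * 3, 60.0, 12,
                               edge_correction="periodic").g
        assert np.allclose(g_t.mean(), g_p.mean(), atol=0.15)

    def test_r_max_validity(self):
        pts = np.random.default_rng(0).uniform(0, 100, (20, 3))
        with pytest.raises(ValueError):
            pair_correlation(pts, (100.0,) * 3, 60.0, 10)


class TestCSREnvelope:
    def test_envelope_brackets_unity(self):
        lo, hi = csr_envelope(200, (200.0,) * 3, 60.0, 12, n_sims=39, seed=0)
        good = slice(2, None)  # small-r bins have few pairs
        assert np.all(lo[good] <= 1.0 + 1e-9)
        assert np.all(hi[good] >= 1.0 - 1e-9)

    def test_csr_pattern_inside_envelope(self):
        rng = np.random.default_rng(1)
        lo, hi = csr_envelope(300, (300.0,) * 3, 80.0, 16, n_sims=99, seed=10)
        pts = rng.uniform(0, 300, (300, 3))
        g = pair_correlation(pts, (300.0,) * 3, 80.0, 16).g
        inside = (g >= lo) & (g <= hi)
        assert inside.mean() >= 0.9

    def test_thomas_pattern_exceeds_upper_envelope(self):
        ph = ls.make_bead_phantom(
            200, box_nm=(400.0,) * 3, bead_radius_nm=3, seed=3, voxel_size_nm=4,
            clustering={"kind": "thomas", "parent_rate": 2.5e-7,
                        "cluster_sigma": 20.0, "mean_children": 12.0},
        )
        pts = ph.ground_truth["bead_centers_nm"]
        g = pair_correlation(pts, (400.0,) * 3, 100.0, 20).g
        lo, hi = csr_envelope(len(pts), (400.0,) * 3, 100.0, 20, n_sims=39, seed=5)
        small_r = slice(1, 10)  # distances below the cluster scale
        assert np.any(g[small_r] > hi[small_r])

    def test_minimum_realizations_enforced(self):
        with pytest.raises(ValueError):
            csr_envelope(50, (100.0,) * 3, 30.0, 10, n_sims=10)


class TestPoreSizes:
    def test_solid_volume_has_empty_distribution(self):
        psd = pore_size_distribution(np.zeros((16, 16, 16), bool), 1.0)
        assert psd.total_porosity == 0.0
        assert len(psd.diameter_bins_nm) == 0

    def test_single_spherical_pore_diameter(self):
        mask = _sphere_mask((16, 16, 16), (8, 8, 8), 5)
        psd = pore_size_distribution(mask, 1.0)
        in_band = psd.volume_fraction[
            (psd.diameter_bins_nm >= 9.0) & (psd.diameter_bins_nm <= 11.0)
        ].sum()
        assert in_band >= 0.9
        assert psd.volume_fraction.sum() == pytest.approx(1.0)

    def test_bimodal_populations(self):
        mask = np.zeros((48, 24, 24), bool)
        mask |= _sphere_mask(mask.shape, (10, 12, 12), 3)
        mask |= _sphere_mask(mask.shape, (32, 12, 12), 8)
        psd = pore_size_distribution(mask, 1.0, bin_width_nm=2.0)
        small = psd.volume_fraction[np.abs(psd.diameter_bins_nm - 6) <= 2].sum()
        large = psd.volume_fraction[np.abs(psd.diameter_bins_nm - 16) <= 2].sum()
        assert small > 0.05 and large > 0.5
        mid = psd.volume_fraction[np.abs(psd.diameter_bins_nm - 11) <= 1].sum()
        assert mid < min(small, large)  # genuine bimodality

    def test_local_thickness_monotone_under_dilation(self):
        rng = np.random.default_rng(0)
        mask = ndi.gaussian_filter(rng.normal(size=(24, 24, 24)), 2) > 0.1
        lt = local_thickness(mask)
        dilated = ndi.binary_dilation(mask, iterations=1)
        lt2 = local_thickness(dilated)
        assert np.all(lt2[mask] >= lt[mask] - 1e-9)

    def test_gel_phantom_distribution_spans_ground_truth(self):
        ph = ls.make_gel_phantom(box_nm=(160.0,) * 3, porosity_target=0.1,
                                 pore_radius_range_nm=(5.0, 15.0),
                                 voxel_size_nm=2.0, seed=4)
        mask = vs.gel_pore_mask(ph)
        psd = pore_size_distribution(mask, 2.0)
        assert psd.total_porosity == pytest.approx(ph.ground_truth["porosity"])
        dmin, dmax = psd.diameter_bins_nm.min(), psd.diameter_bins_nm.max()
        assert dmin >= 2.0
        assert dmax <= 2 * 15.0 + 4.0


class TestVolumeChange:
    def test_identical_masks(self):
        m = _sphere_mask((32, 32, 32), (16, 16, 16), 10)
        assert volume_change(m, m).percent == 0.0

    def test_constructed_shrinkage(self):
        m_wet = _sphere_mask((80, 80, 80), (40, 40, 40), 32.0)
        m_dry = _sphere_mask((80, 80, 80), (40, 40, 40), 32.0 * 0.9886)
        vc = volume_change(m_wet, m_dry)
        assert vc.percent == pytest.approx(-3.4, abs=1.0)
        assert vc.linear_percent == pytest.approx(-1.1, abs=0.5)

    def test_counting(self):
        m = np.zeros((10, 10, 10), bool)
        m[:5] = True
        m2 = m.copy()
        m2[5, :5, :] = True  # +50 voxels on 500
        assert volume_change(m, m2).percent == pytest.approx(10.0)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            volume_change(np.zeros((4, 4, 4), bool), np.ones((4, 4, 4), bool))
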