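"""Vessel-isolation cascade: subtraction, vesselness, morphology, smoothing."""

import numpy as np
import pytest
from scipy import ndimage

import mattmap.synthetic as syn
from mattmap.isolation import (FrangiParams, InflowSeries, VesselIsolator,
                               area_open, binarize_and_intersect,
                               frangi_vesselness_slicewise,
                               guided_bilateral_smooth, isolate_vessels,
                               kernel_extent_mm, pairwise_subtract)

TIMES = np.array(syn.DEFAULT_TIMES)


def _frangi_2d_oracle(image, sigma, beta, c):
    """Direct slice vesselness: Gaussian-derivative Hessian (sigma^2
    normalised), closed-form 2x2 eigenvalues, Frangi weighting."""
    gxx = ndimage.gaussian_filter(image, sigma, order=(2, 0)) * sigma**2
    gyy = ndimage.gaussian_filter(image, sigma, order=(0, 2)) * sigma**2
    gxy = ndimage.gaussian_filter(image, sigma, order=(1, 1)) * sigma**2
    tr, det = gxx + gyy, gxx * gyy - gxy**2
    disc = np.sqrt(np.maximum((gxx - gyy) ** 2 + 4 * gxy**2, 0.0)) / 2.0
    e1, e2 = tr / 2.0 - disc, tr / 2.0 + disc
    lam1 = np.where(np.abs(e1) <= np.abs(e2), e1, e2)
    lam2 = np.where(np.abs(e1) <= np.abs(e2), e2, e1)
    s2 = lam1**2 + lam2**2
    with np.errstate(invalid="ignore", divide="ignore"):
        rb2 = np.where(lam2 != 0, (lam1 / lam2) ** 2, 0.0)
    v = np.exp(-rb2 / (2 * beta**2)) * (1 - np.exp(-s2 / (2 * c**2)))
    v[lam2 >= 0] = 0.0
    return v


class TestPairwiseSubtract:
    def test_identical_series_give_zero(self):
        vol = np.random.default_rng(0).normal(size=(8, 8, 8, 8))
        s = pairwise_subtract(vol, vol, times=TIMES)
        assert np.all(s.data == 0)

    def test_constant_offset(self):
        rng = np.random.default_rng(1)
        label = rng.normal(size=(8, 8, 8, 8))
        s = pairwise_subtract(label, label + 5.0, times=TIMES)
        assert np.allclose(s.data, 5.0)

    def test_recovers_simulated_difference(self, small_phantom):
        cfg = small_phantom["config"]
        s = pairwise_subtract(small_phantom["label"],
                              small_phantom["control"], times=cfg.times)
        assert np.allclose(
            s.data, small_phantom["control"] - small_phantom["label"])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            pairwise_subtract(np.zeros((8, 8, 8, 8)),
                              np.zeros((8, 8, 9, 8)), times=TIMES)

    def test_time_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="times"):
            pairwise_subtract(np.zeros((8, 8, 8, 7)),
                              np.zeros((8, 8, 8, 7)), times=TIMES)


class TestFrangi:
    def test_constant_volume_gives_zero(self):
        v = frangi_vesselness_slicewise(np.full((16, 16, 4), 3.0), "XY")
        assert np.all(v == 0)

    def test_bounded_in_unit_interval(self, small_phantom):
        dm = (small_phantom["control"] - small_phantom["label"]).max(axis=3)
        for plane in ("XY", "YZ", "ZX"):
            v = frangi_vesselness_slicewise(dm, plane)
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_ridge_scale_selection(self):
        # gaussian ridge of sd 2 px: with sigma^2-normalised Hessians the
        # response peaks at sigma = sqrt(2)*2 (gamma=2 ridge-scale theory)
        x = np.arange(64)
        ridge = np.exp(-((x[:, None] - 32.0) ** 2) / (2 * 4.0))
        vol = np.repeat(ridge[:, :, None], 64, axis=1).reshape(64, 64, 1)
        scales = (1.0, 2.0, 2.0 * np.sqrt(2.0), 4.0)
        resp = [frangi_vesselness_slicewise(
            vol, "XY", FrangiParams(scales=(s,), c=0.2))[32, 32, 0]
            for s in scales]
        assert int(np.argmax(resp)) == 2
        theory = [s**2 * 2.0 / (4.0 + s**2) ** 1.5 for s in scales]
        assert np.argsort(resp).tolist() == np.argsort(theory).tolist()

    def test_blob_response_below_ridge_response(self):
        x, y = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        ridge = np.exp(-((x - 32.0) ** 2) / (2 * 4.0))[:, :, None]
        blob = np.exp(-((x - 32.0) ** 2 + (y - 32.0) ** 2) / (2 * 4.0))
        blob = blob[:, :, None]
        p = FrangiParams(scales=(2.0,), c=0.2)
        r_ridge = frangi_vesselness_slicewise(ridge, "XY", p)[32, 32, 0]
        r_blob = frangi_vesselness_slicewise(blob, "XY", p)[32, 32, 0]
        assert r_blob < r_ridge

    def test_matches_independent_hessian_oracle(self):
        # the oracle uses a one-pass scipy Hessian (reflect boundary);
        # discretisation and boundary handling differ slightly, so the
        # comparison is on the interior with a tolerance far below any
        # formula-level disagreement
        rng = np.random.default_rng(4)
        img = ndimage.gaussian_filter(rng.normal(size=(48, 48)), 2.0)
        for sigma, c in ((1.5, 0.05), (3.0, 0.02)):
            mine = frangi_vesselness_slicewise(
                img[:, :, None], "XY",
                FrangiParams(scales=(sigma,), c=c))[:, :, 0]
            oracle = np.clip(_frangi_2d_oracle(img, sigma, 0.5, c), 0, 1)
            r = int(np.ceil(4 * sigma)) + 1
            assert np.allclose(mine[r:-r, r:-r], oracle[r:-r, r:-r],
                               atol=5e-3)

    def test_invalid_plane_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            frangi_vesselness_slicewise(np.zeros((8, 8, 2)), "XZ")
        bad = np.zeros((8, 8, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            frangi_vesselness_slicewise(bad, "XY")


class TestBinarizeIntersect:
    def test_and_semantics(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        c = np.zeros((4, 4, 4))
        a[1, 1, 1] = b[1, 1, 1] = 1.0     # above threshold in two fields only
        a[2, 2, 2] = b[2, 2, 2] = c[2, 2, 2] = 1.0
        mask = binarize_and_intersect([a, b, c], 0.5).mask
        assert not mask[1, 1, 1]
        assert mask[2, 2, 2]

    def test_identical_responses_equal_single_binarization(self):
        rng = np.random.default_rng(2)
        r = rng.random((8, 8, 8))
        mask = binarize_and_intersect([r, r, r], 0.3).mask
        assert np.array_equal(mask, r >= 0.3 * r.max())

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_out_of_range_raises(self, threshold):
        r = np.random.default_rng(0).random((4, 4, 4))
        with pytest.raises(ValueError):
            binarize_and_intersect([r, r, r], threshold)

    def test_tube_retention_at_default_threshold(self):
        # soft oblique cylinder: all three planes respond and the
        # intersection keeps at least 90% of the tube voxels
        cfg = syn.SimulationConfig(shape=(48, 48, 48), seed=0,
                                   noise_sigma=0.0, blob_count=0)
        truth = syn.generate_tube_phantom(cfg, n_tubes=1)
        label, control = syn.simulate_inflow_series(truth, cfg)
        tmax = (control - label).max(axis=3)
        resp = [frangi_vesselness_slicewise(tmax, p) for p in
                ("XY", "YZ", "ZX")]
        mask = binarize_and_intersect(resp, 0.05).mask
        assert mask[truth.mask()].mean() >= 0.90


class _FloodFillOracle:
    """Independent component labelling by explicit BFS flood fill."""

    OFFSETS = {
        6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
            (0, 0, -1)],
    }

    @classmethod
    def offsets(cls, connectivity):
        if connectivity in cls.OFFSETS:
            return cls.OFFSETS[connectivity]
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) == (0, 0, 0):
                        continue
                    order = abs(dx) + abs(dy) + abs(dz)
                    if connectivity == 18 and order == 3:
                        continue
                    out.append((dx, dy, dz))
        return out

    @classmethod
    def area_open(cls, mask, min_size, connectivity):
        mask = np.asarray(mask, bool)
        out = np.zeros_like(mask)
        seen = np.zeros_like(mask)
        offs = cls.offsets(connectivity)
        shape = mask.shape
        for start in zip(*np.nonzero(mask)):
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            queue = [start]
            while queue:
                x, y, z = queue.pop()
                for dx, dy, dz in offs:
                    p = (x + dx, y + dy, z + dz)
                    if (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]
                            and 0 <= p[2] < shape[2]
                            and mask[p] and not seen[p]):
                        seen[p] = True
                        comp.append(p)
                        queue.append(p)
            if len(comp) >= min_size:
                for p in comp:
                    out[p] = True
        return out


class TestAreaOpen:
    def test_component_at_size_boundary(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[2, 2, 2:12] = True  # a 10-voxel line
        assert not area_open(mask, 11).any()
        assert np.array_equal(area_open(mask, 10), mask)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        mask = rng.random((32, 32, 32)) < 0.08
        got = area_open(mask, 20, connectivity)
        want = _FloodFillOracle.area_open(mask, 20, connectivity)
        assert np.array_equal(got, want)

    def test_idempotent_and_anti_extensive(self):
        rng = np.random.default_rng(7)
        mask = rng.random((24, 24, 24)) < 0.1
        once = area_open(mask, 15)
        assert np.array_equal(area_open(once, 15), once)
        assert not np.any(once & ~mask)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            area_open(np.zeros((4, 4, 4), bool), 0)
        with pytest.raises(ValueError):
            area_open(np.zeros((4, 4, 4), bool), 5, connectivity=10)


class TestGuidedBilateral:
    def _series(self, data):
        return InflowSeries(data=data, times=TIMES, voxel_dims=(1, 1, 1))

    def test_identity_on_constant_input(self):
        s = self._series(np.full((12, 12, 12, 8), 4.2))
        guide = np.random.default_rng(0).random((12, 12, 12)) > 0.5
        out = guided_bilateral_smooth(s, guide.astype(float))
        assert np.allclose(out.data, 4.2, atol=1e-12)

    def test_uniform_guide_equals_gaussian_smoothing(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(10, 10, 10, 8))
        s = self._series(data)
        out = guided_bilateral_smooth(s, np.ones((10, 10, 10)),
                                      fwhm_voxels=(3, 3, 3),
                                      range_sigma=1e9)
        # oracle: explicit truncated gaussian with border renormalisation
        from mattmap.isolation import FWHM_PER_SIGMA
        sig = 3.0 / FWHM_PER_SIGMA
        r = int(np.ceil(2 * sig))
        k = np.exp(-0.5 * (np.arange(-r, r + 1) / sig) ** 2)
        w3 = k[:, None, None] * k[None, :, None] * k[None, None, :]
        want = np.empty_like(data)
        for t in range(8):
            num = ndimage.correlate(data[..., t], w3, mode="constant")
            den = ndimage.correlate(np.ones_like(data[..., t]), w3,
                                    mode="constant")
            want[..., t] = num / den
        assert np.allclose(out.data, want, atol=1e-10)

    def test_no_mixing_across_mask_boundary(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(12, 12, 12, 8))
        guide = np.zeros((12, 12, 12))
        guide[:, :, 6:] = 1.0
        s = self._series(data)
        out = guided_bilateral_smooth(s, guide, range_sigma=0.01)
        # vessel-side voxels must be convex combinations of vessel-side
        # inputs only (within 1e-6)
        vessel = guide == 1.0
        vmin = data[vessel].min(axis=0).min()
        vmax = data[vessel].max(axis=0).max()
        assert out.data[vessel].min() >= vmin - 1e-6
        assert out.data[vessel].max() <= vmax + 1e-6
        # and equal pure same-class smoothing
        pure = guided_bilateral_smooth(s, guide, range_sigma=1e-12)
        masked = np.where(vessel[..., None], data, 0.0)
        ones = np.where(vessel[..., None], 1.0, 0.0)
        from mattmap.isolation import (FWHM_PER_SIGMA, _sep_blur,
                                       _spatial_kernels)
        radii = [max(1, int(np.ceil(2.0 * f / FWHM_PER_SIGMA)))
                 for f in (5.0, 5.0, 4.0)]
        kern = _spatial_kernels((5.0, 5.0, 4.0), radii)
        num = _sep_blur(masked, kern)
        den = _sep_blur(np.broadcast_to(ones, data.shape).copy(), kern)
        assert np.allclose(pure.data[vessel], (num / den)[vessel], atol=1e-9)

    def test_preserves_value_range(self, small_phantom):
        cfg = small_phantom["config"]
        s = pairwise_subtract(small_phantom["label"],
                              small_phantom["control"], times=cfg.times)
        guide = small_phantom["truth"].mask().astype(float)
        out = guided_bilateral_smooth(s, guide)
        assert out.data.min() >= s.data.min() - 1e-9
        assert out.data.max() <= s.data.max() + 1e-9

    def test_grayscale_guide_path(self):
        rng = np.random.default_rng(8)
        data = rng.normal(size=(8, 8, 8, 8))
        guide = rng.random((8, 8, 8))
        s = self._series(data)
        out = guided_bilateral_smooth(s, guide, fwhm_voxels=(2, 2, 2),
                                      range_sigma=0.3)
        assert out.data.shape == data.shape
        assert np.all(np.isfinite(out.data))


class TestKernelExtent:
    def test_feet_head_extent_of_reference_protocol(self):
        # 4 voxels of 0.8 mm in the feet-head direction span 3.20 mm
        assert kernel_extent_mm((5, 5, 4), (0.6, 0.6, 0.8))[2] == \
            pytest.approx(3.2)

    def test_identity(self):
        assert kernel_extent_mm((1, 1, 1), (1, 1, 1)) == (1.0, 1.0, 1.0)

    def test_elementwise_product(self):
        assert kernel_extent_mm((5, 5, 4), (0.6, 0.6, 0.8)) == \
            pytest.approx((3.0, 3.0, 3.2))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            kernel_extent_mm((0, 5, 4), (0.6, 0.6, 0.8))


class TestIsolateVessels:
    @pytest.fixture(scope="class")
    def tube_run(self):
        cfg = syn.SimulationConfig(seed=0, m_taper=0.0)
        truth = syn.generate_tube_phantom(cfg)
        label, control = syn.simulate_inflow_series(truth, cfg)
        brain = syn.brain_mask_for(cfg)
        mask, series = isolate_vessels(
            label, control, brain_mask=brain, times=cfg.times,
            voxel_dims=cfg.voxel_dims, min_size=250)
        return cfg, truth, brain, mask, series, (label, control)

    def test_blob_artifacts_removed(self, tube_run):
        cfg, truth, brain, mask, _, _ = tube_run
        rng = np.random.default_rng(cfg.seed + 1)
        blobs = syn._blob_artifacts(cfg, rng) > 0
        away_from_vessels = ~ndimage.binary_dilation(truth.mask(),
                                                     iterations=2)
        assert not np.any(mask.mask & blobs & away_from_vessels)

    def test_mask_within_brain(self, tube_run):
        _, _, brain, mask, _, _ = tube_run
        assert not np.any(mask.mask & ~brain)

    def test_retention_and_false_positive_rates(self, tube_run):
        _, truth, brain, mask, _, _ = tube_run
        tm = truth.mask()
        assert mask.mask[tm].mean() >= 0.85
        assert (mask.mask & ~tm).sum() <= 0.02 * brain.sum()

    def test_deterministic(self, tube_run):
        cfg, truth, brain, mask, series, (label, control) = tube_run
        mask2, series2 = isolate_vessels(
            label, control, brain_mask=brain, times=cfg.times,
            voxel_dims=cfg.voxel_dims, min_size=250)
        assert np.array_equal(mask.mask, mask2.mask)
        assert np.array_equal(series.data, series2.data)

    def test_provenance_recorded(self, tube_run):
        _, _, _, mask, _, _ = tube_run
        assert mask.provenance["min_size"] == 250
        assert mask.provenance["threshold"] == 0.05


class TestVesselIsolatorEstimator:
    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone
        est = VesselIsolator(times=tuple(TIMES), min_size=99)
        assert clone(est).get_params()["min_size"] == 99
        est.set_params(threshold=0.1)
        assert est.get_params()["threshold"] == 0.1

    def test_fit_transform_matches_function(self, small_phantom):
        cfg = small_phantom["config"]
        est = VesselIsolator(times=cfg.times, voxel_dims=cfg.voxel_dims,
                             min_size=100)
        series = est.fit_transform(small_phantom["label"],
                                   small_phantom["control"],
                                   brain_mask=small_phantom["brain"])
        mask, series_fn = isolate_vessels(
            small_phantom["label"], small_phantom["control"],
            brain_mask=small_phantom["brain"], times=cfg.times,
            voxel_dims=cfg.voxel_dims, min_size=100)
        assert np.array_equal(est.mask_.mask, mask.mask)
        assert np.array_equal(series.data, series_fn.data)
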