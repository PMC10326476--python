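import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centaur import (
    ROIS,
    TRACERS,
    TracerScale,
    VolumeImage,
    calibrate_scale,
    compute_suvr,
    ctrz_image,
    load_scale_table,
    published_scales,
    suvr_to_ctrz,
)
from conftest import const_volume, make_mask


@pytest.fixture
def target(grid8):
    m = np.zeros(grid8.shape, dtype=bool)
    m[1:4, 1:4, 1:4] = True
    return make_mask(grid8, m)


@pytest.fixture
def reference(grid8):
    m = np.zeros(grid8.shape, dtype=bool)
    m[5:8, 5:8, 5:8] = True
    return make_mask(grid8, m)


class TestComputeSuvr:
    def test_uniform_image_gives_unity(self, grid8, target, reference):
        assert compute_suvr(const_volume(grid8, 1.7), target, reference) == pytest.approx(1.0)

    def test_ratio_of_region_means(self, grid8, target, reference):
        values = np.zeros(grid8.shape)
        values[target.membership] = 2.4
        values[reference.membership] = 1.2
        suvr = compute_suvr(VolumeImage(grid=grid8, values=values), target, reference)
        assert suvr == pytest.approx(2.0)

    def test_unequal_region_sizes(self, grid8):
        values = np.zeros(grid8.shape)
        tgt = make_mask(grid8, [(0, 0, 0), (0, 0, 1), (0, 0, 2)])
        ref = make_mask(grid8, [(1, 0, 0), (1, 0, 1)])
        values[0, 0, :3] = [1.0, 2.0, 3.0]
        values[1, 0, :2] = [2.0, 2.0]
        assert compute_suvr(VolumeImage(grid=grid8, values=values), tgt, ref) == pytest.approx(1.0)

    def test_invariant_under_global_rescaling(self, grid8, target, reference):
        rng = np.random.default_rng(2)
        values = rng.uniform(0.5, 2.0, grid8.shape)
        pet = VolumeImage(grid=grid8, values=values)
        scaled = VolumeImage(grid=grid8, values=3.7 * values)
        assert compute_suvr(scaled, target, reference) == pytest.approx(
            compute_suvr(pet, target, reference), rel=1e-12)

    def test_missing_voxels_excluded(self, grid8, target, reference):
        values = np.ones(grid8.shape)
        values[target.membership] = 2.0
        idx = tuple(np.argwhere(target.membership)[0])
        values[idx] = np.nan
        suvr = compute_suvr(VolumeImage(grid=grid8, values=values), target, reference)
        assert suvr == pytest.approx(2.0)

    def test_nonpositive_reference_mean_rejected(self, grid8, target, reference):
        with pytest.raises(ValueError, match="reference mean"):
            compute_suvr(const_volume(grid8, 0.0), target, reference)

    def test_empty_mask_rejected(self, grid8, reference):
        with pytest.raises(ValueError, match="empty"):
            compute_suvr(const_volume(grid8, 1.0), make_mask(grid8, []), reference)


class TestCalibrateScale:
    def test_hand_computed_example(self):
        scale = calibrate_scale([0.9, 1.0, 1.1], tracer="T", roi="meta_temporal")
        assert scale.slope == pytest.approx(10.0)
        assert scale.intercept == pytest.approx(-10.0)

    def test_standard_normal_cohort_gives_identity_scale(self):
        scale = calibrate_scale([-1.0, 0.0, 1.0], tracer="T", roi="r")
        assert scale.slope == pytest.approx(1.0)
        assert scale.intercept == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            calibrate_scale([1.0, 1.0], tracer="T", roi="r")

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            calibrate_scale([1.0], tracer="T", roi="r")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_mean_to_zero_sd_to_one(self, seed):
        rng = np.random.default_rng(seed)
        suvrs = rng.uniform(0.8, 3.0, size=rng.integers(3, 50))
        scale = calibrate_scale(suvrs, tracer="T", roi="r")
        mu, sigma = np.mean(suvrs), np.std(suvrs, ddof=1)
        assert suvr_to_ctrz(mu, scale) == pytest.approx(0.0, abs=1e-12)
        assert suvr_to_ctrz(mu + sigma, scale) == pytest.approx(1.0, abs=1e-12)


class TestSuvrToCtrz:
    def test_identity_scale(self):
        scale = TracerScale(tracer="T", roi="r", slope=1.0, intercept=0.0)
        assert suvr_to_ctrz(1.7, scale) == pytest.approx(1.7)

    def test_zero_crossing_at_implied_cu_mean(self):
        scale = published_scales(tracer="GTP1", roi="universal")
        assert suvr_to_ctrz(scale.cu_mean, scale) == pytest.approx(0.0, abs=1e-12)

    def test_published_ftp_meta_temporal_value(self):
        scale = published_scales(tracer="FTP", roi="meta_temporal")
        assert suvr_to_ctrz(2.0, scale) == pytest.approx(10.53)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 5.0), b=st.floats(0.1, 5.0))
    def test_affinity(self, a, b):
        scale = published_scales(tracer="MK6240", roi="meta_temporal")
        diff = suvr_to_ctrz(a, scale) - suvr_to_ctrz(b, scale)
        assert diff == pytest.approx(scale.slope * (a - b), rel=1e-9, abs=1e-9)


class TestPublishedScales:
    def test_mk6240_universal_coefficients(self):
        scale = published_scales(tracer="MK6240", roi="universal")
        assert (scale.slope, scale.intercept) == (10.08, -10.06)

    def test_pi2620_universal_coefficients(self):
        scale = published_scales(tracer="PI2620", roi="universal")
        assert (scale.slope, scale.intercept) == (8.45, -9.61)

    def test_unknown_roi_rejected(self):
        with pytest.raises(KeyError, match="hippocampus"):
            published_scales(tracer="FTP", roi="hippocampus")

    def test_unknown_tracer_rejected(self):
        with pytest.raises(KeyError, match="PIB"):
            published_scales(tracer="PIB", roi="universal")

    def test_full_table_has_all_thirty_pairs(self):
        scales = published_scales()
        assert set(scales) == {(t, r) for t in TRACERS for r in ROIS}
        assert all(s.slope > 0 for s in scales.values())

    def test_ols_fit_recovers_every_packaged_coefficient(self):
        grid = np.arange(0.5, 3.01, 0.1)
        for scale in published_scales().values():
            y = suvr_to_ctrz(grid, scale)
            slope, intercept = np.polyfit(grid, y, 1)
            assert slope == pytest.approx(scale.slope, abs=1e-9)
            assert intercept == pytest.approx(scale.intercept, abs=1e-9)

    def test_table_metadata(self):
        table = load_scale_table()
        assert set(table.pipeline) == {"CL-SPM"}
        assert len(table) == 30


class TestCtrzImage:
    def test_uniform_image_identity_scale(self, grid8, reference):
        scale = TracerScale(tracer="T", roi="r", slope=1.0, intercept=0.0)
        out = ctrz_image(const_volume(grid8, 2.5), reference, scale=scale)
        np.testing.assert_allclose(out.values, 1.0)

    def test_roi_mean_matches_scalar_pathway(self, grid8, target, reference):
        rng = np.random.default_rng(4)
        pet = VolumeImage(grid=grid8, values=rng.uniform(0.5, 2.5, grid8.shape))
        scale = published_scales(tracer="RO948", roi="temporo_parietal")
        img = ctrz_image(pet, reference, scale=scale)
        roi_mean = float(np.mean(img.values[target.membership]))
        scalar = suvr_to_ctrz(compute_suvr(pet, target, reference), scale)
        assert roi_mean == pytest.approx(scalar, abs=1e-9)

    def test_voxel_at_reference_mean_maps_to_slope_plus_intercept(self, grid8, reference):
        scale = published_scales(tracer="MK6240", roi="universal")
        out = ctrz_image(const_volume(grid8, 1.3), reference, scale=scale)
        assert out.values[0, 0, 0] == pytest.approx(0.02)

    def test_default_scale_is_tracer_temporo_parietal(self, grid8, reference):
        out = ctrz_image(const_volume(grid8, 1.0), reference, tracer="FTP")
        expected = 13.75 * 1.0 - 15.92
        assert out.values[0, 0, 0] == pytest.approx(expected)
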