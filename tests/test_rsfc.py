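"""ReHo (Kendall's W), guidance maps, seeds and connectivity maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import rankdata

from presurgmap.rsfc import (FISHER_CLIP, GuidanceMap, SeedError, SeedSpec,
                             build_rh_ma_guidance, compute_reho, fc_map,
                             find_local_maxima, kendall_w, seed_glm,
                             seed_timecourse)
from presurgmap.volumes import MaskVolume, StatMap, Volume4D

from conftest import make_affine


def kendall_w_bruteforce(series):
    """Independent oracle: the rank-sum formula applied literally."""
    series = np.asarray(series, float)
    m, n = series.shape
    ranks = np.array([rankdata(s) for s in series])
    R = ranks.sum(axis=0)
    s = ((R - R.mean()) ** 2).sum()
    return 12.0 * s / (m ** 2 * (n ** 3 - n))


class TestKendallW:
    def test_matches_bruteforce_oracle(self):
        series = np.array([[1, 2, 3, 4], [2, 1, 4, 3], [1, 3, 2, 4]], float)
        assert kendall_w(series) == pytest.approx(
            kendall_w_bruteforce(series), abs=1e-12)
        # frozen value from the oracle
        assert kendall_w(series) == pytest.approx(0.6444444444444445,
                                                  abs=1e-12)

    def test_identical_series_are_perfectly_concordant(self):
        series = np.tile([3.0, 1.0, 2.0, 5.0, 4.0], (27, 1))
        assert kendall_w(series) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_and_rank_invariant(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.normal(size=(9, 12))
        w = kendall_w(series)
        assert 0.0 <= w <= 1.0
        # strictly monotone transforms leave ranks (hence W) unchanged
        assert kendall_w(np.exp(series) * 3 + 1) == pytest.approx(w,
                                                                  abs=1e-12)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            kendall_w(np.zeros((3, 2)))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, hnp.array_shapes(min_dims=2, max_dims=2,
                                                   min_side=3, max_side=10),
                      # a coarse value grid keeps the rank structure stable
                      # under the affine map in floating point
                      elements=st.integers(-1000, 1000).map(
                          lambda v: v / 10.0)),
           st.floats(0.1, 5.0), st.floats(-10, 10))
    def test_property_bounds_and_affine_invariance(self, series, a, b):
        """W stays in [0,1], matches the brute-force formula, and is
        unchanged by positive affine rescaling of every series."""
        w = kendall_w(series)
        assert -1e-12 <= w <= 1 + 1e-12
        assert kendall_w(a * series + b) == pytest.approx(w, abs=1e-9)
        assert w == pytest.approx(kendall_w_bruteforce(series), abs=1e-12)


class TestReHoMap:
    def test_voxelwise_w_matches_bruteforce_neighbourhood(self):
        rng = np.random.default_rng(20)
        data = rng.normal(size=(5, 5, 5, 10))
        vol = Volume4D(data, np.eye(4), 2.0)
        reho = compute_reho(vol, 27)
        # interior voxel: full 27-voxel cube
        block = data[1:4, 1:4, 1:4].reshape(27, 10)
        assert reho.data[2, 2, 2] == pytest.approx(
            kendall_w_bruteforce(block), abs=1e-12)
        # corner voxel: only the in-volume 8-voxel corner
        corner = data[:2, :2, :2].reshape(8, 10)
        assert reho.data[0, 0, 0] == pytest.approx(
            kendall_w_bruteforce(corner), abs=1e-12)

    def test_identical_neighbourhood_scores_one(self):
        data = np.tile(np.sin(np.arange(12.0)), (5, 5, 5, 1))
        reho = compute_reho(Volume4D(data, np.eye(4), 2.0), 27)
        assert reho.data == pytest.approx(1.0, abs=1e-10)

    def test_null_mean_matches_monte_carlo(self):
        # independent white-noise neighbourhoods: mean W near its null level
        rng = np.random.default_rng(21)
        n, m = 20, 27
        sims = [kendall_w_bruteforce(rng.normal(size=(m, n)))
                for _ in range(200)]
        null_mean, null_sd = np.mean(sims), np.std(sims)
        data = rng.normal(size=(8, 8, 8, n))
        reho = compute_reho(Volume4D(data, np.eye(4), 2.0), 27)
        interior = reho.data[1:-1, 1:-1, 1:-1]
        assert abs(interior.mean() - null_mean) < 4 * null_sd

    def test_mask_restricts_neighbours(self):
        rng = np.random.default_rng(22)
        data = rng.normal(size=(4, 4, 4, 8))
        mask = np.zeros((4, 4, 4), np.uint8)
        mask[:2] = 1
        reho = compute_reho(Volume4D(data, np.eye(4), 2.0), 27,
                            MaskVolume(mask, np.eye(4)))
        assert np.all(reho.data[2:] == 0)


class TestGuidance:
    def _reho_map(self, shape=(10, 10, 6)):
        rng = np.random.default_rng(23)
        data = rng.uniform(0, 0.3, shape)
        data[6, 6, 3] = 0.9  # hotspot
        return StatMap(data, make_affine(shape, 2.0), "reho")

    def test_whole_brain_mask_leaves_reho_unchanged(self):
        reho = self._reho_map()
        mask = MaskVolume(np.ones(reho.data.shape), reho.affine)
        guide = build_rh_ma_guidance(reho, mask)
        assert np.array_equal(guide.map.data, reho.data)

    def test_disjoint_mask_warns_and_is_empty(self):
        reho = self._reho_map()
        mask = MaskVolume(np.zeros(reho.data.shape), reho.affine)
        with pytest.warns(UserWarning, match="empty"):
            guide = build_rh_ma_guidance(reho, mask, dilate_mm=0.0)
        assert not np.any(guide.map.data)

    def test_hotspot_found_inside_dilated_mask(self):
        reho = self._reho_map()
        mask = np.zeros(reho.data.shape, np.uint8)
        mask[6, 6, 3] = 1
        guide = build_rh_ma_guidance(reho, MaskVolume(mask, reho.affine),
                                     dilate_mm=4.0)
        peaks = find_local_maxima(guide)
        np.testing.assert_allclose(
            peaks[0][0],
            (reho.affine @ [6, 6, 3, 1])[:3])


class TestLocalMaxima:
    def test_single_blob_yields_single_peak(self):
        shape = (16, 16, 8)
        aff = make_affine(shape, 2.0)
        idx = np.indices(shape).astype(float)
        data = np.exp(-(((idx[0] - 8) / 3) ** 2 + ((idx[1] - 8) / 3) ** 2
                        + ((idx[2] - 4) / 2) ** 2))
        guide = GuidanceMap("reho", StatMap(data, aff, "reho"))
        peaks = find_local_maxima(guide, 5.0)
        assert len(peaks) == 1
        np.testing.assert_allclose(peaks[0][0], (aff @ [8, 8, 4, 1])[:3])

    def test_two_blobs_ranked_by_strength(self):
        shape = (30, 16, 8)
        aff = make_affine(shape, 2.0)
        idx = np.indices(shape).astype(float)
        strong = np.exp(-(((idx[0] - 7) / 2) ** 2 + ((idx[1] - 8) / 2) ** 2
                          + ((idx[2] - 4) / 2) ** 2))
        weak = 0.5 * np.exp(-(((idx[0] - 22) / 2) ** 2
                              + ((idx[1] - 8) / 2) ** 2
                              + ((idx[2] - 4) / 2) ** 2))
        guide = GuidanceMap("reho", StatMap(strong + weak, aff, "reho"))
        peaks = find_local_maxima(guide, 10.0)
        assert len(peaks) == 2
        assert peaks[0][1] > peaks[1][1]
        np.testing.assert_allclose(peaks[0][0], (aff @ [7, 8, 4, 1])[:3],
                                   atol=1e-9)

    def test_constant_map_has_no_peaks(self):
        guide = GuidanceMap("reho", StatMap(np.ones((6, 6, 6)), np.eye(4),
                                            "reho"))
        assert find_local_maxima(guide) == []


class TestSeedsAndFC:
    def _vol(self, shape=(10, 10, 6), n_t=40, voxel=2.0, seed=24):
        rng = np.random.default_rng(seed)
        return Volume4D(rng.normal(size=shape + (n_t,)),
                        make_affine(shape, voxel), 2.0)

    def test_zero_radius_returns_exact_voxel_series(self):
        vol = self._vol()
        center = (vol.affine @ [3, 4, 2, 1])[:3]
        ts = seed_timecourse(vol, SeedSpec(center, 0.0))
        assert np.array_equal(ts, vol.data[3, 4, 2])

    def test_two_voxel_sphere_averages(self):
        vol = self._vol()
        a = (vol.affine @ [3, 4, 2, 1])[:3]
        b = (vol.affine @ [4, 4, 2, 1])[:3]
        mid = (a + b) / 2
        ts = seed_timecourse(vol, SeedSpec(mid, 1.01))
        assert np.allclose(ts, (vol.data[3, 4, 2] + vol.data[4, 4, 2]) / 2)

    def test_sphere_count_matches_bruteforce_scan(self):
        vol = self._vol()
        center = (vol.affine @ [5, 5, 3, 1])[:3]
        radius = 5.0  # 10-mm-diameter seed on a 2 mm grid
        from presurgmap.rsfc import _sphere_voxels
        idx = _sphere_voxels(vol.shape[:3], vol.affine,
                             SeedSpec(center, radius))
        world = (vol.affine @ np.vstack(
            [np.indices(vol.shape[:3]).reshape(3, -1),
             np.ones((1, np.prod(vol.shape[:3])))]))[:3].T
        brute = int((np.linalg.norm(world - center, axis=1)
                     <= radius + 1e-9).sum())
        assert len(idx) == brute

    def test_seed_outside_volume_rejected(self):
        vol = self._vol()
        with pytest.raises(SeedError):
            seed_timecourse(vol, SeedSpec(np.array([500.0, 0, 0]), 0.0))

    def test_self_correlation_is_clipped_finite(self):
        vol = self._vol()
        center = (vol.affine @ [3, 4, 2, 1])[:3]
        fc = fc_map(vol, SeedSpec(center, 0.0))
        z_at_seed = fc.z.data[3, 4, 2]
        assert np.isfinite(z_at_seed)
        assert z_at_seed == pytest.approx(np.arctanh(1 - FISHER_CLIP))

    def test_fisher_z_value(self):
        # z(0.5) = atanh(0.5) = 0.5493
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)
        vol = self._vol()
        center = (vol.affine @ [3, 4, 2, 1])[:3]
        fc = fc_map(vol, SeedSpec(center, 0.0))
        assert np.allclose(fc.z.data, np.arctanh(
            np.clip(fc.r.data, -(1 - FISHER_CLIP), 1 - FISHER_CLIP)))

    def test_fisher_z_odd_and_increasing(self):
        r = np.linspace(-0.99, 0.99, 199)
        z = np.arctanh(r)
        assert np.all(np.diff(z) > 0)
        assert np.allclose(z + z[::-1], 0, atol=1e-12)
        assert np.arctanh(0.0) == 0.0

    def test_seed_glm_t_equals_r_identity(self):
        vol = self._vol(n_t=50)
        center = (vol.affine @ [5, 5, 3, 1])[:3]
        seed = SeedSpec(center, 3.0)
        fc = fc_map(vol, seed)
        res = seed_glm(vol, seed)
        r = fc.r.data.reshape(-1)
        t_expected = r * np.sqrt(res.df / np.maximum(1 - r ** 2, 1e-12))
        assert np.allclose(res.tstat, t_expected, atol=1e-6)

    def test_constant_seed_rejected(self):
        vol = self._vol()
        vol.data[3, 4, 2, :] = 7.0
        center = (vol.affine @ [3, 4, 2, 1])[:3]
        with pytest.raises(ValueError, match="degenerate"):
            seed_glm(vol, SeedSpec(center, 0.0))

    def test_network_phantom_separates_within_from_between(self,
                                                           session_default):
        s = session_default
        fc = fc_map(s.rest, SeedSpec(np.array([-20.0, 20.0, 6.0]), 6.0),
                    s.truth.brain_mask)
        within = np.median(fc.z.data[s.truth.network_masks[0].data > 0])
        between = np.median(fc.z.data[s.truth.network_masks[1].data > 0])
        assert within - between >= 0.5
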