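"""Temporal/spatial preprocessing: outlier rule, slice timing, registration,
single-shot resampling, despiking, joint nuisance projection, smoothing."""

import numpy as np
import pytest
from scipy.stats import norm

from presurgmap.preprocess import (align_cbr, align_ibr, count_outliers,
                                   despike, motion_correct,
                                   outlier_threshold_factor,
                                   project_nuisance, resample_once,
                                   resample_to_iso, resample_volume,
                                   select_reference_volume,
                                   slice_timing_correct, smooth_gaussian)
from presurgmap.volumes import (GeometryError, RigidTransform, Volume3D,
                                Volume4D)

from conftest import asymmetric_blob, make_affine


class TestOutlierRule:
    def test_matches_five_point_five_mad_at_180(self):
        # the default deviation limit is ~5.5 x MAD for 50-500 timepoints
        assert round(outlier_threshold_factor(180), 1) == 5.5

    def test_direct_formula_at_50(self):
        expected = norm.ppf(1 - 0.001 / 50) * np.sqrt(np.pi / 2)
        assert outlier_threshold_factor(50) == pytest.approx(expected)
        assert round(outlier_threshold_factor(50), 2) == 5.15

    def test_monotone_in_length(self):
        ks = [outlier_threshold_factor(n) for n in (50, 180, 500)]
        assert ks[0] < ks[1] < ks[2]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            outlier_threshold_factor(1)

    def test_spike_on_ramp_counted(self):
        rng = np.random.default_rng(3)
        ts = np.linspace(0, 10, 100) + rng.normal(0, 1, 100)
        kappa = outlier_threshold_factor(ts.size)
        base = count_outliers(ts, kappa)
        ts_spiked = ts.copy()
        ts_spiked[50] += 40.0
        assert count_outliers(ts_spiked, kappa) == base + 1

    def test_constant_series_has_no_outliers(self):
        assert count_outliers(np.full(60, 7.0), 5.5) == 0

    def test_infinite_kappa_has_no_outliers(self):
        rng = np.random.default_rng(4)
        assert count_outliers(rng.normal(size=80), np.inf) == 0


class TestReferenceSelection:
    def _spiky_volume(self):
        rng = np.random.default_rng(5)
        shape = (6, 6, 4)
        n_t = 8
        data = rng.normal(0, 1, shape + (n_t,)) + 100.0
        for t in range(n_t):
            if t == 2:
                continue  # the clean volume
            vox = rng.integers(0, 6, size=(30, 2))
            for x, y in vox:
                data[x, y, rng.integers(4), t] += 50.0
        return Volume4D(data, np.eye(4), 2.0)

    def test_cleanest_volume_wins(self):
        vol = self._spiky_volume()
        profile = select_reference_volume(vol)
        assert profile.reference_index == 2
        # the index attains the brute-force minimum
        assert profile.counts[2] == profile.counts.min()

    def test_counts_match_bruteforce_scan(self):
        vol = self._spiky_volume()
        profile = select_reference_volume(vol)
        flat = vol.data.reshape(-1, vol.n_volumes)
        brute = np.zeros(vol.n_volumes, int)
        for series in flat:
            kappa = profile.kappa
            # brute force: same robust rule, one series at a time
            per = np.zeros(vol.n_volumes, bool)
            n_out = count_outliers(series, kappa)
            if n_out:
                from presurgmap.preprocess import _outlier_mask
                per = _outlier_mask(series[None], kappa)[0]
            brute += per
        assert np.array_equal(profile.counts, brute)

    def test_tie_breaks_to_first(self):
        data = np.ones((4, 4, 2, 5)) * 50.0
        profile = select_reference_volume(Volume4D(data, np.eye(4), 2.0))
        assert profile.reference_index == 0

    def test_single_volume(self):
        data = np.ones((4, 4, 2, 1))
        assert select_reference_volume(
            Volume4D(data, np.eye(4), 2.0)).reference_index == 0


class TestSliceTiming:
    def _vol(self, slice_times, n_t=60, tr=2.0):
        z = len(slice_times)
        t = np.arange(n_t) * tr
        data = np.empty((4, 4, z, n_t))
        for zi, st in enumerate(slice_times):
            data[:, :, zi, :] = np.sin(2 * np.pi * 0.05 * (t + st))
        return Volume4D(data, np.eye(4), tr, np.asarray(slice_times))

    def test_zero_offsets_identity(self):
        vol = self._vol([0.0, 0.0, 0.0])
        out = slice_timing_correct(vol)
        assert np.allclose(out.data, vol.data, atol=1e-10)

    def test_phase_dispersion_reduced(self):
        slice_times = [0.0, 0.5, 1.0, 1.5]
        vol = self._vol(slice_times)
        out = slice_timing_correct(vol)

        def phases(v):
            # analytic phase of the fitted 0.05 Hz sinusoid per slice
            t = np.arange(v.n_volumes) * v.tr
            basis = np.stack([np.sin(2 * np.pi * 0.05 * t),
                              np.cos(2 * np.pi * 0.05 * t)], axis=1)
            ph = []
            for z in range(v.shape[2]):
                coef, *_ = np.linalg.lstsq(basis, v.data[0, 0, z], rcond=None)
                ph.append(np.arctan2(coef[1], coef[0]))
            return np.unwrap(np.asarray(ph))

        spread_in = np.ptp(phases(vol))
        spread_out = np.ptp(phases(out))
        assert spread_out < spread_in / 10

    def test_mismatched_slice_times_rejected(self):
        with pytest.raises(ValueError):
            Volume4D(np.zeros((4, 4, 3, 10)), np.eye(4), 2.0,
                     slice_times=[0.0, 0.5])


class TestMotionCorrection:
    def test_injected_rigid_motion_recovered(self, blob):
        injected = RigidTransform([0, 0, np.deg2rad(2.0), 2.0, -1.0, 0.5])
        moving = resample_volume(blob, injected, blob.affine, blob.shape,
                                 method="wsinc")
        vol = Volume4D(np.stack([blob.data, moving.data], -1),
                       blob.affine, 2.0)
        _, tfs = motion_correct(vol, 0)
        expected = injected.inverse().params
        err = np.abs(tfs[1].params - expected)
        assert err[3:].max() < 0.3          # mm
        assert np.rad2deg(err[:3]).max() < 0.3  # degrees

    def test_motion_free_data_gives_identity(self, blob):
        vol = Volume4D(np.stack([blob.data] * 3, -1), blob.affine, 2.0)
        _, tfs = motion_correct(vol, 0)
        for tf in tfs:
            assert np.abs(tf.params).max() < 1e-3

    def test_reference_index_out_of_range(self, blob):
        vol = Volume4D(blob.data[..., None], blob.affine, 2.0)
        with pytest.raises(ValueError):
            motion_correct(vol, 1)


class TestAlignment:
    def test_cbr_same_grid_is_identity(self, blob):
        vol = Volume4D(blob.data[..., None], blob.affine, 2.0)
        t1 = resample_to_iso(blob, 3)
        out = align_cbr(vol, t1, 3)
        # interior voxels match the source within interpolation tolerance
        inner = out.data[4:-4, 4:-4, 3:-3, 0]
        src = resample_volume(blob, RigidTransform.identity(),
                              t1.affine, t1.shape).data[4:-4, 4:-4, 3:-3]
        assert np.allclose(inner, src, atol=1e-8)

    def test_cbr_output_grid_is_isotropic_target(self):
        # 3.75 mm in-plane acquisition resampled onto a 2-mm grid
        shape = (16, 16, 8)
        aff = np.diag([3.75, 3.75, 4.0, 1.0])
        vol = Volume4D(np.random.default_rng(0).normal(
            size=shape + (2,)), aff, 2.0)
        t1 = resample_to_iso(Volume3D(np.zeros((30, 30, 16)),
                                      np.diag([2.0, 2.0, 2.0, 1.0])), 2)
        out = align_cbr(vol, t1, 2)
        assert np.allclose(out.voxel_sizes, 2.0)

    def test_cbr_rejects_wrong_t1_grid(self, blob):
        vol = Volume4D(blob.data[..., None], blob.affine, 2.0)
        with pytest.raises(GeometryError):
            align_cbr(vol, blob, 2)  # blob grid is 3 mm, not 2 mm

    def test_ibr_self_registration_is_identity(self, blob):
        tf = align_ibr(blob, blob)
        assert np.abs(tf.params[3:]).max() < 0.1
        assert np.rad2deg(np.abs(tf.params[:3])).max() < 0.1

    def test_ibr_recovers_known_shift(self, blob):
        injected = RigidTransform([0, 0, 0, 4.0, 0, 0])
        moving = resample_volume(blob, injected, blob.affine, blob.shape,
                                 method="trilinear")
        tf = align_ibr(moving, blob)
        assert np.abs(tf.params[3:] - injected.inverse().params[3:]).max() \
            < 0.5

    def test_ibr_constant_image_rejected(self, blob):
        flat = Volume3D(np.ones(blob.shape), blob.affine)
        with pytest.raises(ValueError):
            align_ibr(flat, blob)


class TestResampleOnce:
    def test_identity_composite_returns_input(self, blob):
        vol = Volume4D(blob.data[..., None], blob.affine, 2.0)
        ident = RigidTransform.identity()
        out = resample_once(vol, [ident], ident, blob.affine, blob.shape)
        assert np.allclose(out.data[..., 0], blob.data, atol=1e-8)

    def test_composition_beats_sequential_interpolation(self, blob):
        plus = RigidTransform([0, 0, 0, 2.0, 0, 0])
        minus = RigidTransform([0, 0, 0, -2.0, 0, 0])
        once = resample_volume(blob, plus.compose(minus), blob.affine,
                               blob.shape)
        twice = resample_volume(
            resample_volume(blob, plus, blob.affine, blob.shape),
            minus, blob.affine, blob.shape)
        rms_once = np.sqrt(((once.data - blob.data) ** 2).mean())
        rms_twice = np.sqrt(((twice.data - blob.data) ** 2).mean())
        assert rms_once < rms_twice

    def test_known_shift_matches_analytic_phantom(self):
        # smooth Gaussian phantom shifted by a known amount
        shape = (24, 24, 12)
        aff = make_affine(shape, 3.0)
        idx = np.indices(shape).astype(float)
        c = (np.array(shape) - 1) / 2

        def gauss(dx_vox):
            return 100 * np.exp(-(((idx[0] - c[0] - dx_vox) / 4) ** 2
                                  + ((idx[1] - c[1]) / 4) ** 2
                                  + ((idx[2] - c[2]) / 2.5) ** 2))

        vol = Volume3D(gauss(0.0), aff)
        shift = RigidTransform([0, 0, 0, -3.0, 0, 0])  # pull-back: +1 voxel
        out = resample_volume(vol, shift, aff, shape)
        expected = gauss(1.0)
        inner = (slice(5, -5), slice(5, -5), slice(3, -3))
        assert np.abs(out.data[inner] - expected[inner]).max() \
            < 0.01 * expected.max()


class TestDespike:
    def test_single_spike_compressed_others_untouched(self):
        rng = np.random.default_rng(6)
        sigma = 0.5
        smooth = 2.0 * np.sin(np.linspace(0, 3, 120))
        ts = smooth + rng.normal(0, sigma, 120)
        spiked = ts.copy()
        spiked[60] = smooth[60] + 8 * sigma  # exactly 8 sigma off the trend
        out = despike(spiked)
        assert abs(out[60] - smooth[60]) < 4.3 * sigma  # compressed below c2
        # the saturating rule only touches residuals beyond 2.5 sigma:
        # everything that stays under the threshold is bit-unchanged, and
        # near-threshold samples move by at most a sliver
        delta = np.delete(np.abs(out - spiked), 60)
        assert np.median(delta) == 0.0
        assert (delta > 0).mean() < 0.05
        assert delta.max() < 0.5 * sigma

    def test_spike_free_series_unchanged(self):
        ts = np.sin(np.linspace(0, 4, 80)) * 3
        assert np.abs(despike(ts) - ts).max() < 1e-6

    def test_constant_series_passthrough(self):
        ts = np.full(30, 5.0)
        assert np.array_equal(despike(ts), ts)

    def test_matrix_input_matches_per_row(self):
        rng = np.random.default_rng(7)
        rows = rng.normal(size=(5, 60)) + np.linspace(0, 2, 60)
        rows[2, 30] += 10
        batch = despike(rows)
        # batched and single-series calls agree far below the noise scale
        # (the L1 trend fit is numerically sensitive at machine precision)
        for i in range(5):
            assert np.allclose(batch[i], despike(rows[i]), atol=1e-3)


class TestNuisanceProjection:
    def test_exact_regressor_removed(self):
        rng = np.random.default_rng(8)
        reg = rng.normal(size=(100, 1))
        resid = project_nuisance(reg.T.copy(), reg, None, 0)
        assert np.linalg.norm(resid) < 1e-8

    @pytest.mark.parametrize("freq,lo,hi", [(0.05, 0.95, 1.0),
                                            (0.2, 0.0, 0.01)])
    def test_band_retention(self, freq, lo, hi):
        n, tr = 180, 2.0
        t = np.arange(n) * tr
        sig = np.sin(2 * np.pi * freq * t)[None, :]
        resid = project_nuisance(sig, None, (0.01, 0.08), 2, tr)
        retained = (resid ** 2).sum() / (sig ** 2).sum()
        assert lo <= retained <= hi

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(20, 120))
        regs = rng.normal(size=(120, 4))
        once = project_nuisance(y, regs, (0.01, 0.08), 2, tr=2.0)
        twice = project_nuisance(once, regs, (0.01, 0.08), 2, tr=2.0)
        assert np.abs(twice - once).max() < 1e-8

    def test_duplicated_regressors_warn_not_crash(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(3, 50))
        reg = rng.normal(size=(50, 1))
        dup = np.concatenate([reg, reg], axis=1)
        with pytest.warns(UserWarning, match="rank-deficient"):
            r1 = project_nuisance(y, dup, None, 1)
        r2 = project_nuisance(y, reg, None, 1)
        assert np.allclose(r1, r2, atol=1e-10)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, blob):
        assert smooth_gaussian(blob, 0.0) is blob

    def test_half_fwhm_amplitude_ratio(self):
        # impulse smoothed with 4 mm FWHM on a 2 mm grid: the value one
        # half-FWHM (2 mm) from the peak is half the peak by definition
        shape = (21, 21, 21)
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        data = np.zeros(shape)
        data[10, 10, 10] = 1.0
        out = smooth_gaussian(Volume3D(data, aff), 4.0)
        ratio = out.data[11, 10, 10] / out.data[10, 10, 10]
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_constant_volume_unchanged(self):
        vol = Volume3D(np.full((8, 8, 8), 3.0), np.eye(4))
        out = smooth_gaussian(vol, 4.0)
        assert np.allclose(out.data, 3.0, atol=1e-10)

    def test_negative_fwhm_rejected(self, blob):
        with pytest.raises(ValueError):
            smooth_gaussian(blob, -1.0)
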