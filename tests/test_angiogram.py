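"""GPF correction, complex-difference angiograms, smoothing, MIP, quality filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokeangio.angiogram import (
    AngiogramSeries,
    AngiogramVolume,
    BFramePair,
    average_series,
    compute_angiogram,
    compute_angiogram_channels,
    correct_gpf,
    estimate_bulk_phase,
    mip_enface,
    quality_filter,
    smooth_volume,
)


def _speckle_frame(seed, shape=(32, 40)):
    rng = np.random.default_rng(seed)
    return np.exp(1j * rng.uniform(0, 2 * np.pi, shape)) * rng.uniform(0.5, 1.5, shape)


class TestCorrectGpf:
    def test_pure_phase_offset_inverted_exactly(self):
        a = _speckle_frame(0)
        pair = correct_gpf(BFramePair(a, a * np.exp(1j * 0.7)))
        assert np.allclose(pair.frame_b, a)

    def test_identical_frames_unchanged(self):
        a = _speckle_frame(1)
        pair = correct_gpf(BFramePair(a, a.copy()))
        assert np.allclose(pair.frame_b, a)

    def test_frame_a_never_modified(self):
        a = _speckle_frame(2)
        pair = correct_gpf(BFramePair(a, a * np.exp(1j * 1.1)))
        assert np.array_equal(pair.frame_a, a)

    def test_zero_pair_rejected(self):
        z = np.zeros((4, 4), complex)
        with pytest.raises(ValueError):
            correct_gpf(BFramePair(z, z))

    def test_zero_energy_aline_gets_zero_phase(self):
        a = _speckle_frame(3)
        a[:, 5] = 0
        b = a * np.exp(1j * 0.3)
        pair = correct_gpf(BFramePair(a, b))
        assert np.allclose(pair.frame_b[:, 5], 0)

    @given(st.floats(-np.pi + 1e-3, np.pi - 1e-3))
    @settings(max_examples=25, deadline=None)
    def test_gpf_invariance_property(self, phase):
        """Any global unit-modulus factor on frame_b leaves the angiogram
        unchanged after correction (machine tolerance)."""
        a = _speckle_frame(4)
        b = _speckle_frame(5)  # fully decorrelated, worst case
        ref = compute_angiogram(correct_gpf(BFramePair(a, b)))
        out = compute_angiogram(correct_gpf(BFramePair(a, b * np.exp(1j * phase))))
        assert np.linalg.norm(out - ref) <= 1e-6 * max(np.linalg.norm(ref), 1e-30)

    def test_bulk_phase_recovery_with_dynamic_minority(self):
        """5% dynamic pixels: recovered phase within 0.05 rad over seeds."""
        from strokeangio.synthgen import SceneSpec, generate_scene, render_bframe_pair

        spec = SceneSpec.small(seed=42, n_segments=12, noise_sigma=0.02)
        scene, _ = generate_scene(spec)
        errs = []
        for s in range(100):
            pair = render_bframe_pair(scene, s % spec.grid_ny, bulk_phase=1.2,
                                      spec=spec, seed=s)
            errs.append(abs(estimate_bulk_phase(pair) - 1.2))
        assert max(errs) < 0.05


class TestComputeAngiogram:
    def test_static_tissue_zero(self):
        a = _speckle_frame(6)
        assert np.allclose(compute_angiogram(BFramePair(a, a.copy())), 0)

    def test_antipodal_phasors_give_two(self):
        a = np.ones((3, 3), complex)
        b = np.ones((3, 3), complex)
        b[1, 1] = np.exp(1j * np.pi)
        out = compute_angiogram(BFramePair(a, b))
        assert out[1, 1] == pytest.approx(2.0)
        assert out[0, 0] == pytest.approx(0.0)

    def test_non_negative(self):
        out = compute_angiogram(BFramePair(_speckle_frame(7), _speckle_frame(8)))
        assert (out >= 0).all()

    def test_diagnostic_channels_shapes(self):
        a, b = _speckle_frame(9), _speckle_frame(10)
        dphi, dint = compute_angiogram_channels(BFramePair(a, b))
        assert dphi.shape == a.shape and dint.shape == a.shape
        assert (dphi >= 0).all() and (dint >= 0).all()


class TestSmoothVolume:
    def test_constant_volume_interior_unchanged(self):
        vol = AngiogramVolume(np.full((16, 16, 16), 3.0))
        out = smooth_volume(vol)
        assert np.allclose(out.data[4:-4, 4:-4, 4:-4], 3.0)

    def test_impulse_response_matches_gaussian_kernel(self):
        from scipy import ndimage

        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        out = smooth_volume(AngiogramVolume(vol)).data
        expected = ndimage.gaussian_filter(vol, 1.0)
        assert np.allclose(out, expected)

    def test_total_intensity_preserved_for_interior_blob(self):
        vol = np.zeros((24, 24, 24))
        vol[10:14, 10:14, 10:14] = 1.0
        out = smooth_volume(AngiogramVolume(vol)).data
        assert abs(out.sum() - vol.sum()) / vol.sum() < 0.01

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.random((10, 10, 10))
        b = rng.random((10, 10, 10))
        sa = smooth_volume(AngiogramVolume(a)).data
        sb = smooth_volume(AngiogramVolume(b)).data
        sab = smooth_volume(AngiogramVolume(a + b)).data
        assert np.allclose(sab, sa + sb, atol=1e-10)


class TestAverageSeries:
    def test_copies_average_to_original(self):
        f = np.random.default_rng(1).random((8, 8))
        series = AngiogramSeries([f.copy() for _ in range(60)])
        assert np.allclose(average_series(series), f)

    def test_noise_reduction_sqrt_n(self):
        rng = np.random.default_rng(2)
        sds = []
        for _ in range(20):
            frames = [rng.normal(1.0, 0.5, (16, 16)).clip(0) for _ in range(60)]
            sds.append(average_series(AngiogramSeries(frames)).std())
        # sd of the mean of 60 iid frames ~ sigma / sqrt(60)
        assert np.mean(sds) == pytest.approx(0.5 / np.sqrt(60), rel=0.25)

    def test_only_kept_frames_averaged(self):
        lo = np.zeros((4, 4))
        hi = np.ones((4, 4))
        series = AngiogramSeries([lo, hi, lo, hi],
                                 quality_flags=[False, True, False, True])
        assert np.allclose(average_series(series), 1.0)

    def test_no_kept_frames_raises(self):
        series = AngiogramSeries([np.ones((2, 2))], quality_flags=[False])
        with pytest.raises(ValueError):
            average_series(series)


class TestMipEnface:
    def _vol(self):
        data = np.zeros((64, 8, 8))
        return data

    def test_bright_voxel_in_band_projected(self):
        data = self._vol()
        data[30, 3, 4] = 5.0
        out = mip_enface(AngiogramVolume(data), center_z=32)
        assert out.image[3, 4] == 5.0

    def test_bright_voxel_outside_band_absent(self):
        data = self._vol()
        data[5, 3, 4] = 5.0
        out = mip_enface(AngiogramVolume(data), center_z=32)
        assert out.image[3, 4] == 0.0

    def test_band_is_31_pixels(self):
        out = mip_enface(AngiogramVolume(self._vol()), center_z=32)
        z_lo, z_hi = out.depth_band_px
        assert z_hi - z_lo == 31

    def test_mip_bounds_mean_projection(self):
        rng = np.random.default_rng(3)
        data = rng.random((64, 6, 6))
        vol = AngiogramVolume(data)
        out = mip_enface(vol, center_z=32)
        mean_proj = data[17:48].mean(axis=0)
        assert np.all(out.image >= mean_proj)

    def test_band_outside_volume_raises(self):
        with pytest.raises(ValueError):
            mip_enface(AngiogramVolume(self._vol()), center_z=5)


class TestQualityFilter:
    def _series(self, n=100, seed=4):
        rng = np.random.default_rng(seed)
        return [rng.normal(1.0, 0.01, (16, 16)).clip(0) for _ in range(n)]

    def test_first_60_of_clean_100_kept(self):
        out = quality_filter(AngiogramSeries(self._series()))
        assert out.quality_flags.sum() == 60
        assert out.quality_flags[:60].all()

    def test_corrupted_frames_discarded(self):
        frames = self._series()
        for i in (10, 30, 50):
            frames[i] = frames[i] * 10
        out = quality_filter(AngiogramSeries(frames))
        assert not out.quality_flags[[10, 30, 50]].any()
        assert out.quality_flags.sum() == 60

    def test_identical_frames_all_pass(self):
        frames = [np.ones((8, 8)) for _ in range(30)]
        with pytest.warns(UserWarning):
            out = quality_filter(AngiogramSeries(frames))
        assert out.quality_flags.all()

    def test_keep_list_override(self):
        out = quality_filter(AngiogramSeries(self._series(10)), keep_list=[0, 5])
        assert list(np.flatnonzero(out.quality_flags)) == [0, 5]
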