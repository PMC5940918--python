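"""Unit tests for the time-invariant-constraint reconstruction core."""

import numpy as np
import pytest

from insitucdi import forward, insitu
from insitucdi.optics import ComplexField


class TestWeightedStaticUpdate:
    def test_hand_example(self):
        s_prev = np.full((2, 2), 1.0 + 0j)
        s_this = np.full((2, 2), 2.0 + 0j)
        out = insitu.weighted_static_update(s_prev, s_this, 0.8)
        np.testing.assert_allclose(out, 1.2)

    def test_endpoints(self):
        a, b = np.ones((2, 2)), np.full((2, 2), 5.0)
        np.testing.assert_allclose(insitu.weighted_static_update(a, b, 1.0), a)
        np.testing.assert_allclose(insitu.weighted_static_update(a, b, 0.0), b)

    def test_rejects_bad_gamma(self):
        with pytest.raises(ValueError):
            insitu.weighted_static_update(np.ones((2, 2)), np.ones((2, 2)), 1.5)


class TestFourierMagnitudeProjection:
    def test_magnitudes_replaced_on_valid_pixels(self):
        rng = np.random.default_rng(0)
        n = 32
        wave = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        measured = np.abs(rng.normal(size=(n, n))) + 0.1
        valid = np.ones((n, n), bool)
        out = insitu.fourier_magnitude_projection(wave, measured, valid)
        mags = np.abs(forward.fft_centered(out))
        np.testing.assert_allclose(mags, measured, rtol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        n = 32
        wave = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        measured = np.abs(rng.normal(size=(n, n))) + 0.1
        valid = rng.uniform(size=(n, n)) > 0.1
        once = insitu.fourier_magnitude_projection(wave, measured, valid)
        twice = insitu.fourier_magnitude_projection(once, measured, valid)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_invalid_pixels_pass_through(self):
        rng = np.random.default_rng(2)
        n = 16
        wave = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        measured = np.full((n, n), 3.0)
        valid = np.zeros((n, n), bool)  # nothing measured
        out = insitu.fourier_magnitude_projection(wave, measured, valid)
        np.testing.assert_allclose(out, wave, atol=1e-12)


class TestObjectUpdate:
    def test_unit_probe_full_step(self):
        # With |P| = 1 everywhere, alpha = 1 and the update is
        # O' = O + (psi' - psi)/(1 + eps): a full replacement step.
        n = 8
        obj = np.full((n, n), 2.0 + 1j)
        probe = np.ones((n, n), dtype=complex)
        psi = obj * probe
        psi_new = psi + (0.5 - 0.25j)
        out = insitu.object_update(obj, psi, psi_new, probe, epsilon=0.0)
        np.testing.assert_allclose(out, obj + (0.5 - 0.25j), rtol=1e-12)

    def test_zero_probe_rejected(self):
        z = np.zeros((4, 4), complex)
        with pytest.raises(ValueError):
            insitu.object_update(z, z, z, z, epsilon=0.0)

    def test_regulariser_suppresses_dark_pixels(self):
        # Where |P|^2 << epsilon the update weight |P|^2/(|P|^2 + eps)
        # vanishes, so unilluminated pixels barely move.
        n = 4
        probe = np.ones((n, n), dtype=complex)
        probe[0, 0] = 1e-4
        obj = np.zeros((n, n), complex)
        psi = obj * probe
        psi_new = psi + 1.0
        out = insitu.object_update(obj, psi, psi_new, probe, epsilon=1e-2)
        assert abs(out[0, 0]) < abs(out[1, 1]) * 1e-3


class TestSplitObject:
    def test_partition(self):
        n = 8
        st = np.zeros((n, n), bool)
        dy = np.zeros((n, n), bool)
        st[:, :3] = True
        dy[:, 5:] = True
        masks = insitu.RegionMasks(st, dy)
        obj = np.arange(n * n, dtype=complex).reshape(n, n)
        s, d = insitu.split_object(obj, masks)
        np.testing.assert_array_equal(s + d, obj * masks.union)
        assert np.all(s[~st] == 0) and np.all(d[~dy] == 0)

    def test_overlapping_masks_rejected(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            insitu.RegionMasks(m, m)


class TestRFactor:
    def test_hand_example(self):
        # |2-1| + |1-3| = 3 over sum(measured) = 2 + 1 = 3 -> R = 1.0
        m = [np.array([[2.0, 1.0]])]
        c = [np.array([[1.0, 3.0]])]
        v = [np.ones((1, 2), bool)]
        assert insitu.r_factor(m, c, v) == pytest.approx(1.0)

    def test_perfect_match_is_zero(self):
        m = [np.random.default_rng(0).uniform(1, 2, (8, 8))]
        assert insitu.r_factor(m, m, [np.ones((8, 8), bool)]) == 0.0

    def test_invalid_pixels_excluded(self):
        m = [np.array([[2.0, 100.0]])]
        c = [np.array([[1.0, 0.0]])]
        v = [np.array([[True, False]])]
        assert insitu.r_factor(m, c, v) == pytest.approx(0.5)

    def test_multi_frame_pooling(self):
        m = [np.array([[2.0]]), np.array([[2.0]])]
        c = [np.array([[1.0]]), np.array([[3.0]])]
        v = [np.ones((1, 1), bool)] * 2
        assert insitu.r_factor(m, c, v) == pytest.approx(0.5)


class TestMasksFromPinholes:
    def test_disjoint_and_sized(self):
        masks = insitu.masks_from_pinholes(
            256, 20e-9, 1.0e-6, 1.6e-6, dilation_px=2, hole_diameter2=1.2e-6
        )
        assert not np.any(masks.static_support & masks.dynamic_support)
        # dynamic disc is larger
        assert masks.dynamic_support.sum() > masks.static_support.sum()

    def test_dilation_grows_support(self):
        tight = insitu.masks_from_pinholes(256, 20e-9, 1.0e-6, 1.6e-6, 0)
        wide = insitu.masks_from_pinholes(256, 20e-9, 1.0e-6, 1.6e-6, 3)
        assert wide.static_support.sum() > tight.static_support.sum()
        assert np.all(wide.static_support[tight.static_support])


class TestAlgorithmParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            insitu.AlgorithmParams(gamma=1.5)
        with pytest.raises(ValueError):
            insitu.AlgorithmParams(n_iterations=0)
        with pytest.raises(ValueError):
            insitu.AlgorithmParams(indexing="bogus")

    def test_smoothing_schedule(self):
        prm = insitu.AlgorithmParams(
            n_iterations=100, smooth_sigma0=4.0, smooth_frac=0.4, smooth_cycles=2
        )
        assert prm.smoothing_sigma(0) == pytest.approx(4.0)
        # second cycle restarts at half the width
        assert prm.smoothing_sigma(20) == pytest.approx(2.0)
        # after the annealed stretch the smoothing is off
        assert prm.smoothing_sigma(40) == 0.0
        assert prm.smoothing_sigma(99) == 0.0

    def test_smoothing_disabled(self):
        prm = insitu.AlgorithmParams(n_iterations=100, smooth_sigma0=0.0)
        assert all(prm.smoothing_sigma(j) == 0.0 for j in range(100))


def tiny_series(seed=0, n=64, n_frames=3, noise=False):
    """A small noiseless two-region scene for solver smoke tests."""
    rng = np.random.default_rng(seed)
    px = 20e-9
    masks = insitu.masks_from_pinholes(
        n, px, 0.24e-6, 0.4e-6, dilation_px=1, hole_diameter2=0.3e-6
    )
    probe = ComplexField(
        (masks.static_support | masks.dynamic_support).astype(complex), px
    )
    static = masks.static_support * (
        rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    )
    frames, truths = [], []
    for t in range(n_frames):
        dyn = masks.dynamic_support * (
            rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        )
        obj = static + dyn
        truths.append(obj)
        pattern = np.abs(forward.fft_centered(obj * probe.values)) ** 2
        if noise:
            frame = forward.add_poisson(pattern, seed=seed + t)
        else:
            frame = forward.DiffractionFrame(pattern, None)
        frames.append(frame)
    return frames, probe, masks, truths


class TestInSituCDI:
    def test_needs_two_frames(self):
        frames, probe, masks, _ = tiny_series()
        with pytest.raises(ValueError):
            insitu.InSituCDI(frames[:1], probe, masks, 1.0)

    def test_r_trace_decreases(self):
        frames, probe, masks, _ = tiny_series()
        prm = insitu.AlgorithmParams(n_iterations=60, seed=1)
        res = insitu.InSituCDI(frames, probe, masks, 1.0, prm).fit()
        assert res.r_trace.shape == (60,)
        assert res.final_r < res.r_trace[0]

    def test_deterministic(self):
        frames, probe, masks, _ = tiny_series()
        prm = insitu.AlgorithmParams(n_iterations=10, seed=5)
        a = insitu.InSituCDI(frames, probe, masks, 1.0, prm).fit()
        b = insitu.InSituCDI(frames, probe, masks, 1.0, prm).fit()
        np.testing.assert_array_equal(a.r_trace, b.r_trace)
        np.testing.assert_array_equal(
            a.objects[0].values, b.objects[0].values
        )

    def test_objects_respect_support(self):
        frames, probe, masks, _ = tiny_series()
        prm = insitu.AlgorithmParams(n_iterations=5, seed=0)
        res = insitu.InSituCDI(frames, probe, masks, 1.0, prm).fit()
        outside = ~masks.union
        for o in res.objects:
            assert np.abs(o.values[outside]).max() == 0.0

    def test_summary_mentions_key_fields(self):
        frames, probe, masks, _ = tiny_series()
        prm = insitu.AlgorithmParams(n_iterations=3, seed=0)
        res = insitu.InSituCDI(frames, probe, masks, 1.0, prm).fit()
        text = res.summary()
        assert "R-factor" in text and "frames" in text
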