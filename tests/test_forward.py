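"""Unit tests for the forward diffraction model."""

import numpy as np
import pytest

from insitucdi import forward, optics
from insitucdi.optics import CLASSICAL_ELECTRON_RADIUS, ComplexField


def random_field(n=64, px=20e-9, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    return ComplexField(vals, px)


class TestFFT:
    def test_round_trip(self):
        f = random_field()
        back = forward.ifft_centered(forward.fft_centered(f.values))
        np.testing.assert_allclose(back, f.values, atol=1e-12)

    def test_dc_at_center(self):
        n = 64
        vals = np.ones((n, n), dtype=np.complex128)
        spec = forward.fft_centered(vals)
        assert abs(spec[n // 2, n // 2]) == pytest.approx(n * n)
        spec[n // 2, n // 2] = 0.0
        np.testing.assert_allclose(spec, 0.0, atol=1e-8)

    def test_parseval(self):
        f = random_field()
        n = f.n
        power_real = np.sum(np.abs(f.values) ** 2)
        power_fourier = np.sum(np.abs(forward.fft_centered(f.values)) ** 2)
        assert power_fourier == pytest.approx(n * n * power_real, rel=1e-12)


class TestEffectiveElectronDensity:
    def test_weak_phase_limit(self):
        # A thin slab with small phase phi has t - 1 ~ i*phi, so
        # rho = i*(t-1)*A/(re*lambda) ~ -phi*A/(re*lambda) (real).
        wavelength = 1.55e-10
        px = 20e-9
        phi = 1e-4
        t = np.full((8, 8), np.exp(1j * phi))
        rho = forward.effective_electron_density(
            ComplexField(t, px), wavelength
        )
        expected = -phi * px**2 / (CLASSICAL_ELECTRON_RADIUS * wavelength)
        np.testing.assert_allclose(rho.values.real, expected, rtol=1e-3)

    def test_unit_transmission_is_zero(self):
        rho = forward.effective_electron_density(
            ComplexField(np.ones((8, 8)), 20e-9), 1.55e-10
        )
        np.testing.assert_array_equal(rho.values, 0.0)


class TestCountScale:
    def test_hand_value(self):
        # flux 1e11 ph/um^2/s = 1e23 ph/m^2/s, eta 0.8, 1 ms, lambda 1.5498e-10,
        # extent 10.24 um: scale = 1e23*0.8*1e-3*(re*lambda/extent)^2
        wavelength = 1.5498e-10
        extent = 10.24e-6
        expected = (
            1e23
            * 0.8
            * 1e-3
            * (CLASSICAL_ELECTRON_RADIUS * wavelength / extent) ** 2
        )
        got = forward.count_scale(1e11, 0.8, 1e-3, wavelength, extent)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.455e-19, rel=1e-3)


class TestDualFlux:
    def test_reduces_to_single_flux_when_equal(self):
        px, wavelength = 20e-9, 2.34e-9
        rng = np.random.default_rng(5)
        n = 64
        d = np.zeros((n, n), complex)
        s = np.zeros((n, n), complex)
        d[10:30, 40:60] = rng.normal(size=(20, 20))
        s[10:30, 4:24] = rng.normal(size=(20, 20))
        flux = 3.5e6
        dual = forward.dual_flux_intensity(
            ComplexField(d, px),
            ComplexField(s, px),
            forward.FluxSettings(
                detector_efficiency=0.8, dynamic_flux=flux, static_flux=flux
            ),
            wavelength,
        )
        single = forward.diffraction_intensity(
            ComplexField(d + s, px),
            forward.FluxSettings(incident_flux=flux, detector_efficiency=0.8),
            wavelength,
        )
        np.testing.assert_allclose(dual, single, rtol=1e-10, atol=1e-12)

    def test_nonnegative(self):
        px, wavelength = 20e-9, 2.34e-9
        rng = np.random.default_rng(6)
        n = 32
        d = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        s = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        pattern = forward.dual_flux_intensity(
            ComplexField(d, px),
            ComplexField(s, px),
            forward.FluxSettings(dynamic_flux=1e4, static_flux=1e8),
            wavelength,
        )
        assert np.all(pattern >= 0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward.dual_flux_intensity(
                ComplexField(np.ones((8, 8)), 1e-9),
                ComplexField(np.ones((16, 16)), 1e-9),
                forward.FluxSettings(dynamic_flux=1.0, static_flux=1.0),
                2.34e-9,
            )


class TestPoisson:
    def test_mean_and_variance(self):
        lam = 50.0
        expected = np.full((256, 256), lam)
        frame = forward.add_poisson(expected, seed=42)
        assert frame.counts.mean() == pytest.approx(lam, rel=0.01)
        assert frame.counts.var() == pytest.approx(lam, rel=0.05)

    def test_deterministic_per_seed(self):
        expected = np.full((32, 32), 7.0)
        a = forward.add_poisson(expected, seed=1)
        b = forward.add_poisson(expected, seed=1)
        c = forward.add_poisson(expected, seed=2)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_rejects_negative_expectation(self):
        with pytest.raises(ValueError):
            forward.add_poisson(np.full((4, 4), -1.0), seed=0)


class TestMissingCenter:
    def test_block_size_and_position(self):
        n, hw = 64, 2
        frame = forward.DiffractionFrame(np.ones((n, n)), None)
        masked = forward.apply_missing_center(frame, hw)
        assert int(np.sum(~masked.valid)) == (2 * hw + 1) ** 2
        c = n // 2
        assert not masked.valid[c, c]
        assert masked.valid[c - hw - 1, c]
        np.testing.assert_array_equal(masked.counts, frame.counts)

    def test_idempotent(self):
        frame = forward.DiffractionFrame(np.ones((32, 32)), None)
        once = forward.apply_missing_center(frame, 2)
        twice = forward.apply_missing_center(once, 2)
        np.testing.assert_array_equal(once.valid, twice.valid)

    def test_oversized_block_rejected(self):
        frame = forward.DiffractionFrame(np.ones((8, 8)), None)
        with pytest.raises(ValueError):
            forward.apply_missing_center(frame, 10)


class TestIntegrateSubframes:
    def test_sums(self):
        parts = [np.full((4, 4), v) for v in (1.0, 2.0, 3.0)]
        np.testing.assert_array_equal(
            forward.integrate_subframes(parts), np.full((4, 4), 6.0)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            forward.integrate_subframes([])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward.integrate_subframes([np.ones((4, 4)), np.ones((8, 8))])


class TestDiffractionFrame:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            forward.DiffractionFrame(np.full((4, 4), -1.0), None)

    def test_default_valid_mask(self):
        f = forward.DiffractionFrame(np.ones((4, 4)), None)
        assert f.valid.all() and f.valid.shape == (4, 4)
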