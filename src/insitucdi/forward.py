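"""Forward diffraction model: exit wave → measured photon counts.

The measured pattern is the squared magnitude of the centred FFT of the exit
wave, scaled into photon counts by the kinematic-scattering prefactor
I0·η·Δt·(r_e·λ / (a·σ1))², where a·σ1 is the physical extent of the
reconstruction array.  That prefactor yields counts when the Fourier
transform acts on the object expressed as *projected electron density in
electrons per pixel*; :func:`effective_electron_density` performs the exact
conversion from a complex transmission t(r):

    ρ̃(r) = i·(t(r) − 1)·A_px / (r_e·λ)

which reduces to n_e·h·A_px (electrons in the pixel column) in the
weak-phase limit and remains an exact reparametrisation of t for strong
objects.  All reconstructions in this package operate in these units.

Also here: the differential-flux two-region model, Poisson noise, the
missing-centre validity mask, and sub-frame motion-blur integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as _fft

from .optics import CLASSICAL_ELECTRON_RADIUS, ComplexField

__all__ = [
    "FluxSettings",
    "DiffractionFrame",
    "fft_centered",
    "ifft_centered",
    "effective_electron_density",
    "count_scale",
    "diffraction_intensity",
    "dual_flux_intensity",
    "add_poisson",
    "apply_missing_center",
    "integrate_subframes",
]


def fft_centered(values: np.ndarray) -> np.ndarray:
    """Unnormalised 2-D FFT with the zero-frequency sample at (N/2, N/2)."""
    return _fft.fftshift(_fft.fft2(_fft.ifftshift(values)))


def ifft_centered(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft_centered` (includes the 1/N² factor)."""
    return _fft.fftshift(_fft.ifft2(_fft.ifftshift(values)))


@dataclass(frozen=True)
class FluxSettings:
    """Photon-budget settings for the forward model.

    ``incident_flux`` is the uniform flux I0 in photons·µm⁻²·s⁻¹ (Eq-9-style
    single-flux mode).  ``dynamic_flux`` / ``static_flux`` are the per-region
    fluxes I_D and I_S (same units) of the differential-flux mode; fluence in
    photons·µm⁻² is flux × exposure.
    """

    incident_flux: float = 0.0
    detector_efficiency: float = 1.0
    exposure: float = 1.0
    dynamic_flux: float = 0.0
    static_flux: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "incident_flux",
            "exposure",
            "dynamic_flux",
            "static_flux",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.detector_efficiency <= 1.0:
            raise ValueError("detector_efficiency must lie in [0, 1]")


@dataclass
class DiffractionFrame:
    """One measured diffraction pattern: counts plus a validity mask."""

    counts: np.ndarray
    valid: np.ndarray
    exposure: float = 1.0
    index: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.valid is None:
            self.valid = np.ones(self.counts.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.counts.shape != self.valid.shape:
            raise ValueError("counts and valid mask must share a shape")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.counts.shape[0]


def effective_electron_density(
    transmission: ComplexField, wavelength: float
) -> ComplexField:
    """Convert a complex transmission to electrons-per-pixel scattering units.

    ρ̃ = i·(t − 1)·A_px/(r_e·λ).  The real part reduces to the projected
    electron count per pixel column in the weak-phase limit.
    """
    a_px = transmission.pixel_size**2
    values = (
        1j
        * (transmission.values - 1.0)
        * a_px
        / (CLASSICAL_ELECTRON_RADIUS * wavelength)
    )
    return ComplexField(values, transmission.pixel_size, plane="sample")


def count_scale(
    flux_per_um2_s: float,
    detector_efficiency: float,
    exposure: float,
    wavelength: float,
    array_extent: float,
) -> float:
    """Counts per |FFT[P·ρ̃]|² unit: I0·η·Δt·(r_e·λ/(a·σ1))².

    ``array_extent`` is the physical side of the sample-plane array,
    a·σ1 = N·(reconstruction pixel) = λ·z/p.  ``flux_per_um2_s`` is in
    photons·µm⁻²·s⁻¹ and is converted to SI internally.
    """
    flux_si = flux_per_um2_s * 1e12  # photons per m^2 per s
    return (
        flux_si
        * detector_efficiency
        * exposure
        * (CLASSICAL_ELECTRON_RADIUS * wavelength / array_extent) ** 2
    )


def diffraction_intensity(
    exit_wave: ComplexField,
    flux: FluxSettings,
    wavelength: float,
) -> np.ndarray:
    """Expected counts per detector pixel for a single uniform flux.

    ``exit_wave`` is P(r)·ρ̃(r) in electrons-per-pixel units (see module
    docstring); the result is I0·η·Δt·(r_e·λ/(a·σ1))²·|FFT[ψ]|².
    """
    scale = count_scale(
        flux.incident_flux,
        flux.detector_efficiency,
        flux.exposure,
        wavelength,
        exit_wave.extent,
    )
    return scale * np.abs(fft_centered(exit_wave.values)) ** 2


def dual_flux_intensity(
    dynamic_wave: ComplexField,
    static_wave: ComplexField,
    flux: FluxSettings,
    wavelength: float,
) -> np.ndarray:
    """Expected counts for the two-region differential-flux model.

    I(k) = η·Δt·(r_e·λ/(a·σ1))² · { I_D·|Ψ_D|² + I_S·|Ψ_S|²
           + √(I_D·I_S)·2·Re(Ψ_D·Ψ_S*) },

    which reduces exactly to the single-flux pattern of the summed waves when
    I_D = I_S.  Tiny negative excursions from rounding are clamped to zero.
    """
    if dynamic_wave.values.shape != static_wave.values.shape:
        raise ValueError("dynamic and static waves must share a grid")
    scale = count_scale(
        1.0,
        flux.detector_efficiency,
        flux.exposure,
        wavelength,
        dynamic_wave.extent,
    )
    psi_d = fft_centered(dynamic_wave.values)
    psi_s = fft_centered(static_wave.values)
    i_d, i_s = flux.dynamic_flux, flux.static_flux
    pattern = (
        i_d * np.abs(psi_d) ** 2
        + i_s * np.abs(psi_s) ** 2
        + np.sqrt(i_d * i_s) * 2.0 * np.real(psi_d * np.conj(psi_s))
    )
    return np.clip(scale * pattern, 0.0, None)


def add_poisson(
    expected: np.ndarray, seed: int, exposure: float = 1.0, index: int = 0
) -> DiffractionFrame:
    """Draw an independent Poisson realisation of an expected-count pattern."""
    expected = np.asarray(expected, dtype=np.float64)
    if np.any(expected < 0):
        raise ValueError("expected counts must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(np.float64)
    return DiffractionFrame(
        counts, np.ones(expected.shape, dtype=bool), exposure=exposure, index=index
    )


def apply_missing_center(
    frame: DiffractionFrame, half_width: int
) -> DiffractionFrame:
    """Invalidate the central (2·half_width+1)² block around zero frequency.

    The zero-frequency pixel sits at index (N//2, N//2) in the centred FFT
    convention.  Counts are unchanged; the validity mask is cleared.
    Idempotent.
    """
    n = frame.n
    if 2 * half_width + 1 > n:
        raise ValueError("missing-centre block larger than the detector")
    valid = frame.valid.copy()
    c = n // 2
    valid[c - half_width : c + half_width + 1, c - half_width : c + half_width + 1] = (
        False
    )
    return DiffractionFrame(
        frame.counts.copy(), valid, exposure=frame.exposure, index=frame.index
    )


def integrate_subframes(subframe_patterns: list[np.ndarray]) -> np.ndarray:
    """Sum expected-count patterns of sub-exposures (motion blur in intensity).

    Dynamics during one detector frame blur the *intensity*, not the complex
    amplitude, so sub-frame patterns add pixelwise.
    """
    if not subframe_patterns:
        raise ValueError("need at least one subframe")
    shapes = {p.shape for p in subframe_patterns}
    if len(shapes) > 1:
        raise ValueError(f"subframes disagree on shape: {shapes}")
    return np.sum(subframe_patterns, axis=0)
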