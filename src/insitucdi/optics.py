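"""Physical-optics utilities for coherent diffractive imaging.

Wavelength/energy conversion, tabulated X-ray optical constants, dual-pinhole
aperture synthesis, band-limited angular-spectrum propagation, and the
geometry-derived quantities (reconstruction pixel size, detector-edge
resolution, linear oversampling ratio) that a far-field CDI experiment is
characterised by.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as _fft

__all__ = [
    "HC_EV_NM",
    "CLASSICAL_ELECTRON_RADIUS",
    "ExperimentGeometry",
    "OpticalConstants",
    "ComplexField",
    "OPTICAL_CONSTANTS",
    "get_optical_constants",
    "energy_to_wavelength",
    "dual_pinhole_aperture",
    "propagate",
    "detector_edge_resolution",
    "oversampling_ratio",
    "reconstruction_pixel_size",
]

#: hc in eV·nm (CODATA, rounded to the conventional 1239.84).
HC_EV_NM = 1239.84

#: Classical electron radius r_e in metres.
CLASSICAL_ELECTRON_RADIUS = 2.8179403262e-15


def energy_to_wavelength(energy_ev: float) -> float:
    """Convert photon energy in eV to wavelength in metres.

    λ = hc/E with hc = 1239.84 eV·nm.

    Parameters
    ----------
    energy_ev : float
        Photon energy in electron-volts, must be positive.

    Returns
    -------
    float
        Wavelength in metres.
    """
    if energy_ev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_ev}")
    return HC_EV_NM / energy_ev * 1e-9


@dataclass(frozen=True)
class ExperimentGeometry:
    """Far-field CDI experiment geometry.

    Parameters
    ----------
    photon_energy : float
        Photon energy in eV.
    sample_to_detector_distance : float
        z, in metres.
    detector_pixels : int
        N, pixels per detector side (square detector).
    detector_pitch : float
        p, detector pixel size in metres.
    illuminated_extent : float
        a, tight linear extent of the illuminated area in metres
        (outer edge to outer edge for a dual pinhole).
    aperture_to_sample_distance : float
        Propagation distance from the pinhole aperture to the sample plane,
        metres.
    """

    photon_energy: float
    sample_to_detector_distance: float
    detector_pixels: int
    detector_pitch: float
    illuminated_extent: float
    aperture_to_sample_distance: float = 0.0
    wavelength: float = field(init=False)

    def __post_init__(self) -> None:
        for name in (
            "photon_energy",
            "sample_to_detector_distance",
            "detector_pitch",
            "illuminated_extent",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.detector_pixels < 2:
            raise ValueError("detector_pixels must be >= 2")
        object.__setattr__(
            self, "wavelength", energy_to_wavelength(self.photon_energy)
        )


def reconstruction_pixel_size(geometry: ExperimentGeometry) -> float:
    """Sample-plane pixel size λ·z/(N·p) of the reconstruction, in metres."""
    return (
        geometry.wavelength
        * geometry.sample_to_detector_distance
        / (geometry.detector_pixels * geometry.detector_pitch)
    )


def detector_edge_resolution(geometry: ExperimentGeometry) -> float:
    """Full-period resolution at the detector edge, 2·λ·z/(N·p), in metres.

    The full-period convention (twice the reconstruction pixel) is used
    throughout the package; the half-period value is
    :func:`reconstruction_pixel_size`.
    """
    return 2.0 * reconstruction_pixel_size(geometry)


def oversampling_ratio(geometry: ExperimentGeometry) -> float:
    """Linear oversampling ratio σ1 = (λ·z/p)/a.

    λ·z/p is the sample-plane extent covered by the reconstruction array;
    dividing by the illuminated extent a gives the linear oversampling of the
    phase problem.  σ1 > 1 is required for the problem to be solvable.
    """
    extent = (
        geometry.wavelength
        * geometry.sample_to_detector_distance
        / geometry.detector_pitch
    )
    return extent / geometry.illuminated_extent


@dataclass(frozen=True)
class OpticalConstants:
    """Complex refractive index decrement n = 1 − δ + iβ for one material."""

    material: str
    delta: float
    beta: float
    photon_energy: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.photon_energy <= 0:
            raise ValueError("photon_energy must be positive")


# Tabulated δ, β at the two energies the simulations use.  Values follow
# Henke-style electron-density arithmetic (δ = r_e λ² n_e / 2π,
# β = µλ/4π); the protein β at 530 eV is anchored to µ = 1.25e4 cm⁻¹ for
# H50C30N9O10S1 at ρ = 1.35 g cm⁻³, and the Au/H2O soft-X-ray values carry
# approximate dispersion corrections near the O K-edge.
OPTICAL_CONSTANTS: dict[tuple[str, float], OpticalConstants] = {
    ("Pb", 8000.0): OpticalConstants("Pb", 2.90e-5, 3.20e-6, 8000.0),
    ("H2O", 8000.0): OpticalConstants("H2O", 3.60e-6, 1.28e-8, 8000.0),
    ("Au", 530.0): OpticalConstants("Au", 8.3e-3, 2.0e-3, 530.0),
    ("H2O", 530.0): OpticalConstants("H2O", 7.4e-4, 2.1e-5, 530.0),
    # Average protein H50C30N9O10S1 at 1.35 g cm^-3.
    ("protein", 530.0): OpticalConstants("protein", 9.0e-4, 2.327e-4, 530.0),
}


def get_optical_constants(material: str, photon_energy: float) -> OpticalConstants:
    """Look up bundled optical constants for a material at an energy (eV)."""
    key = (material, float(photon_energy))
    if key not in OPTICAL_CONSTANTS:
        known = sorted({f"{m}@{e:g}eV" for m, e in OPTICAL_CONSTANTS})
        raise KeyError(
            f"no tabulated constants for {material!r} at {photon_energy:g} eV; "
            f"available: {', '.join(known)}"
        )
    return OPTICAL_CONSTANTS[key]


@dataclass
class ComplexField:
    """A 2-D complex field sampled on a regular square grid.

    Used for the aperture transmission, the illumination P(r), object and
    exit-wave functions, and Fourier-space fields.
    """

    values: np.ndarray
    pixel_size: float
    plane: str = "sample"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("ComplexField requires a square 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def extent(self) -> float:
        """Physical side length of the grid in metres."""
        return self.n * self.pixel_size

    def power(self) -> float:
        """Total integrated power Σ|f|² (grid-sum convention)."""
        return float(np.sum(np.abs(self.values) ** 2))

    def copy(self) -> "ComplexField":
        return ComplexField(self.values.copy(), self.pixel_size, self.plane)


def dual_pinhole_aperture(
    hole_diameter: float,
    center_spacing: float,
    n: int,
    pixel_size: float,
    hole_diameter2: float | None = None,
) -> ComplexField:
    """Binary transmission of a dual-pinhole aperture.

    Two discs separated centre-to-centre by ``center_spacing`` along the
    horizontal axis, placed symmetrically about the grid centre.  The left
    disc has diameter ``hole_diameter``; the right disc ``hole_diameter2``
    when given, else the same.  Unequal diameters make the aperture (and
    hence the support) non-centrosymmetric, which removes the conjugate-twin
    ambiguity of the phase problem.  A pixel is open when its centre lies
    inside a disc (no anti-aliasing, for bit-reproducibility).
    ``center_spacing = 0`` collapses both holes onto a single disc;
    ``hole_diameter = 0`` yields an empty aperture.

    Raises
    ------
    ValueError
        If the discs overlap (0 < spacing < mean diameter) or are clipped by
        the grid boundary.
    """
    if hole_diameter2 is None:
        hole_diameter2 = hole_diameter
    if center_spacing < 0:
        raise ValueError("center_spacing must be >= 0")
    if hole_diameter < 0 or hole_diameter2 < 0:
        raise ValueError("hole_diameter must be >= 0")
    if 0 < center_spacing < (hole_diameter + hole_diameter2) / 2.0:
        raise ValueError("pinholes overlap: spacing < mean diameter")
    half_extent = n * pixel_size / 2.0
    for d in (hole_diameter, hole_diameter2):
        if d > 0 and center_spacing / 2.0 + d / 2.0 > half_extent:
            raise ValueError("pinholes clipped by the grid boundary")

    coords = (np.arange(n) - n // 2) * pixel_size
    x, y = np.meshgrid(coords, coords, indexing="xy")
    values = np.zeros((n, n), dtype=np.complex128)
    for cx, d in (
        (-center_spacing / 2.0, hole_diameter),
        (center_spacing / 2.0, hole_diameter2),
    ):
        if d > 0:
            values[(x - cx) ** 2 + y**2 < (d / 2.0) ** 2] = 1.0
    return ComplexField(values, pixel_size, plane="aperture")


def propagate(
    fld: ComplexField, distance: float, wavelength: float
) -> ComplexField:
    """Free-space propagation by the band-limited angular-spectrum method.

    Exact for free space on a periodic grid: multiplies the field's Fourier
    transform by exp(i·2π·d·sqrt(1/λ² − fx² − fy²)); evanescent components
    (1/λ² < fx² + fy²) are suppressed.  Unitary on the propagating band, so
    total power is conserved and propagation by −d inverts propagation by +d.
    ``distance = 0`` is an exact identity.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if distance == 0.0:
        return fld.copy()
    n = fld.n
    f = _fft.fftfreq(n, d=fld.pixel_size)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    f2 = fx**2 + fy**2
    kz2 = 1.0 / wavelength**2 - f2
    propagating = kz2 > 0
    if not propagating.all():
        warnings.warn(
            "angular-spectrum kernel truncates evanescent components; "
            "grid sampling is coarser than λ/2",
            stacklevel=2,
        )
    kernel = np.zeros_like(f2, dtype=np.complex128)
    kernel[propagating] = np.exp(
        2j * np.pi * distance * np.sqrt(kz2[propagating])
    )
    spectrum = _fft.fft2(fld.values)
    out = _fft.ifft2(spectrum * kernel)
    plane = "sample" if fld.plane == "aperture" else fld.plane
    return ComplexField(out, fld.pixel_size, plane=plane)
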