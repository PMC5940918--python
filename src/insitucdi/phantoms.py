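"""Synthetic specimens for the diffraction simulations.

Three generators: a time-evolving dendrite-like growth sequence (the dynamic
specimen for the hard-X-ray simulation), a lacey gold web (the static
scattering structure for the soft-X-ray dose study), and a cell-like object
(vesicle plus protein aggregates).  A fourth operation converts per-material
thickness maps into the complex transmission function of the thin-object
(projection) approximation.

All generators are pure functions of (grid, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optics import ComplexField, OpticalConstants

__all__ = [
    "ThicknessMap",
    "DynamicScene",
    "make_dendrite_series",
    "make_cell_phantom",
    "make_lacey_gold",
    "thickness_to_transmission",
    "band_limit",
]


def band_limit(values: np.ndarray, frac: float) -> np.ndarray:
    """Hard circular low-pass at ``frac`` of the grid Nyquist frequency.

    Zeroes every Fourier component with radial frequency above
    ``frac × f_Nyquist``, imposing an exactly known band limit on a phantom:
    the shortest full period retained is ``2 · pixel / frac``.  Accepts real
    or complex arrays; real input returns real output.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    n0, n1 = values.shape
    fy = np.fft.fftfreq(n0)
    fx = np.fft.fftfreq(n1)
    keep = fy[:, None] ** 2 + fx[None, :] ** 2 <= (frac * 0.5) ** 2
    out = np.fft.ifft2(np.fft.fft2(values) * keep)
    return out.real if np.isrealobj(values) else out


@dataclass
class ThicknessMap:
    """Per-material projected thickness (metres) on the sample-plane grid."""

    thickness: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        shapes = {m: a.shape for m, a in self.thickness.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"inconsistent grids across materials: {shapes}")
        for m, a in self.thickness.items():
            if np.any(a < 0):
                raise ValueError(f"negative thickness for material {m!r}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n(self) -> int:
        return next(iter(self.thickness.values())).shape[0]

    @property
    def materials(self) -> list[str]:
        return list(self.thickness)


@dataclass
class DynamicScene:
    """An ordered time series of thickness maps with a fixed frame interval."""

    frames: list[ThicknessMap]
    frame_interval: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a DynamicScene needs at least one frame")
        n0, mats0 = self.frames[0].n, set(self.frames[0].materials)
        for f in self.frames:
            if f.n != n0 or set(f.materials) != mats0:
                raise ValueError("all frames must share grid and materials")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _disc_mask(n: int, center_px: tuple[float, float], radius_px: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    cy, cx = center_px
    return (yy - cy) ** 2 + (xx - cx) ** 2 < radius_px**2


def make_dendrite_series(
    n: int,
    pixel_size: float,
    n_frames: int,
    seed: int,
    *,
    max_thickness: float = 500e-9,
    water_thickness: float = 1e-6,
    region_center: tuple[float, float] | None = None,
    region_radius: float | None = None,
    n_tips: int = 3,
    step_px: float = 1.5,
    branch_prob: float = 0.06,
    smooth_px: float = 1.0,
    frame_interval: float = 1e-3,
) -> DynamicScene:
    """Generate a branching, tip-growing dendrite immersed in a water slab.

    A few growth tips start on the edge of the growth region (a disc of
    ``region_radius`` about ``region_center``, in metres relative to the grid
    centre; defaults to the full grid) and advance inward with jittered
    directions, occasionally branching, depositing lead whose thickness ramps
    toward ``max_thickness`` at the root.  Per-pixel thickness is
    non-decreasing over frames (growth only), matching an electrodeposition
    growth phase.  A mild Gaussian blur (``smooth_px``) anti-aliases the
    deposit so the phantom is band-limited near the grid Nyquist frequency.

    Returns a scene whose frames carry materials ``"Pb"`` (the dendrite) and
    ``"H2O"`` (a uniform slab of ``water_thickness``).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if region_radius is None:
        region_radius = n * pixel_size / 2.0
    radius_px = region_radius / pixel_size
    if radius_px < 8:
        raise ValueError("grid/region too small for the branch scale")
    if region_center is None:
        center_px = (n / 2.0, n / 2.0)
    else:
        center_px = (
            n / 2.0 + region_center[0] / pixel_size,
            n / 2.0 + region_center[1] / pixel_size,
        )
    region = _disc_mask(n, center_px, radius_px)

    rng = np.random.default_rng(seed)
    # Tips start on the region boundary, heading toward the region centre.
    angles = rng.uniform(0, 2 * np.pi, size=n_tips)
    tips = []
    for ang in angles:
        y = center_px[0] + radius_px * 0.95 * np.sin(ang)
        x = center_px[1] + radius_px * 0.95 * np.cos(ang)
        tips.append({"pos": np.array([y, x]), "dir": ang + np.pi, "width": 3.0})

    height = np.zeros((n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    frames: list[ThicknessMap] = []
    steps_per_frame = max(1, int(round(2.0 * radius_px / (step_px * n_frames))))

    for _ in range(n_frames):
        for _ in range(steps_per_frame):
            new_tips = []
            for tip in tips:
                tip["dir"] += rng.normal(0.0, 0.35)
                tip["pos"] = tip["pos"] + step_px * np.array(
                    [np.sin(tip["dir"]), np.cos(tip["dir"])]
                )
                y, x = tip["pos"]
                if not (0 <= y < n and 0 <= x < n):
                    continue
                if (y - center_px[0]) ** 2 + (x - center_px[1]) ** 2 > radius_px**2:
                    continue
                # Stamp a rounded deposit; thickness tapers with tip width.
                w = tip["width"]
                amp = max_thickness * min(1.0, w / 3.0)
                lo_y, hi_y = int(max(0, y - 3 * w)), int(min(n, y + 3 * w + 1))
                lo_x, hi_x = int(max(0, x - 3 * w)), int(min(n, x + 3 * w + 1))
                d2 = (yy[lo_y:hi_y, lo_x:hi_x] - y) ** 2 + (
                    xx[lo_y:hi_y, lo_x:hi_x] - x
                ) ** 2
                stamp = amp * np.exp(-d2 / (2.0 * (w / 1.5) ** 2))
                np.maximum(
                    height[lo_y:hi_y, lo_x:hi_x],
                    stamp,
                    out=height[lo_y:hi_y, lo_x:hi_x],
                )
                if rng.uniform() < branch_prob and w > 1.2:
                    new_tips.append(
                        {
                            "pos": tip["pos"].copy(),
                            "dir": tip["dir"] + rng.choice([-1.0, 1.0]) * 0.9,
                            "width": w * 0.8,
                        }
                    )
                tip["width"] = max(1.0, w * 0.999)
                new_tips.append(tip)
            tips = new_tips
            if not tips:
                break
        pb = ndimage.gaussian_filter(height, smooth_px) if smooth_px > 0 else height
        pb = np.clip(pb, 0.0, max_thickness) * region
        frames.append(
            ThicknessMap(
                {
                    "Pb": pb.copy(),
                    "H2O": np.full((n, n), water_thickness),
                },
                pixel_size,
            )
        )
    return DynamicScene(frames, frame_interval, seed)


def make_cell_phantom(
    n: int,
    pixel_size: float,
    seed: int,
    *,
    max_thickness: float = 1e-6,
    water_thickness: float = 1e-6,
    cell_extent: float = 3e-6,
    organelle_length: float = 2e-6,
    n_aggregates: int = 25,
    region_center: tuple[float, float] = (0.0, 0.0),
) -> ThicknessMap:
    """Cell-like phantom: one elongated organelle plus protein aggregates.

    The protein (average composition H50C30N9O10S1) occupies a
    ``cell_extent`` × ``cell_extent`` square about ``region_center`` (metres
    from the grid centre); total protein thickness is capped at
    ``max_thickness``.  The whole field carries a uniform water slab.
    """
    if n * pixel_size < cell_extent:
        raise ValueError("grid smaller than the requested cell extent")
    rng = np.random.default_rng(seed)
    cy = n / 2.0 + region_center[0] / pixel_size
    cx = n / 2.0 + region_center[1] / pixel_size
    half = cell_extent / 2.0 / pixel_size
    yy, xx = np.mgrid[0:n, 0:n]

    # Elongated organelle: rotated ellipse with a smooth dome profile.
    theta = rng.uniform(0, np.pi)
    la = organelle_length / 2.0 / pixel_size
    lb = la * rng.uniform(0.22, 0.32)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    r2 = (u / la) ** 2 + (v / lb) ** 2
    protein = 0.7 * max_thickness * np.sqrt(np.clip(1.0 - r2, 0.0, None))

    # Scattered cytosolic aggregates (small smooth blobs).
    for _ in range(n_aggregates):
        ay = cy + rng.uniform(-0.9, 0.9) * half
        ax = cx + rng.uniform(-0.9, 0.9) * half
        ar = rng.uniform(2.0, 0.12 * half)
        d2 = (yy - ay) ** 2 + (xx - ax) ** 2
        protein += 0.5 * max_thickness * np.exp(-d2 / (2 * ar**2))

    inside = (np.abs(yy - cy) < half) & (np.abs(xx - cx) < half)
    protein = np.clip(protein, 0.0, max_thickness) * inside
    return ThicknessMap(
        {"protein": protein, "H2O": np.full((n, n), water_thickness)},
        pixel_size,
    )


def make_lacey_gold(
    n: int,
    pixel_size: float,
    thickness: float,
    seed: int,
    *,
    fill_fraction: float = 0.35,
    correlation_px: float = 8.0,
    region_center: tuple[float, float] = (0.0, 0.0),
    region_radius: float | None = None,
) -> ThicknessMap:
    """Binary lacey web of gold with uniform thickness.

    Ridges of a smoothed Gaussian random field (pixels where the field is
    close to its median) form a connected web resembling lacey carbon.  The
    open fraction is set exactly by quantile thresholding, so the fill
    fraction equals ``fill_fraction`` up to rasterisation.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if not 0.0 < fill_fraction < 1.0:
        raise ValueError("fill_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n, n))
    smooth = ndimage.gaussian_filter(noise, correlation_px)
    dev = np.abs(smooth - np.median(smooth))
    if region_radius is not None:
        cy = n / 2.0 + region_center[0] / pixel_size
        cx = n / 2.0 + region_center[1] / pixel_size
        region = _disc_mask(n, (cy, cx), region_radius / pixel_size)
        cut = np.quantile(dev[region], fill_fraction)
        web = (dev < cut) & region
    else:
        cut = np.quantile(dev, fill_fraction)
        web = dev < cut
    return ThicknessMap({"Au": web * thickness}, pixel_size)


def thickness_to_transmission(
    maps: ThicknessMap,
    constants: dict[str, OpticalConstants],
    wavelength: float,
) -> ComplexField:
    """Complex transmission of the thin-object (projection) approximation.

    t(r) = exp( i·(2π/λ)·Σ_m (−δ_m + i·β_m)·h_m(r) ), so |t| ≤ 1 everywhere
    and a non-absorbing material (β = 0) gives a pure phase object.
    """
    missing = [m for m in maps.materials if m not in constants]
    if missing:
        raise ValueError(f"missing optical constants for materials: {missing}")
    phase = np.zeros((maps.n, maps.n), dtype=np.complex128)
    for m, h in maps.thickness.items():
        c = constants[m]
        phase += (2j * np.pi / wavelength) * (-c.delta + 1j * c.beta) * h
    return ComplexField(np.exp(phase), maps.pixel_size, plane="sample")
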