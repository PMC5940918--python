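"""Time-invariant-constraint phase retrieval for in situ CDI.

A time series of far-field diffraction patterns is measured while a dynamic
specimen under one pinhole interferes with a static region under the other.
Because the static region does not change between frames, its reconstruction
is shared across the whole series: each sweep over the frames blends the
static estimate carried from the previous frame with the stored one,

    S'_t = γ·S_{t-1} + (1 − γ)·S_t,          (weighting factor γ, default 0.8)

combines it with the frame's dynamic estimate into an object O_t = S'_t + D_t,
forms the exit wave ψ_t = O_t·P with the known illumination P, enforces the
measured Fourier magnitudes (missing-centre pixels left unconstrained),
and updates the object by the probe-weighted rule

    O'_t = O_t + |P|·P* / (α·(|P|² + ε)) · (ψ'_t − ψ_t),   α = max|P|.

The updated object is split by the static/dynamic support masks, the static
part is chained into the next frame, and after a full sweep the normalised
L1 Fourier discrepancy (R-factor) monitors convergence.

The module exposes both the individual update operations and a
Model/Results pair (:class:`InSituCDI` / :class:`InSituResults`) in the
style of statsmodels: the model is built from the data and the experiment
description, ``fit()`` runs the iterations and returns the estimates with
their diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward import DiffractionFrame, fft_centered, ifft_centered
from .optics import ComplexField

__all__ = [
    "RegionMasks",
    "AlgorithmParams",
    "InSituCDI",
    "InSituResults",
    "weighted_static_update",
    "fourier_magnitude_projection",
    "object_update",
    "split_object",
    "r_factor",
    "reconstruct_series",
    "masks_from_pinholes",
]


@dataclass
class RegionMasks:
    """Disjoint boolean supports for the static and dynamic regions."""

    static_support: np.ndarray
    dynamic_support: np.ndarray

    def __post_init__(self) -> None:
        self.static_support = np.asarray(self.static_support, dtype=bool)
        self.dynamic_support = np.asarray(self.dynamic_support, dtype=bool)
        if self.static_support.shape != self.dynamic_support.shape:
            raise ValueError("support masks must share a shape")
        if np.any(self.static_support & self.dynamic_support):
            raise ValueError("static and dynamic supports must be disjoint")
        if not self.static_support.any() or not self.dynamic_support.any():
            raise ValueError("both supports must be non-empty")

    @property
    def union(self) -> np.ndarray:
        return self.static_support | self.dynamic_support


def masks_from_pinholes(
    n: int,
    pixel_size: float,
    hole_diameter: float,
    center_spacing: float,
    dilation_px: int = 2,
    hole_diameter2: float | None = None,
) -> RegionMasks:
    """Support masks from the two pinhole discs, dilated to absorb fringes.

    The static region is the left disc (diameter ``hole_diameter``), the
    dynamic region the right disc (``hole_diameter2`` when given, else the
    same), matching :func:`insitucdi.optics.dual_pinhole_aperture`.  Each is
    dilated by ``dilation_px`` pixels; overlapping pixels after dilation are
    assigned to neither support.
    """
    if hole_diameter2 is None:
        hole_diameter2 = hole_diameter
    coords = (np.arange(n) - n // 2) * pixel_size
    x, y = np.meshgrid(coords, coords, indexing="xy")
    left = (x + center_spacing / 2.0) ** 2 + y**2 < (hole_diameter / 2.0) ** 2
    right = (x - center_spacing / 2.0) ** 2 + y**2 < (
        hole_diameter2 / 2.0
    ) ** 2
    if dilation_px > 0:
        st = ndimage.binary_dilation(left, iterations=dilation_px)
        dy = ndimage.binary_dilation(right, iterations=dilation_px)
    else:
        st, dy = left, right
    overlap = st & dy
    return RegionMasks(st & ~overlap, dy & ~overlap)


@dataclass
class AlgorithmParams:
    """Tunables of the time-invariant-constraint algorithm.

    gamma : weighting factor of the static blend, in [0, 1] (default 0.8).
    epsilon_frac : regulariser of the object update as a fraction of
        max|P|² (default 1e-6).
    n_iterations : number of full sweeps over the time series.
    share_static : when False the static blend and cross-frame chaining are
        disabled, degrading the method to independent per-frame
        support-constrained retrieval (used for ablation).
    indexing : how the static estimate propagates between frames.
        "chain" (default) treats the static function as one object carried
        along the sweep, exponentially smoothed by γ at each frame — the
        strongest reading of the time-invariance recursion.  "same-frame"
        blends the carried static with the frame's own stored static from
        the previous sweep; "shifted" stores each split at the next frame
        index (the literal t+1 label).
    probe_threshold : |P| fraction below which the initial object is zeroed
        rather than divided by P.
    alpha_squared : use α = max|P|² instead of the printed α = max|P| in the
        object update (comparison switch).
    smooth_sigma0 : starting σ (pixels) of the coarse-to-fine real-space
        smoothing applied to the updated object during the early iterations.
        Random starts otherwise stagnate in local minima of the magnitude
        constraint; annealing the scale from coarse to fine lets the strong
        low-frequency structure lock in first.  0 disables.
    smooth_frac : fraction of the iterations over which the smoothing is
        annealed to zero (the remainder run the plain update).
    smooth_cycles : number of coarse-to-fine sweeps within the annealed
        stretch, each restarting at half the previous σ.
    """

    gamma: float = 0.8
    epsilon_frac: float = 1e-6
    n_iterations: int = 500
    seed: int = 0
    share_static: bool = True
    indexing: str = "chain"
    probe_threshold: float = 0.01
    alpha_squared: bool = False
    smooth_sigma0: float = 4.0
    smooth_frac: float = 0.4
    smooth_cycles: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.indexing not in ("chain", "same-frame", "shifted"):
            raise ValueError(
                "indexing must be 'chain', 'same-frame' or 'shifted'"
            )
        if self.smooth_sigma0 < 0:
            raise ValueError("smooth_sigma0 must be >= 0")
        if not 0.0 <= self.smooth_frac <= 1.0:
            raise ValueError("smooth_frac must lie in [0, 1]")
        if self.smooth_cycles < 1:
            raise ValueError("smooth_cycles must be >= 1")

    def smoothing_sigma(self, iteration: int) -> float:
        """σ of the annealed smoothing at a given iteration (0 = off)."""
        n_anneal = int(self.smooth_frac * self.n_iterations)
        if self.smooth_sigma0 == 0.0 or iteration >= n_anneal or n_anneal == 0:
            return 0.0
        per_cycle = max(1, n_anneal // self.smooth_cycles)
        cycle = min(iteration // per_cycle, self.smooth_cycles - 1)
        frac = (iteration - cycle * per_cycle) / per_cycle
        sigma = self.smooth_sigma0 * 0.5**cycle * (1.0 - min(frac, 1.0))
        return sigma if sigma > 0.3 else 0.0


def weighted_static_update(
    s_prev_frame: np.ndarray, s_this_frame: np.ndarray, gamma: float
) -> np.ndarray:
    """Convex blend γ·S_{t−1} + (1−γ)·S_t of two static estimates."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if s_prev_frame.shape != s_this_frame.shape:
        raise ValueError("static estimates must share a grid")
    return gamma * s_prev_frame + (1.0 - gamma) * s_this_frame


def fourier_magnitude_projection(
    exit_wave: np.ndarray,
    measured_magnitude: np.ndarray,
    valid: np.ndarray,
) -> np.ndarray:
    """Replace calculated Fourier magnitudes by measured ones, keep phases.

    On invalid (missing-centre) pixels the calculated complex value passes
    through unchanged.  Zero-magnitude calculated pixels adopt the measured
    magnitude with zero phase.  Returns the updated real-space exit wave.
    """
    spectrum = fft_centered(exit_wave)
    mag = np.abs(spectrum)
    phase = np.where(mag > 0, spectrum / np.where(mag > 0, mag, 1.0), 1.0)
    projected = np.where(valid, measured_magnitude * phase, spectrum)
    return ifft_centered(projected)


def object_update(
    obj: np.ndarray,
    exit_wave: np.ndarray,
    exit_wave_updated: np.ndarray,
    probe: np.ndarray,
    epsilon: float,
    alpha_squared: bool = False,
) -> np.ndarray:
    """Probe-weighted object update O' = O + |P|P*/(α(|P|²+ε))·(ψ' − ψ)."""
    abs_p = np.abs(probe)
    alpha = float(abs_p.max())
    if alpha == 0.0:
        raise ValueError("probe is identically zero")
    if alpha_squared:
        alpha = alpha**2
    weight = abs_p * np.conj(probe) / (alpha * (abs_p**2 + epsilon))
    return obj + weight * (exit_wave_updated - exit_wave)


def split_object(
    obj_updated: np.ndarray, masks: RegionMasks
) -> tuple[np.ndarray, np.ndarray]:
    """Split an updated object into static and dynamic parts by support.

    Pixels outside both supports are dropped (support constraint), so
    S + D equals the object masked to the union support.
    """
    return obj_updated * masks.static_support, obj_updated * masks.dynamic_support


def r_factor(
    measured_magnitudes: list[np.ndarray],
    calculated_magnitudes: list[np.ndarray],
    valid_masks: list[np.ndarray],
) -> float:
    """Normalised L1 Fourier discrepancy over all frames and valid pixels.

    R = Σ_t Σ_k ||Ψ_m| − |Ψ_calc|| / Σ_t Σ_k |Ψ_m|.
    """
    if not measured_magnitudes:
        raise ValueError("need at least one frame")
    num = 0.0
    den = 0.0
    for m, c, v in zip(measured_magnitudes, calculated_magnitudes, valid_masks):
        num += float(np.sum(np.abs(m[v] - c[v])))
        den += float(np.sum(m[v]))
    if den == 0.0:
        raise ValueError("all-zero measured magnitudes: R-factor undefined")
    return num / den


@dataclass
class InSituResults:
    """Reconstruction estimates and diagnostics returned by ``fit``.

    objects : per-frame complex object estimates (effective electron-density
        units, supported on the union mask).
    exit_waves : per-frame O_t·P.
    static_estimate : the shared static-region object after the final sweep.
    r_trace : R-factor per iteration.
    """

    model: "InSituCDI"
    objects: list[ComplexField]
    exit_waves: list[ComplexField]
    static_estimate: ComplexField
    r_trace: np.ndarray
    params: AlgorithmParams

    @property
    def n_frames(self) -> int:
        return len(self.objects)

    @property
    def final_r(self) -> float:
        return float(self.r_trace[-1])

    def dynamic_objects(self) -> list[ComplexField]:
        """Per-frame object restricted to the dynamic support."""
        m = self.model.masks.dynamic_support
        return [
            ComplexField(o.values * m, o.pixel_size, plane="sample")
            for o in self.objects
        ]

    def summary(self) -> str:
        lines = [
            "In situ CDI reconstruction",
            "=" * 44,
            f"{'frames':<28}{self.n_frames}",
            f"{'grid':<28}{self.objects[0].n} x {self.objects[0].n}",
            f"{'pixel size':<28}{self.objects[0].pixel_size * 1e9:.3f} nm",
            f"{'iterations':<28}{self.params.n_iterations}",
            f"{'gamma (static blend)':<28}{self.params.gamma}",
            f"{'static constraint':<28}"
            f"{'on' if self.params.share_static else 'off'}",
            f"{'initial R-factor':<28}{self.r_trace[0]:.4f}",
            f"{'final R-factor':<28}{self.final_r:.4f}",
        ]
        return "\n".join(lines)


class InSituCDI:
    """Model: simultaneous phase retrieval of a diffraction time series.

    Parameters
    ----------
    frames : list of DiffractionFrame
        The measured time series (≥ 2 frames; the time-invariant constraint
        is vacuous for one).
    probe : ComplexField
        Known illumination P(r) on the sample-plane grid.
    masks : RegionMasks
        Static/dynamic supports, consistent with the probe's footprint.
    count_scale : float
        Counts per |FFT|² unit (see :func:`insitucdi.forward.count_scale`);
        measured magnitudes are √(counts / count_scale).
    params : AlgorithmParams, optional
    """

    def __init__(
        self,
        frames: list[DiffractionFrame],
        probe: ComplexField,
        masks: RegionMasks,
        count_scale: float,
        params: AlgorithmParams | None = None,
    ):
        if len(frames) < 2:
            raise ValueError(
                "the time-invariant constraint needs at least 2 frames"
            )
        n = probe.n
        for f in frames:
            if f.n != n:
                raise ValueError("frame/probe grid mismatch")
        if masks.static_support.shape != (n, n):
            raise ValueError("mask/probe grid mismatch")
        if count_scale <= 0:
            raise ValueError("count_scale must be positive")
        self.frames = frames
        self.probe = probe
        self.masks = masks
        self.count_scale = count_scale
        self.params = params or AlgorithmParams()
        self.measured = [np.sqrt(f.counts / count_scale) for f in frames]
        self.valid = [f.valid for f in frames]

    def _initial_state(
        self, rng: np.random.Generator
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Random-phase initial static/dynamic estimates per frame."""
        p = self.probe.values
        abs_p = np.abs(p)
        ok = abs_p > self.params.probe_threshold * abs_p.max()
        inv_p = np.zeros_like(p)
        inv_p[ok] = 1.0 / p[ok]
        statics, dynamics = [], []
        for mag, v in zip(self.measured, self.valid):
            phase = rng.uniform(0.0, 2.0 * np.pi, size=mag.shape)
            spectrum = np.where(v, mag, 0.0) * np.exp(1j * phase)
            obj = ifft_centered(spectrum) * inv_p
            s, d = split_object(obj, self.masks)
            statics.append(s)
            dynamics.append(d)
        return statics, dynamics

    def fit(self) -> InSituResults:
        """Run the iterative reconstruction and return the results."""
        prm = self.params
        rng = np.random.default_rng(prm.seed)
        p = self.probe.values
        epsilon = prm.epsilon_frac * float(np.abs(p).max() ** 2)
        statics, dynamics = self._initial_state(rng)
        n_frames = len(self.frames)
        objects = [np.zeros_like(p) for _ in range(n_frames)]
        r_trace = np.empty(prm.n_iterations)

        s_chain = statics[0]
        for j in range(prm.n_iterations):
            sigma = prm.smoothing_sigma(j)
            calc_mags: list[np.ndarray] = []
            for t in range(n_frames):
                if not prm.share_static:
                    s_blend = statics[t]
                elif prm.indexing == "chain":
                    s_blend = s_chain
                else:
                    s_blend = weighted_static_update(
                        s_chain, statics[t], prm.gamma
                    )
                obj = s_blend + dynamics[t]
                psi = obj * p
                spectrum_mag = np.abs(fft_centered(psi))
                calc_mags.append(spectrum_mag)
                psi_updated = fourier_magnitude_projection(
                    psi, self.measured[t], self.valid[t]
                )
                obj_updated = object_update(
                    obj, psi, psi_updated, p, epsilon, prm.alpha_squared
                )
                if sigma > 0.0:
                    obj_updated = ndimage.gaussian_filter(
                        obj_updated.real, sigma
                    ) + 1j * ndimage.gaussian_filter(obj_updated.imag, sigma)
                s_new, d_new = split_object(obj_updated, self.masks)
                objects[t] = s_new + d_new
                dynamics[t] = d_new
                if prm.indexing == "chain":
                    # One static object flows through the sweep, smoothed by
                    # the weighted blend at every frame.
                    s_chain = weighted_static_update(
                        s_chain, s_new, prm.gamma
                    )
                    statics[t] = s_new
                else:
                    if prm.indexing == "shifted":
                        statics[(t + 1) % n_frames] = s_new
                    else:
                        statics[t] = s_new
                    s_chain = s_new
            r_trace[j] = r_factor(self.measured, calc_mags, self.valid)

        px = self.probe.pixel_size
        fields = [ComplexField(o, px, plane="sample") for o in objects]
        waves = [ComplexField(o * p, px, plane="sample") for o in objects]
        static_mean = np.mean(
            [o * self.masks.static_support for o in objects], axis=0
        )
        return InSituResults(
            model=self,
            objects=fields,
            exit_waves=waves,
            static_estimate=ComplexField(static_mean, px, plane="sample"),
            r_trace=r_trace,
            params=prm,
        )


def reconstruct_series(
    frames: list[DiffractionFrame],
    probe: ComplexField,
    masks: RegionMasks,
    count_scale: float,
    params: AlgorithmParams | None = None,
) -> InSituResults:
    """Functional entry point: build the model and fit it."""
    return InSituCDI(frames, probe, masks, count_scale, params).fit()
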