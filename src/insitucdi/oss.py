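"""Single-frame phase retrieval by oversampling smoothness (OSS).

The reference reconstructor for the dose-reduction study.  OSS runs a
hybrid input-output (HIO) iteration inside a fixed real-space support and,
outside the support, progressively low-pass filters the density with a
Gaussian kernel W(k) = exp(−k²/(2α²)) whose width α steps down linearly
from N to N/10 over the iteration schedule.  The tightening filter damps
the high-frequency noise that HIO otherwise accumulates outside the
support.

Best-of-N selection: several independent random starts are run and the
reconstruction with the lowest single-frame Fourier R-factor is returned.

An optional a-priori static structure (a known complex object on a subset
of the support) can be re-imposed every iteration, the mode used when a
strongly scattering auxiliary structure accompanies a weakly illuminated
specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as _fft

from .forward import DiffractionFrame, fft_centered, ifft_centered
from .insitu import r_factor
from .optics import ComplexField

__all__ = ["OssParams", "OSS", "OSSResults", "oss_reconstruct"]


@dataclass
class OssParams:
    """OSS tunables.

    n_iterations : total iterations per run (default 500).
    n_runs : independent random starts; the lowest-R run wins (default 10).
    hio_beta : HIO feedback parameter (default 0.9).
    n_filters : number of filter-width steps; α descends linearly from N to
        N/10 across them (default 10).
    twin_break_frac : fraction of the early iterations during which the
        support is truncated to a non-centrosymmetric subset (its upper
        ~65 % in rows).  A centrosymmetric support (e.g. a circular
        pinhole) admits the conjugate-twin solution, and HIO-family
        iterations then stagnate on truth/twin mixtures; temporarily
        reducing the support to an asymmetric part selects one twin
        (Fienup & Wackerman, J. Opt. Soc. Am. A 3, 1897 (1986)).  Set to
        0 to disable (e.g. when the support is already asymmetric).
    """

    n_iterations: int = 500
    n_runs: int = 10
    hio_beta: float = 0.9
    n_filters: int = 10
    twin_break_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if not 0.0 <= self.twin_break_frac < 1.0:
            raise ValueError("twin_break_frac must lie in [0, 1)")


@dataclass
class OSSResults:
    """Best-of-N OSS reconstruction with per-run diagnostics."""

    model: "OSS"
    object_estimate: ComplexField
    r_factor: float
    run_r_factors: np.ndarray
    best_run: int
    params: OssParams

    def summary(self) -> str:
        lines = [
            "OSS reconstruction",
            "=" * 44,
            f"{'grid':<28}{self.object_estimate.n} x {self.object_estimate.n}",
            f"{'iterations / run':<28}{self.params.n_iterations}",
            f"{'independent runs':<28}{self.params.n_runs}",
            f"{'best run (0-based)':<28}{self.best_run}",
            f"{'per-run R-factors':<28}"
            + ", ".join(f"{r:.4f}" for r in self.run_r_factors),
            f"{'final R-factor':<28}{self.r_factor:.4f}",
        ]
        return "\n".join(lines)


class OSS:
    """Model: single-frame phase retrieval with a fixed support.

    Parameters
    ----------
    frame : DiffractionFrame
        Measured counts with validity mask.
    support : ndarray of bool
        Real-space support of the object.
    count_scale : float
        Counts per |FFT|² unit; magnitudes are √(counts/count_scale).
    pixel_size : float
        Sample-plane pixel, metres.
    params : OssParams, optional
    known_static : ndarray, optional
        A-priori complex object values re-imposed on ``static_mask`` every
        iteration.
    """

    def __init__(
        self,
        frame: DiffractionFrame,
        support: np.ndarray,
        count_scale: float,
        pixel_size: float,
        params: OssParams | None = None,
        known_static: np.ndarray | None = None,
        static_mask: np.ndarray | None = None,
    ):
        support = np.asarray(support, dtype=bool)
        if not support.any():
            raise ValueError("support must be non-empty")
        if support.shape != frame.counts.shape:
            raise ValueError("support/frame grid mismatch")
        if count_scale <= 0:
            raise ValueError("count_scale must be positive")
        if (known_static is None) != (static_mask is None):
            raise ValueError("known_static and static_mask go together")
        self.frame = frame
        self.support = support
        self.count_scale = count_scale
        self.pixel_size = pixel_size
        self.params = params or OssParams()
        self.known_static = known_static
        self.static_mask = (
            np.asarray(static_mask, dtype=bool) if static_mask is not None else None
        )
        self.measured = np.sqrt(frame.counts / count_scale)
        self.valid = frame.valid
        rows = np.nonzero(support.any(axis=1))[0]
        cut = rows[0] + int(0.65 * (rows[-1] - rows[0]))
        self.reduced_support = support & (
            np.arange(support.shape[0])[:, None] <= cut
        )

    def _filter_widths(self) -> np.ndarray:
        """Filter width α per iteration: N → N/10 in n_filters steps."""
        n = self.frame.n
        prm = self.params
        alphas = np.linspace(n, n / 10.0, prm.n_filters)
        per_step = int(np.ceil(prm.n_iterations / prm.n_filters))
        return np.repeat(alphas, per_step)[: prm.n_iterations]

    def _run(self, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        prm = self.params
        n = self.frame.n
        idx = np.arange(n) - n // 2
        ky, kx = np.meshgrid(idx, idx, indexing="ij")
        k2 = kx**2 + ky**2

        phase = rng.uniform(0.0, 2.0 * np.pi, size=(n, n))
        rho = ifft_centered(
            np.where(self.valid, self.measured, 0.0) * np.exp(1j * phase)
        )
        if self.known_static is not None:
            rho = np.where(self.static_mask, self.known_static, rho)

        n_break = int(prm.twin_break_frac * prm.n_iterations)
        final_r = np.inf
        for j, alpha in enumerate(self._filter_widths()):
            support = self.reduced_support if j < n_break else self.support
            spectrum = fft_centered(rho)
            mag = np.abs(spectrum)
            final_r = r_factor([self.measured], [mag], [self.valid])
            unit = np.where(mag > 0, spectrum / np.where(mag > 0, mag, 1.0), 1.0)
            projected = np.where(self.valid, self.measured * unit, spectrum)
            rho_proj = ifft_centered(projected)
            # HIO: keep the projection inside the support, feedback outside.
            rho_new = np.where(support, rho_proj, rho - prm.hio_beta * rho_proj)
            # OSS: low-pass the density outside the support.
            window = np.exp(-(k2) / (2.0 * alpha**2))
            filtered = ifft_centered(fft_centered(rho_new) * window)
            rho = np.where(support, rho_new, filtered)
            if self.known_static is not None:
                rho = np.where(self.static_mask, self.known_static, rho)
        return rho, final_r

    def fit(self) -> OSSResults:
        """Run ``n_runs`` seeded starts and keep the lowest-R result."""
        prm = self.params
        best_rho, run_rs = None, []
        for run in range(prm.n_runs):
            rng = np.random.default_rng((prm.seed, run))
            rho, r = self._run(rng)
            run_rs.append(r)
            if best_rho is None or r <= min(run_rs[:-1], default=np.inf):
                best_rho = rho
        run_rs = np.asarray(run_rs)
        best = int(np.argmin(run_rs))
        return OSSResults(
            model=self,
            object_estimate=ComplexField(best_rho, self.pixel_size, plane="sample"),
            r_factor=float(run_rs[best]),
            run_r_factors=run_rs,
            best_run=best,
            params=prm,
        )


def oss_reconstruct(
    frame: DiffractionFrame,
    support: np.ndarray,
    count_scale: float,
    pixel_size: float,
    params: OssParams | None = None,
    known_static: np.ndarray | None = None,
    static_mask: np.ndarray | None = None,
) -> tuple[ComplexField, float]:
    """Functional entry point; returns (best object, its Fourier R-factor)."""
    res = OSS(
        frame,
        support,
        count_scale,
        pixel_size,
        params,
        known_static,
        static_mask,
    ).fit()
    return res.object_estimate, res.r_factor
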