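# Methods

This note records the physical model, the reconstruction algorithms, the
phantom generators, and the numerical choices behind the package, with
the reasoning for each non-obvious decision.

## 1. Physical model

### Geometry and sampling

A far-field (Fraunhofer) geometry is assumed throughout: a plane wave of
energy *E* illuminates a dual-pinhole aperture, the transmitted wave
propagates a short distance to the specimen plane, and the exit wave
diffracts to a square detector of *N* × *N* pixels of pitch *p* at
distance *z*. The sample-plane reconstruction pixel is λz/(Np), the
array extent is λz/p, and the linear oversampling ratio is
σ₁ = (λz/p)/a with *a* the illuminated extent (outer edge to outer edge
of the two pinholes). The detector-edge *full-period* resolution is
2λz/(Np); the full-period convention is used for every resolution quoted
by the package. Aperture-to-specimen propagation uses the band-limited
angular-spectrum method, which is exact for free space on a periodic
grid, unitary, and invertible.

### Specimen model

Specimens are thin objects in the projection approximation: per-material
projected thickness maps h_m(r) combine into a complex transmission

    t(r) = exp( i·(2π/λ)·Σ_m (−δ_m + i·β_m)·h_m(r) ),

with tabulated optical constants (δ, β) for Pb and water at 8 keV and
Au, water, and average protein (H50C30N9O10S1, ρ = 1.35 g cm⁻³,
µ = 1.25×10⁴ cm⁻¹ at 530 eV) at 530 eV.

### From exit wave to photon counts

The scattered intensity follows kinematic (first Born) scattering. The
object entering the Fourier transform is the *effective projected
electron density* in electrons per pixel,

    ρ̃(r) = i·(t(r) − 1)·A_px / (r_e·λ),

an exact reparametrisation of the transmission that reduces to n_e·h·A_px
(the electron content of the pixel column) in the weak-phase limit. With
an unnormalised FFT the expected counts are

    I(k) = I₀·η·Δt·(r_e·λ / (a·σ₁))² · |FFT[P·ρ̃]|²,

where I₀ is the incident flux (photons µm⁻² s⁻¹, converted to SI), η the
detector efficiency, Δt the exposure, and a·σ₁ the array extent. Only
scattered photons are modelled; the unscattered direct beam would land in
the beamstop (missing centre) region, which is excluded from every
magnitude constraint anyway. This convention yields physically sensible
photon budgets (total counts ≈ flux × open aperture area in the
strong-scattering limit, via Parseval).

When the two pinholes carry different fluxes I_D and I_S (the
dose-reduction configuration), the pattern is the coherent sum

    I(k) = η·Δt·(r_e·λ/(a·σ₁))²·{ I_D|Ψ_D|² + I_S|Ψ_S|² + 2√(I_D·I_S)·Re(Ψ_D Ψ_S*) },

which reduces exactly to the single-flux expression when I_D = I_S — a
property enforced by the test suite.

Measurement realism: per-pixel Poisson noise; a (2h+1)² missing-centre
block (beamstop) marked invalid rather than zero; and motion blur —
each detector frame integrates the *intensities* of several sub-frames
of the evolving specimen, since dynamics blur intensity, not amplitude.

### Absorbed dose

Dose uses the standard fluence estimate D = F·(µ/ρ)·E with unit
conversions (photons µm⁻² → cm⁻², eV → J, J g⁻¹ → Gy). For average
protein at 530 eV, µ/ρ = 9.26×10³ cm² g⁻¹, giving 2.75×10³ Gy at
3.5×10⁴ photons µm⁻² and scaling linearly.

## 2. Time-invariant-constraint reconstruction (`insitu`)

Each sweep over the frame series maintains a single static-region object
S shared by all frames. At frame t the carried static estimate is
blended exponentially, S′ = γ·S + (1−γ)·S_t with γ = 0.8, combined with
the frame's dynamic estimate into O_t = S′ + D_t, propagated to the
detector, subjected to the Fourier-magnitude projection (invalid pixels
pass through), and updated by the probe-weighted rule

    O′ = O + |P|·P* / (α·(|P|² + ε)) · (ψ′ − ψ),    α = max|P|,

then split by the static/dynamic support masks. Convergence is monitored
by the normalised L1 Fourier discrepancy pooled over frames and valid
pixels,

    R = Σ ||Ψ_meas| − |Ψ_calc|| / Σ |Ψ_meas|.

Two numerical choices matter in practice:

* **Annealed real-space smoothing.** From random starts the plain
  iteration stagnates in local minima of the magnitude constraint (the
  same runs converge when started near the solution, so the fixed point
  is attracting but its basin is small). The solver therefore smooths the
  updated object with a Gaussian whose width anneals from σ₀ = 4 px to 0
  over the first 40 % of the iterations in two coarse-to-fine cycles
  ("frequency marching"): low frequencies lock in first, then detail.
  The final 60 % of iterations run the unmodified update, so the
  converged state satisfies the plain fixed-point equations.

* **Support masks from the pinholes.** The static/dynamic supports are
  the two pinhole discs dilated by 2 px (to absorb propagation fringes);
  pixels claimed by both after dilation are assigned to neither.

The model/results API mirrors statsmodels: `InSituCDI(frames, probe,
masks, count_scale, params).fit()` returns `InSituResults` with per-frame
objects, exit waves, the shared static estimate, the R trace, and
`summary()`.

## 3. Single-frame retrieval (`oss`)

The reference single-frame reconstructor combines HIO (β = 0.9) with a
Gaussian low-pass applied *outside* the support whose width α steps from
N down to N/10 across ten stages — tight high-frequency noise control at
late iterations while the support constraint does the work inside.
Best-of-N: several seeded random starts, keeping the run with the lowest
Fourier R-factor. A known static structure (complex values on a mask)
can be re-imposed every iteration.

**Twin breaking.** A centrosymmetric support (a single circular pinhole)
admits the conjugate-twin solution, and HIO-family iterations then
stagnate on truth/twin mixtures — measured here as a reconstruction
correlating strongly with both the object and its twin at high spatial
frequencies, with the stall persisting at 2000 iterations. The standard
remedy (Fienup & Wackerman, J. Opt. Soc. Am. A 3, 1897 (1986)) is applied:
during the first 15 % of iterations the support is truncated to its upper
65 % of rows, which is non-centrosymmetric and selects one twin. For the
dual-pinhole time series the package avoids the ambiguity at the source
by using *unequal* pinhole diameters (2.0 µm static, 2.4 µm dynamic),
making the support union non-centrosymmetric outright.

## 4. Quantitative evaluation (`metrics`)

Fourier ring correlation uses the conjugated, ring-restricted form
FRC(q) = Re Σ_q Ψ_a Ψ_b* / √(Σ_q|Ψ_a|²·Σ_q|Ψ_b|²); resolution is the
full period 1/f at the first crossing of the 1/e threshold that persists
for two rings of the median-smoothed curve (an isolated noisy dip does
not count). When the curve never crosses, the detector-edge resolution is
reported with a `crossed = False` flag — the reconstruction is then
faithful over the whole measured band.

Before scoring, reconstructions are registered to the truth over the
trivial ambiguities of far-field magnitudes — global phase, integer
translation, and the conjugate point reflection — which no algorithm can
recover from intensities and which would otherwise dominate the FRC.

## 5. Phantom generators and their realism

* **Dendrite time series** (8 keV study): seeded procedural growth —
  tips advance inward from the rim of the growth region with jittered
  headings, occasionally branching; deposits are rounded stamps with
  per-pixel thickness *non-decreasing in time* (growth only), capped at
  500 nm of Pb, immersed in 1 µm of water confined to the illuminated
  discs. Two realism controls matter:
  * *Slow-growth window.* The scene is evolved for `history_subframes`
    (300) sub-steps and only the final n_frames × subframes (50) are
    recorded. A specimen videoed at 100 Hz changes little between frames;
    compressing an entire growth into 5 frames would create ~70× too much
    per-frame change and put a large motion-blur floor under the
    R-factor. The per-frame scoring truth is the *mean* of the 10
    sub-frame densities — exactly the object an ideal reconstruction of
    the motion-blurred frame recovers.
  * *Imposed band limit.* The complex scattering density of each
    sub-frame is hard low-passed at 0.8 × Nyquist, so the finest full
    period present is exactly 2·px/0.8 = 50 nm at the desk scale. This
    gives the resolution claim a sharp, generator-independent reference.
    The limit is applied to the complex density, not the thickness maps,
    because a low-passed thickness can go (unphysically) negative.
* **Cell phantom** (530 eV study): an elongated organelle (rotated
  ellipse with dome profile) plus scattered cytosolic aggregates, protein
  thickness ≤ 1 µm, in a uniform 1 µm water slab. The water stays in the
  model: at 530 eV it scatters weakly per unit thickness but supplies a
  large share of the total signal, and removing it degrades every
  reconstruction.
* **Lacey gold web**: ridges of a smoothed Gaussian random field
  (quantile-thresholded, so the fill fraction is exact), 20 nm thick,
  confined to the static pinhole.

All generators are pure functions of (grid, parameters, seed).

## 6. The two end-to-end studies

### Dendrite time series (`FIG2_DESK_PRESET`)

512² grid, 20 nm pixels, pinholes 2.0/2.4 µm spaced 2.8 µm (σ₁ ≈ 2.05),
8 keV, flux 10¹¹ photons µm⁻² s⁻¹, η = 0.8, five 10 ms frames of 10 × 1 ms
sub-exposures, Poisson noise, 5×5 missing centre; 500 sweeps.

Why 20 nm pixels: the L1 R-factor has a Poisson noise floor dominated by
dim pixels (for expected counts λ ≪ 1 the per-pixel ratio
E||m|−|c||/|c| ≈ 1/√λ), and at finer sampling the floor rises above any
useful convergence threshold. At 20 nm pixels with this photon budget the
floor is ≈ 0.05, so a converged run is clearly distinguishable from a
stagnated one. Outcome at seed 1: final R = 0.0496 (at the noise floor),
FRC never crosses 1/e → resolution 40.0 nm = detector edge, within the
50 nm imposed band limit + 2 px bound. Seeds 2, 3, 7 reproduce this
(R = 0.048–0.050, 40.0 nm).

### Dose-reduction study (`FIG5_DESK_PRESET`)

550² grid at the same 10.6 nm pixel as the full-scale geometry (pitch
doubled to compensate the halved N), 530 eV, pinholes 1.5 µm spaced
2.0 µm. The specimen arm is reconstructed by OSS (300 iterations ×
5 runs) at each rung of the fluence ladder 3.5×10⁴…3.5×10⁷ photons µm⁻²,
(a) alone through a single pinhole, and (b) together with the lacey-gold
static structure illuminated at 1.4×10¹⁰ photons µm⁻², whose known
flux-weighted exit wave is enforced every iteration. In mode (b) the
retrieval operates on the flux-weighted object √I_D·O_D + √I_S·O_S, and
the specimen estimate is recovered by dividing out √I_D.

The fluence-reduction factor is computed discretely on the ladder: for
each with-static rung (f, r), the matching conventional fluence is the
smallest rung whose conventional resolution is ≤ r; if no rung reaches r,
the top rung stands in as a strict lower bound. No interpolation is used,
because single-frame retrieval does not improve monotonically with
fluence — the conventional arm of this strong-phase, complex-valued
specimen largely stagnates well above the noise floor at every rung,
which is precisely the instability the time-invariant static structure
removes.

## 7. Limitations

* Projection (thin-object) approximation; no multislice propagation.
* Kinematic scattering only; no direct beam, detector readout noise,
  dark current, or saturation.
* Optical constants are bundled point values at the two working energies,
  with approximate dispersion near the O K-edge; they affect simulation
  contrast only, not the dose/geometry arithmetic.
* The dendrite generator is a procedural stand-in with the stated growth
  statistics, not a measured growth movie; conclusions are about
  algorithm behaviour (convergence, resolution, constraint ablation),
  not about a specific specimen.
* The conventional (no-static) arm of the dose study is
  stagnation-limited rather than noise-limited; its resolutions are
  therefore conservative, and the reduction factor is reported as a
  lower bound when the conventional arm never matches the constrained
  resolution.
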