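# insitucdi

Simulation and reconstruction toolkit for **in situ coherent diffractive
imaging (CDI)**: dynamic imaging of a specimen in solution by combining a
time series of far-field diffraction patterns with a *time-invariant*
static region that scatters coherently alongside the specimen.

A dual-pinhole aperture illuminates two neighbouring regions: a **static**
region (empty solvent, a substrate, or a strongly scattering structure
known a priori) and a **dynamic** region containing the evolving specimen.
Because the static region's exit wave is the same in every frame, it acts
as a powerful real-space constraint: the reconstruction of the whole time
series shares one static estimate, which dramatically stabilises phase
retrieval per frame and — when the static side is bright — lets the
specimen be imaged at a small fraction of the fluence (and therefore
radiation dose) that conventional single-frame CDI needs.

The package provides:

| module        | contents |
|---------------|----------|
| `optics`      | energy/wavelength conversion, tabulated optical constants, dual-pinhole apertures, band-limited angular-spectrum propagation, geometry arithmetic (reconstruction pixel, detector-edge resolution, oversampling ratio) |
| `phantoms`    | seeded generators: growing dendrite time series, cell-like phantom, lacey gold web; thickness → complex transmission; hard band-limiting |
| `forward`     | exit wave → expected photon counts (kinematic scattering), two-region differential-flux model, Poisson noise, missing-centre masks, sub-frame motion blur |
| `insitu`      | the time-invariant-constraint reconstruction algorithm (`InSituCDI` model / `InSituResults`), R-factor |
| `oss`         | single-frame phase retrieval by oversampling smoothness (HIO + tightening Gaussian filter), best-of-N, optional a-priori static structure |
| `metrics`     | Fourier ring correlation, 1/e-threshold resolution, absorbed dose, registration over trivial ambiguities |
| `cli_io`      | HDF5/TIFF I/O, INI run configs, the `insitucdi` command-line tool |
| `experiments` | end-to-end presets: the 8 keV dendrite time-series study and the 530 eV dose-reduction study |

## Worked example: dendrite time series

Simulate a 512×512, 5-frame time series of a dendrite growing in water at
8 keV (flux 10¹¹ photons µm⁻² s⁻¹, 10 ms frames integrated from 10 × 1 ms
sub-exposures, Poisson noise, 5×5 missing centre), reconstruct it with the
time-invariant constraint, and score it against the known phantom:

```python
from insitucdi import experiments

exp = experiments.FIG2_DESK_PRESET          # 512**2, 20 nm pixels, sigma1 ~ 2
result, score, sim = experiments.dendrite_time_series(
    exp, seed=1, n_iterations=500
)
print(result.summary())
print(f"resolution {score.resolution * 1e9:.1f} nm "
      f"(band limit {exp.band_limit_full_period * 1e9:.0f} nm)")
```

Typical output (seed 1; takes ~3 minutes on one CPU):

```
In situ CDI reconstruction
============================================
frames                      5
grid                        512 x 512
pixel size                  20.000 nm
iterations                  500
gamma (static blend)        0.8
static constraint           on
initial R-factor            0.6638
final R-factor              0.0496
resolution 40.0 nm (band limit 50 nm)
```

The final R-factor 0.0496 sits at the Poisson noise floor of this photon
budget, and the 40.0 nm FRC-1/e resolution equals the detector edge (the
FRC never drops below 1/e), i.e. the reconstruction is faithful out to the
finest length scale present in the band-limited phantom. Running with
`share_static=False` on the same frames degrades the reconstruction
markedly — the static constraint is what makes the time series solvable.

The same pipeline is scriptable from the shell:

```bash
insitucdi simulate --preset fig2-desk --seed 1 --out runs/sim
insitucdi reconstruct --in runs/sim/frames.h5 --out runs/rec --iterations 500
insitucdi evaluate --truth runs/sim/truth_magnitude.tif \
                   --recon runs/rec/recon.h5 --out runs/eval \
                   --pixel-size 20e-9
insitucdi dose --fluence 3.5e4        # -> 2752 Gy
```

## Worked example: dose reduction

The soft-X-ray (530 eV) study reconstructs a cell-like phantom across a
fluence ladder of 3.5×10⁴ … 3.5×10⁷ photons µm⁻², with and without a
lacey-gold static structure illuminated at 1.4×10¹⁰ photons µm⁻² and
enforced a priori during retrieval:

```python
from insitucdi import experiments, oss

study = experiments.dose_reduction_study(
    experiments.FIG5_DESK_PRESET, seed=1,
    oss_params=oss.OssParams(n_iterations=300, n_runs=5, seed=1),
)
print(study.resolution_with_static)     # improves with fluence, ~21 nm at top
print(study.resolution_without_static)  # stagnates at >150 nm
print(study.reduction_factor)           # >= 10
```

With the bright static structure the specimen resolution reaches the
detector edge (≈21 nm full period) already at moderate fluence, while
conventional single-pinhole retrieval of the same complex-valued specimen
stalls far above it at every rung of the ladder; the fluence needed to
match a given resolution drops by at least an order of magnitude. Absorbed
dose scales linearly with fluence (2.75×10³ Gy at the bottom rung,
2.75×10⁶ Gy at the top for average protein at 530 eV).

## Reproduction

All stochastic paths are seeded and deterministic. To regenerate every
quantitative result from scratch (about 15 minutes on one CPU):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The test suite, including the two end-to-end studies:

```bash
python -m pytest -q
```

See `docs/methods.md` for the physical model, parameter choices, and
numerical details.
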