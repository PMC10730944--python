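# icefield

Simulation of cryo-EM images of biological samples embedded in amorphous
ice, with two interchangeable models of the ice:

* an **atomistic model** — explicit water-molecule coordinates, rasterised
  into projected-potential slices atom by atom (a synthetic, seeded
  stand-in for molecular-dynamics water boxes); and
* a **statistical model** — each slice of ice is a Gaussian random field
  (GRF) with a prescribed mean, variance, and power spectrum, generated in
  milliseconds regardless of how many water molecules it represents.

The package exists because explicit water does not scale: a typical
cryo-electron-tomography sample (a 400 × 400 × 150 nm lamella of
low-density amorphous ice, LDA, ~0.94 g/cm³) contains over 750 million
water molecules.  The GRF model replaces all of them with three
statistical constants and a two-Gaussian spectrum, and `icefield`
includes the full validation machinery — exit-wave moments, radial power
spectra, contrast-to-noise ratios, Fourier shell correlation, weighted
back projection, Kolmogorov–Smirnov tests — needed to demonstrate that
images and tomograms simulated with the two models are statistically
indistinguishable.

## The model

Images are formed with the multislice algorithm: the specimen potential is
cut into slices of thickness Δz (default 5 Å) along the beam, and the
electron wavefunction ψₙ is alternately transmitted and propagated,

    tₙ(x,y) = exp(i σ ∫ V dz),      Pₙ(k) = exp(−i π λ k² Δz),
    ψₙ₊₁ = F⁻¹{ Pₙ · F[ tₙ ψₙ ] },

followed by a contrast transfer function (defocus + spherical aberration,
Gaussian coherence envelopes) and Poisson detection at a stated dose.

Each GRF ice slice containing N water molecules per Å² has

* mean potential  V₀ = N κ (fe_O(0) + 2 fe_H(0)) ≈ 145.59 N  (eV·Å), with
  κ = 2πℏ²/(mₑq) = 47.88 V·Å² and fe the electron scattering factors;
* variance  σ_N² = σ₀² N  with the fitted constant σ₀² = 10 195.82;
* power spectrum  P(q) = a₁ e^(−q²/2s₁²) + a₂ e^(−(q−m)²/2s₂²), peaked at
  m = 1/2.88 Å⁻¹, the reciprocal of the mean O–O distance in LDA ice
  (a₁ = 0.199, s₁ = 0.731, a₂ = 0.801, s₂ = 0.081).

Fields are synthesised with √P amplitudes and uniform random phases
(without Hermitian symmetry, so one FFT yields two independent slices),
normalised to calibrated targets, masked to the sample shape (cuboids,
slabs, cylinders, or spline-deformed "natural" cylinders), and added
wherever the macromolecular potential is below V₀/3.  A packaged
calibration table corrects the targets for the pixel-size-dependent
difference between analytic and rasterised water statistics; see
`docs/methods.md`.

## Worked example

```python
import numpy as np
from icefield import grf, multislice as ms, physics, sample, stats, tomo

beam = physics.BeamParameters.from_energy(300.0)

# a 100x100x50 A synthetic water box and its GRF twin at 0.5 A pixels
box = sample.WaterBoxSpec(box=(100.0, 100.0, 50.0), density=0.94, seed=1)
atoms = sample.generate_water_box(box)
vol = tomo.build_potential_volume(atoms, 0.5, (200, 200), 50.0, 5.0, wrap=True)
wave_atom = ms.exit_wave(vol, beam)

n_per_area = sample.water_number_density(0.94) * 5.0
rng = np.random.default_rng(2)
slices = []
for _ in range(5):
    pair = grf.synthesize_grf_pair(grf.IceSliceSpec(n_per_area, 0.5, (200, 200)), rng=rng)
    slices.extend(pair)
wave_grf = ms.exit_wave(ms.PotentialVolume(slices, 0.5, 5.0), beam)
```

prints (via `stats.field_moments` on each wave):

```
300 keV beam: wavelength 0.019687 A, interaction parameter 6.5262e-04 rad/(V*A)
mean ice potential coefficient: 145.60 eV*A per (molecule/A^2)
GRF correlation length: 0.421 A
water box: 15711 molecules, density 0.940 g/cm^3
atomistic exit wave: Re 0.9865 +- 0.0155, Im 0.1478 +- 0.0592
      GRF exit wave: Re 0.9870 +- 0.0158, Im 0.1484 +- 0.0596
```

The two exit waves carry the same means and standard deviations in both
components to well under a percent — the ice is statistically the same,
but the GRF stack took a few FFTs instead of rasterising 47 000 atoms.
The imaginary mean of ~0.148 is the accumulated mean phase
σ·V₀·(areal density of the 50 Å stack); the standard deviations are the
ice "noise" that gives real micrographs their texture.

## Command line

```
icefield simulate-image --config run.yaml --seed 3 --output image.mrc
icefield simulate-tilt  --config run.yaml --output series.mrc     # + series.rawtlt
icefield reconstruct    --tilt series.mrc --angles series.rawtlt --defocus -25000
icefield calibrate-ice  --pixel-sizes 0.1:1.0:10 --seed 0
icefield compare-stats  a.mrc b.mrc --report cmp.json
```

Configuration is YAML (beam energy, pixel size, slice thickness, defocus,
dose, sample shape and ice model, tilt scheme, master seed); unknown keys
are rejected.  Images and volumes are MRC; every command is bit-reproducible
for a fixed seed.

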