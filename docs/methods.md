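# Methods

This note records the models implemented in `icefield`, the assumptions
behind them, the calibration procedure that couples the statistical ice
model to the atomistic one, and the numerical choices a user should know
about before trusting or extending the package.

## Electron optics and atomic potentials

Beam constants are relativistic throughout: the wavelength is
λ = hc/√(E(E+2mc²)) and the interaction parameter
σ = 2π m_rel q λ/h², in rad·V⁻¹·Å⁻¹ so that σ·(projected potential in
V·Å) is a phase in radians.  There is no non-relativistic mode.

Electron scattering factors use the five-Gaussian parameterisation of
International Tables for Crystallography Vol. C, Table 4.3.2.2, shipped
as a plain-text table (`data/electron_form_factors.tsv`, generated from
gemmi 0.7.4 and cross-checked against it in the test suite).  With
κ = 2πℏ²/(mₑq) = 47.8776 V·Å², the forward factors give

    κ (fe_O(0) + 2 fe_H(0)) = 47.8776 × 3.041 = 145.596 eV·Å

per water molecule per unit area — the coefficient of the mean inner
potential of amorphous ice used everywhere in the package.  A practical
advantage of the Gaussian parameterisation is that the single-atom
projected potential is an analytic sum of Gaussians, finite at r = 0, so
rasterisation needs no singularity handling.

Atoms are rasterised through a fine radial lookup table (4096 points,
linear interpolation) truncated at 3 Å, evaluated on a 2× supersampled
grid and area-averaged down.  The supersampling is deliberate
anti-aliasing: point sampling folds the single-atom potential's
above-Nyquist power back into the band and measurably inflates the
high-frequency content (and hence the propagation-induced amplitude
contrast) of atomistic water stacks.  The plane integral of a rasterised
single atom reproduces κ·fe(0) to better than 1% at 0.05 Å sampling
(zero-frequency identity, tested).

## The synthetic water generator

The gold-standard ice is emulated, not simulated: molecules are placed by
seeded batched rejection sampling with a periodic minimum-image exclusion
distance, then decorated with two hydrogens at the rigid three-site
geometry (O–H 0.9572 Å, H–O–H 104.52°) in a seeded random orientation
("point" mode, with hydrogens co-located on the oxygen, exists for
variance oracles).  The molecule count is exactly
round(ρ·V·N_A/Mr), so density round-trips by construction.

The default exclusion distance is 2.65 Å, chosen so that the generated
structure emulates low-density amorphous ice in the two respects that
matter for image statistics: the mean nearest-neighbour O–O spacing
comes out at ~2.8 Å (LDA: 2.88 Å; hard-core rejection sampling jams
before reaching it exactly), and the structure-factor maximum — hence the
peak of the slice-potential power spectrum — falls at 1/2.88 Å⁻¹, where
the fitted GRF spectrum peaks.  What the generator does **not** emulate:
the hydrogen-bond network, the detailed radial distribution function of
simulated water (its first peak is at contact rather than at 2.8 Å, and
its compressibility, S(0) ≈ 0.25, is higher than real water's ≈ 0.06),
orientational correlations, and ions.  Passing equivalence tests
therefore show that the GRF matches *this* gold standard under the
multislice map; they are evidence about the method, not about any
specific molecular-dynamics force field.

## The GRF ice model and its calibration

Each ice slice with N molecules/Å² is a stationary Gaussian random field
with mean 145.59·N eV·Å, variance σ₀²·N with σ₀² = 10 195.82, and the
two-Gaussian spectrum peaked at m = 1/2.88 Å⁻¹ (a₁ = 0.199, s₁ = 0.731,
a₂ = 0.801, s₂ = 0.081; dimensionless weights sum to 1, widths in
cycles/Å).  The spectrum is shape-only: synthesis assigns √P(|q|)
amplitudes with uniformly random phases, takes one inverse FFT, and
affinely normalises each of the real and imaginary parts — two
independent fields per transform — to the corrected target moments.
Slices are mutually independent, justified by the model's correlation
length: the 1/e lag of the autocorrelation (the isotropic 2D inverse
transform of P) evaluates to 0.42 Å, far below the 3–5 Å slice
thicknesses in use.  Synthesis is restricted to the engine's frequency
band (2/3 Nyquist, below).

Masking: fields are cut to a sample shape (cuboid, slab, cylinder, or a
"natural" cylinder whose axis offset and radius vary along the tilt axis
as cubic splines in the centred axial coordinate), and added only at
pixels where the macromolecular potential is below one third of the
slice's mean ice potential (V₀/3, strict inequality, so a zero threshold
adds nothing to a non-negative slice).

### Correction table

The analytic targets assume ideal continuous fields; the engine works
with truncated, interpolated, band-limited, finitely-sampled ones.  A
packaged table (`data/grf_correction_table.tsv`, regenerable with
`icefield calibrate-ice`, generating seed recorded in its header) stores
the ratio observed/analytic for the mean and the variance as a function
of pixel area, interpolated linearly in area and clamped at both ends.
Calibration rasterises seeded three-slice water stacks (80 × 80 Å in xy,
periodic, hydrogens folded at the z faces), band-limits them exactly as
the engine does, and normalises by the realised molecule count, so the
ratios measure transfer loss rather than Poisson count fluctuations.
Monte-Carlo jitter is cleaned up isotonically (ratios non-increasing in
pixel area; the mean column additionally clamped to ≤ 1).

Two deliberate properties of this calibration differ from a naive
per-slice reading:

* **The variance ratio is measured on the accumulated stack**,
  var(Σ slices)/n, not on single slices.  Rasterised water slices are
  negatively correlated across slice boundaries (excluded volume: a
  molecule near a boundary depletes its neighbourhood on the other
  side), by about −3.6% in var(sum)/Σvar at Δz = 5 Å.  A
  slice-independent GRF cannot represent that covariance, so it is
  folded into the effective per-slice variance; the GRF then reproduces
  the accumulated-phase statistics the multislice engine actually sees,
  at the cost of sitting ~3.5% below the water's true single-slice
  variance.
* **The variance ratio may exceed 1 at very fine pixels.**  The fitted
  σ₀² = 10 195.82 is an empirical constant for a relaxed water model;
  the synthetic generator's fine-pixel in-band variance is a few percent
  above it, and the table stores the honest ratio rather than clamping.

The Campbell-theorem oracle puts this in context: for independently
placed point molecules the pointwise variance per unit areal density is
∬V_mol² d²r = 20 583 (eV·Å)² (0.05 Å grid, matching the closed-form
Fourier integral to 0.5%); rigid three-site geometry with
orientation-averaged cross terms gives 13 458, fully incoherent atoms
11 443, and short-range exclusion reduces the realised value further.
The fitted 10 195.82 is therefore *not* the point-molecule Campbell
integral (it is a factor ~2 smaller) and is treated as an empirical
constant of the original model fit, reported alongside the oracle rather
than asserted against it.

## Multislice engine

Transmission is a pure phase factor; propagation multiplies by
exp(−iπλk²Δz) in Fourier space; the exit plane is the far face of the
last slice.  Both the transmission function and the propagator are
band-limited to 2/3 of Nyquist — standard multislice anti-aliasing —
which also defines the band within which ice statistics are calibrated
and compared.  Strict intensity conservation (1e−8 relative) holds with
the band limit disabled; with it enabled, the removed corner band
carries away a small amount of power by design.

The objective lens applies χ(k) = πλΔf·k² + (π/2)Csλ³k⁴ with negative
defocus meaning underfocus (first zero of the pure-defocus transfer
function at k = √(1/λ|Δf|)), one Gaussian focal-spread envelope
(parameter in Å) and one Gaussian source-spread envelope (parameter in
rad, acting on the aberration displacement Δf·k + Csλ²k³), plus an
optional hard objective aperture.  Amplitude contrast arises only from
the aperture; there is no absorptive potential and no thermal smearing
(a no-op hook would slot into the scattering table).  The detector is an
ideal Poisson counter: mean counts = intensity × dose × pixel area
(2.5 e⁻/Å² on 1.34 Å pixels gives the bookkeeping value 4.49 e⁻/pixel);
no MTF/DQE.

## Tomography

The tilt axis is +y (right-handed positive angles).  Atomistic samples
are rigidly rotated and re-rasterised per angle; GRF ice is regenerated
per image, with the shape mask rotated instead — the model's on-the-fly
property.  CTF correction is per-image phase flipping (multiplication of
image Fourier coefficients by sign(CTF); zero bins pass unchanged); the
full 3D-varying-defocus correction is intentionally out of scope, which
is acceptable for model comparisons because both ice models pass through
the identical pipeline.  Weighted back projection ramp-filters each image
along x and back-projects with bilinear interpolation; the volume voxel
size equals the image pixel size and nz = nx (the zero-tilt field of
view).  By default the per-image mean is removed first (bright-field
images have background 1, and the sharp field edge otherwise leaves a
bowl artefact); phantom-fidelity tests use raw projections.  An
independent-implementation cross-check against `skimage.transform.iradon`
on a shared sinogram is part of the test suite.

### What equivalence means at reconstruction level

Without detector noise, reconstructions from the two ice models are
*not* statistically identical: each GRF projection carries fresh ice
noise which averages away under back projection, while rigid atomistic
water reconstructs its coherent 3D texture (interior voxel std ~40%
apart at 64³, 60 projections).  At a realistic per-image dose
(2.5 e⁻/Å²), shot noise dominates both and the voxel-value histograms
become indistinguishable (two-sample KS D ≈ 0.002 at 64³).  The
equivalence claim is therefore dose-contextual, and the package's
reconstruction comparison is run at experimental dose.

## Reproducibility and seeds

Every stochastic path (water placement, molecule orientations, GRF
phases, detector noise) draws from an explicitly passed seed or
generator; the CLI derives named substreams (water-box, grf-slices,
detector-j) from one master seed via hashed SeedSequence keys, so
partial pipelines are independently reproducible and every command is
bit-reproducible for a fixed seed.

## Problem sizes

The validation experiments in the test suite run at desk scale, chosen
to keep the full suite in a few minutes on one CPU: the exit-wave
equivalence uses three independent 200 × 200 × 100 Å boxes at 0.5 Å
pixels (≈ 1.26 × 10⁵ molecules each) with moments compared between
3-realisation ensembles, and spectra compared on slice potentials with
0.04 Å⁻¹ bins (half the fitted peak width s₂ — finer localisation of a
peak of width 0.081 is not statistically meaningful; exit-wave spectra
additionally carry a multiple-scattering pedestal that biases broad peak
maxima low).  The tomographic comparison uses a 64³ Å cylinder over
±90° in 3° steps.  Large-volume geometry (the 750-million-molecule
lamella) enters through molecule-count bookkeeping and shape masking,
not through atomistic rasterisation.

## Known limitations

* The water generator reproduces density and pair-exclusion structure,
  not true water structure (see above); σ₀² and the spectrum parameters
  are constants of the original fit, not re-fitted to this generator.
* Inelastic scattering, beam-induced motion, dose-dependent ice
  evolution, detector MTF/DQE, higher-order aberrations, and
  frozen-phonon sampling are all out of scope.
* Phase flipping with the nominal per-image defocus ignores the defocus
  gradient across thick samples.
* The GRF model cannot represent cross-slice covariance or rotationally
  consistent ice; both are calibrated around (accumulated-variance
  target; dose-dominated comparisons) rather than modelled.
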