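"""Multislice exit-wave computation and image formation.

The specimen potential is divided into slices of thickness dz along the
beam (+z).  Each slice acts as a thin phase object: the wave is
multiplied by t(x,y) = exp(i sigma Vproj(x,y)) and then Fresnel-propagated
to the next slice by multiplying with P(k) = exp(-i pi lambda k^2 dz) in
Fourier space.  Both the transmission function and the propagator are
band-limited to 2/3 of the Nyquist frequency to prevent aliased
wrap-around.  The exit plane is the far face of the last slice.

The objective lens applies a phase-shift chi(k) from defocus and
spherical aberration, damped by Gaussian partial-coherence envelopes,
and the detector draws Poisson counts with mean intensity*dose*pixel
area.  Negative defocus means underfocus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grf import BAND_LIMIT_FRACTION
from .physics import BeamParameters

__all__ = [
    "PotentialVolume",
    "Wavefield",
    "OpticsConfig",
    "DetectorConfig",
    "transmission_function",
    "fresnel_propagate",
    "exit_wave",
    "apply_ctf",
    "ctf_1d",
    "detect",
]


@dataclass
class PotentialVolume:
    """Ordered stack of projected-potential slices (V·Å), beam along +z."""

    slices: list
    pixel_size: float
    slice_thickness: float = 5.0
    z0: float = 0.0

    def __post_init__(self):
        if self.slice_thickness <= 0:
            raise ValueError("slice thickness must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        shapes = {np.shape(s) for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices are not congruent: {shapes}")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return np.shape(self.slices[0])


@dataclass
class Wavefield:
    """Complex 2D wavefunction with its sampling and wavelength metadata."""

    psi: np.ndarray
    pixel_size: float
    wavelength: float

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=complex)
        if not np.all(np.isfinite(self.psi)):
            raise ValueError("wavefield contains non-finite values")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.psi) ** 2


@dataclass(frozen=True)
class OpticsConfig:
    """Objective-lens model: defocus (Å, negative = underfocus), Cs (mm),
    optional objective aperture (cycles/Å), and Gaussian coherence
    envelopes (focal spread in Å; source spread as an angle in rad)."""

    defocus: float = 0.0
    cs_mm: float = 0.0
    aperture: float | None = None
    focal_spread: float = 0.0
    source_spread: float = 0.0

    def __post_init__(self):
        if self.focal_spread < 0 or self.source_spread < 0:
            raise ValueError("envelope parameters must be non-negative")


@dataclass(frozen=True)
class DetectorConfig:
    """Idealised counting detector: dose in e⁻/Å² and a noise seed."""

    dose: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


def _freq_grids(shape: tuple[int, int], pixel_size: float):
    ky = np.fft.fftfreq(shape[0], pixel_size)
    kx = np.fft.fftfreq(shape[1], pixel_size)
    return ky[:, None], kx[None, :]


def _band_mask(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    ky, kx = _freq_grids(shape, pixel_size)
    return np.hypot(ky, kx) <= BAND_LIMIT_FRACTION / (2.0 * pixel_size)


def transmission_function(slice_potential: np.ndarray, sigma: float) -> np.ndarray:
    """Pure phase object t = exp(i sigma Vproj); |t| = 1 everywhere."""
    return np.exp(1j * sigma * np.asarray(slice_potential, dtype=float))


def fresnel_propagate(wave: Wavefield, dz: float, band_limit: bool = True) -> Wavefield:
    """Free-space (paraxial) propagation over dz >= 0.

    Multiplies by exp(-i pi lambda k^2 dz) in Fourier space; conserves
    total intensity (unitary apart from the optional band limit).
    """
    if dz < 0:
        raise ValueError("propagation distance must be non-negative")
    ky, kx = _freq_grids(wave.psi.shape, wave.pixel_size)
    k2 = ky**2 + kx**2
    prop = np.exp(-1j * np.pi * wave.wavelength * k2 * dz)
    if band_limit:
        prop = prop * _band_mask(wave.psi.shape, wave.pixel_size)
    psi = np.fft.ifft2(prop * np.fft.fft2(wave.psi))
    return Wavefield(psi, wave.pixel_size, wave.wavelength)


def exit_wave(
    volume: PotentialVolume,
    beam: BeamParameters,
    band_limit: bool = True,
) -> Wavefield:
    """Propagate a unit plane wave through all slices.

    Alternates transmission and Fresnel propagation; the final
    propagation carries the wave to the exit plane of the last slice.
    """
    if len(volume) == 0:
        raise ValueError("potential volume has no slices")
    ny, nx = volume.shape
    psi = np.ones((ny, nx), dtype=complex)
    ky, kx = _freq_grids((ny, nx), volume.pixel_size)
    k2 = ky**2 + kx**2
    prop = np.exp(-1j * np.pi * beam.wavelength * k2 * volume.slice_thickness)
    mask = _band_mask((ny, nx), volume.pixel_size) if band_limit else 1.0
    prop = prop * mask
    for s in volume.slices:
        t = transmission_function(s, beam.sigma)
        if band_limit:
            t = np.fft.ifft2(mask * np.fft.fft2(t))
        psi = np.fft.ifft2(prop * np.fft.fft2(t * psi))
    return Wavefield(psi, volume.pixel_size, beam.wavelength)


def aberration_phase(k2: np.ndarray, wavelength: float, optics: OpticsConfig) -> np.ndarray:
    """chi(k) = pi lambda df k^2 + (pi/2) Cs lambda^3 k^4 (radians)."""
    cs_A = optics.cs_mm * 1e7
    return np.pi * wavelength * optics.defocus * k2 + 0.5 * np.pi * cs_A * wavelength**3 * k2**2


def coherence_envelope(k2: np.ndarray, wavelength: float, optics: OpticsConfig) -> np.ndarray:
    """Gaussian temporal (focal-spread) and spatial (source-spread) envelopes."""
    env = np.ones_like(k2)
    if optics.focal_spread > 0:
        env = env * np.exp(-0.5 * (np.pi * wavelength * optics.focal_spread * k2) ** 2)
    if optics.source_spread > 0:
        cs_A = optics.cs_mm * 1e7
        # image displacement per unit source tilt: df*k + Cs*lambda^2*k^3
        disp = optics.defocus * np.sqrt(k2) + cs_A * wavelength**2 * k2**1.5
        env = env * np.exp(-0.5 * (np.pi * optics.source_spread * disp) ** 2)
    return env


def apply_ctf(wave: Wavefield, optics: OpticsConfig) -> np.ndarray:
    """Image intensity |psi_image|^2 after the objective lens.

    The exit wave is multiplied in Fourier space by
    A(k) E(k) exp(-i chi(k)) and squared in real space.  With zero
    aberrations and no envelopes/aperture the intensity equals
    |psi_exit|^2 exactly.
    """
    ky, kx = _freq_grids(wave.psi.shape, wave.pixel_size)
    k2 = ky**2 + kx**2
    h = coherence_envelope(k2, wave.wavelength, optics) * np.exp(
        -1j * aberration_phase(k2, wave.wavelength, optics)
    )
    if optics.aperture is not None:
        h = h * (np.sqrt(k2) <= optics.aperture)
    psi_img = np.fft.ifft2(h * np.fft.fft2(wave.psi))
    return np.abs(psi_img) ** 2


def ctf_1d(k, wavelength: float, optics: OpticsConfig) -> np.ndarray:
    """Phase-contrast transfer function sin(chi) * envelopes at |k|.

    For pure defocus the first zero sits at k = sqrt(1/(lambda |df|)).
    """
    k = np.asarray(k, dtype=float)
    k2 = k**2
    return np.sin(aberration_phase(k2, wavelength, optics)) * coherence_envelope(
        k2, wavelength, optics
    )


def detect(
    intensity: np.ndarray,
    pixel_size: float,
    det: DetectorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Poisson counting image with per-pixel mean intensity*dose*pixel area."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    if rng is None:
        rng = np.random.default_rng(det.seed)
    mean = intensity * det.dose * pixel_size**2
    return rng.poisson(mean).astype(np.int64)
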