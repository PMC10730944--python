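"""Statistical comparison toolkit: moments, power spectra, CNR, FSC, KS.

These are the quantities used to demonstrate that images simulated with
the atomistic and the GRF ice models are statistically interchangeable:
exit-wave component moments, radially averaged power spectra, the
contrast-to-noise ratio of particles against an ice background, Fourier
shell correlation between reconstructions and reference maps, and the
two-sample Kolmogorov–Smirnov test on voxel-value distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "FieldMoments",
    "RadialProfile",
    "FSCCurve",
    "field_moments",
    "radial_power_spectrum",
    "spectrum_peak",
    "cnr",
    "fsc_curve",
    "fsc_average",
    "ks_two_sample",
    "gaussian_lowpass",
]


@dataclass(frozen=True)
class FieldMoments:
    mean_real: float
    mean_imag: float
    std_real: float
    std_imag: float


def field_moments(field: np.ndarray, mask: np.ndarray | None = None) -> FieldMoments:
    """Sample moments of the real and imaginary parts over masked pixels."""
    field = np.asarray(field)
    if mask is None:
        vals = field.ravel()
    else:
        vals = field[np.asarray(mask, bool)]
    if vals.size < 2:
        raise ValueError("mask must select at least two pixels")
    return FieldMoments(
        float(vals.real.mean()),
        float(vals.imag.mean()) if np.iscomplexobj(vals) else 0.0,
        float(vals.real.std()),
        float(vals.imag.std()) if np.iscomplexobj(vals) else 0.0,
    )


@dataclass
class RadialProfile:
    """Azimuthally averaged power per frequency bin (contiguous, 0..Nyquist)."""

    centers: np.ndarray
    power: np.ndarray
    counts: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.centers[1] - self.centers[0])


def radial_power_spectrum(
    field: np.ndarray,
    pixel_size: float,
    n_bins: int | None = None,
    subtract_mean: bool = True,
) -> RadialProfile:
    """|FFT|² of a 2D field, azimuthally averaged into equal-width bins.

    Power is normalised so that the sum over all Fourier pixels equals
    the field variance times the pixel count (Parseval with the DC term
    removed when ``subtract_mean``).
    """
    field = np.asarray(field)
    if field.ndim != 2:
        raise ValueError("field must be 2D")
    ny, nx = field.shape
    if n_bins is None:
        n_bins = min(ny, nx) // 2
    work = field - field.mean() if subtract_mean else field
    power = np.abs(np.fft.fft2(work)) ** 2 / (ny * nx)
    q = np.hypot(
        np.fft.fftfreq(ny, pixel_size)[:, None], np.fft.fftfreq(nx, pixel_size)[None, :]
    )
    nyquist = 1.0 / (2.0 * pixel_size)
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    # corner coefficients (|q| between Nyquist and sqrt(2)*Nyquist) are
    # folded into the top bin so that total power is conserved (Parseval)
    idx = np.clip(np.digitize(q.ravel(), edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=power.ravel(), minlength=n_bins)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialProfile(centers, sums / np.maximum(counts, 1), counts)


def spectrum_peak(profile: RadialProfile, exclude_dc: bool = True) -> float:
    """Peak frequency of a radial profile, parabolically interpolated.

    The DC bin is excluded from the search; a parabola through the three
    bins around the maximum refines the location to sub-bin precision.
    """
    start = 1 if exclude_dc else 0
    p = profile.power
    i = int(np.argmax(p[start:])) + start
    if 0 < i < len(p) - 1:
        denom = p[i - 1] - 2.0 * p[i] + p[i + 1]
        if denom != 0:
            delta = 0.5 * (p[i - 1] - p[i + 1]) / denom
            return float(profile.centers[i] + np.clip(delta, -0.5, 0.5) * profile.bin_width)
    return float(profile.centers[i])


def cnr(image: np.ndarray, signal_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio.

    CNR = sqrt( (1/N) sum_i (s_i - mu_B)^2 ) / sigma_B over the N signal
    pixels, with mu_B, sigma_B the background mean and (population)
    standard deviation.
    """
    image = np.asarray(image, dtype=float)
    s = image[np.asarray(signal_mask, bool)]
    b = image[np.asarray(background_mask, bool)]
    if s.size == 0 or b.size == 0:
        raise ValueError("signal and background masks must be non-empty")
    sigma_b = b.std()
    if sigma_b == 0:
        raise ZeroDivisionError("background has zero standard deviation")
    return float(np.sqrt(np.mean((s - b.mean()) ** 2)) / sigma_b)


@dataclass
class FSCCurve:
    """Per-shell Fourier correlation with shell populations."""

    centers: np.ndarray
    fsc: np.ndarray
    counts: np.ndarray


def fsc_curve(vol_a: np.ndarray, vol_b: np.ndarray, n_shells: int | None = None,
              voxel_size: float = 1.0) -> FSCCurve:
    """Fourier shell correlation between two congruent volumes.

    Uses the real-input FFT so conjugate-symmetric halves are not double
    counted; shells are equal width in |k| with DC assigned to shell 1.
    """
    vol_a = np.asarray(vol_a, dtype=float)
    vol_b = np.asarray(vol_b, dtype=float)
    if vol_a.shape != vol_b.shape:
        raise ValueError("volumes must be congruent")
    n = min(vol_a.shape)
    if n_shells is None:
        n_shells = n // 2
    fa = np.fft.rfftn(vol_a)
    fb = np.fft.rfftn(vol_b)
    freqs = [np.fft.fftfreq(s, voxel_size) for s in vol_a.shape[:-1]]
    freqs.append(np.fft.rfftfreq(vol_a.shape[-1], voxel_size))
    grids = np.meshgrid(*freqs, indexing="ij")
    q = np.sqrt(sum(g**2 for g in grids))
    nyquist = 1.0 / (2.0 * voxel_size)
    edges = np.linspace(0.0, nyquist, n_shells + 1)
    idx = np.clip(np.digitize(q.ravel(), edges) - 1, 0, n_shells - 1)
    keep = q.ravel() <= nyquist
    idx = idx[keep]
    cross = np.bincount(idx, weights=(fa * np.conj(fb)).real.ravel()[keep], minlength=n_shells)
    pa = np.bincount(idx, weights=(np.abs(fa) ** 2).ravel()[keep], minlength=n_shells)
    pb = np.bincount(idx, weights=(np.abs(fb) ** 2).ravel()[keep], minlength=n_shells)
    counts = np.bincount(idx, minlength=n_shells)
    denom = np.sqrt(pa * pb)
    fsc = np.divide(cross, denom, out=np.ones_like(cross), where=denom > 0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return FSCCurve(centers, np.clip(fsc, -1.0, 1.0), counts)


def fsc_average(curve: FSCCurve, max_frequency: float | None = None) -> float:
    """Shell-population-weighted mean of the FSC:
    sum_i N_i FSC_i / sum_i N_i, optionally restricted to shells below a
    frequency cutoff (e.g. the reciprocal of a stated resolution)."""
    sel = np.ones(len(curve.fsc), dtype=bool)
    if max_frequency is not None:
        sel = curve.centers <= max_frequency
    n = curve.counts[sel]
    if n.sum() == 0:
        raise ValueError("no shells below the requested frequency")
    return float(np.sum(n * curve.fsc[sel]) / np.sum(n))


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value."""
    a = np.ravel(np.asarray(sample_a, dtype=float))
    b = np.ravel(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sp_stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def gaussian_lowpass(image: np.ndarray, pixel_size: float, cutoff: float) -> np.ndarray:
    """Gaussian frequency-domain low-pass filter.

    ``cutoff`` is the 1/e half width in cycles/Å.  (One plausible reading
    of a "low-pass filter width"; exposed as a utility, not a claim about
    any particular convention.)
    """
    image = np.asarray(image, dtype=float)
    q2 = (
        np.fft.fftfreq(image.shape[0], pixel_size)[:, None] ** 2
        + np.fft.fftfreq(image.shape[1], pixel_size)[None, :] ** 2
    )
    return np.fft.ifft2(np.fft.fft2(image) * np.exp(-q2 / cutoff**2)).real
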