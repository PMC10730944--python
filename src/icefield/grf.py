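"""Statistical (Gaussian-random-field) model of amorphous ice.

Instead of rasterising hundreds of millions of water molecules, each
multislice slice of ice is modelled as a stationary Gaussian random field
with a prescribed mean, variance, and power spectrum:

* mean potential: V0 = N * kappa * (fe_O(0) + 2 fe_H(0)) ≈ 145.59 N
  (eV·Å, with N the molecular areal density per slice);
* variance: sigma_N^2 = sigma_0^2 * N, with the fitted constant
  sigma_0^2 = 10195.82 (eV·Å)^2 per (molecule·Å⁻²);
* power-spectrum shape: a two-Gaussian model
  P(q) = a1 exp(-q^2/(2 s1^2)) + a2 exp(-(q-m)^2/(2 s2^2)),
  with the second Gaussian peaked at m = 1/2.88 Å⁻¹, the reciprocal of
  the mean O–O distance in low-density amorphous ice.

Because the engine rasterises atoms with a truncated, interpolated,
band-limited potential, the observed mean and variance of a rasterised
water slice differ from the analytic targets in a pixel-size-dependent
way.  A calibration table of mean/variance ratios (observed/analytic),
indexed by pixel area, corrects the GRF targets so that GRF slices are
statistically interchangeable with rasterised atomistic slices.

Fields are synthesised in Fourier space with sqrt(P) amplitudes and
uniform random phases *without* Hermitian symmetry, so the real and
imaginary parts of the inverse transform are two independent GRFs — one
synthesis serves two slices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.integrate import quad
from scipy.special import j0

from . import physics
from .constants import KAPPA_V_A2

__all__ = [
    "GRFIceParams",
    "CorrectionTable",
    "IceSliceSpec",
    "power_spectrum_model",
    "correlation_length",
    "expected_moments",
    "calibrate_correction_table",
    "synthesize_grf_pair",
    "apply_ice_to_slice",
    "campbell_variance_coefficient",
    "default_correction_table",
]

#: Fraction of the Nyquist frequency retained by the multislice engine;
#: GRF synthesis and calibration use the same band so that atomistic and
#: GRF slices carry the same in-band statistics.
BAND_LIMIT_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class GRFIceParams:
    """Statistical constants of the continuum ice model.

    Defaults are the fitted values for low-density amorphous ice
    (power-spectrum weights/widths in cycles/Å, variance coefficient in
    (eV·Å)² per molecule·Å⁻², mean coefficient in eV·Å per molecule·Å⁻²).
    """

    a1: float = 0.199
    s1: float = 0.731
    a2: float = 0.801
    s2: float = 0.081
    m: float = 1.0 / 2.88
    sigma0_sq: float = 10195.82
    v0_coeff: float = 145.59
    threshold_fraction: float = 1.0 / 3.0

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("spectrum weights must be non-negative")
        if min(self.s1, self.s2, self.m) <= 0:
            raise ValueError("spectrum widths and peak frequency must be positive")


def power_spectrum_model(q, params: GRFIceParams | None = None):
    """Two-Gaussian power-spectrum shape P(q); q in cycles/Å, q >= 0."""
    params = params or GRFIceParams()
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("spatial frequency q must be non-negative")
    return params.a1 * np.exp(-(q**2) / (2.0 * params.s1**2)) + params.a2 * np.exp(
        -((q - params.m) ** 2) / (2.0 * params.s2**2)
    )


def correlation_length(
    params: GRFIceParams | None = None,
    r_max: float = 5.0,
    n_points: int = 2001,
    q_max: float = 10.0,
) -> float:
    """Lag at which the radial autocorrelation falls to 1/e of its zero-lag value.

    The autocorrelation is the isotropic 2D inverse Fourier transform of
    the power-spectrum model, evaluated on a fine radial grid; the first
    1/e crossing is located by linear interpolation.
    """
    params = params or GRFIceParams()
    r = np.linspace(0.0, r_max, n_points)

    def acf_at(lag: float) -> float:
        val, _ = quad(
            lambda q: power_spectrum_model(q, params) * j0(2.0 * np.pi * q * lag) * 2.0 * np.pi * q,
            0.0,
            q_max,
            limit=400,
        )
        return val

    acf0 = acf_at(0.0)
    target = 1.0 / np.e
    prev = 1.0
    for i in range(1, n_points):
        cur = acf_at(r[i]) / acf0
        if cur <= target:
            # linear interpolation between the bracketing grid points
            return r[i - 1] + (prev - target) / (prev - cur) * (r[i] - r[i - 1])
        prev = cur
    raise RuntimeError(f"autocorrelation never reached 1/e within {r_max} Å")


@dataclass(frozen=True)
class IceSliceSpec:
    """One slice of GRF ice: areal density, grid, and random seed."""

    n_per_area: float  # molecules per Å² in this slice (number density × Δz)
    pixel_size: float
    shape: tuple[int, int]
    seed: int = 0

    def __post_init__(self):
        if self.n_per_area < 0:
            raise ValueError("molecular areal density must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if any(s <= 0 or s % 2 for s in self.shape):
            raise ValueError("field dimensions must be positive and even")


class CorrectionTable:
    """Pixel-area-indexed mean and variance correction ratios.

    Ratios are observed-over-analytic for rasterised water slices;
    interpolation is linear in pixel area and clamped at both ends.
    Both columns are non-increasing in pixel area (enforced at
    construction by an isotonic pass when requested).
    """

    def __init__(self, pixel_areas, mean_ratio, variance_ratio, meta: dict | None = None):
        order = np.argsort(pixel_areas)
        self.pixel_areas = np.asarray(pixel_areas, dtype=float)[order]
        self.mean_ratio = np.asarray(mean_ratio, dtype=float)[order]
        self.variance_ratio = np.asarray(variance_ratio, dtype=float)[order]
        self.meta = dict(meta or {})
        if len(self.pixel_areas) == 0:
            raise ValueError("correction table must not be empty")
        if np.any(self.mean_ratio <= 0) or np.any(self.variance_ratio <= 0):
            raise ValueError("correction ratios must be positive")

    def _interp(self, column: np.ndarray, pixel_area: float) -> float:
        return float(np.interp(pixel_area, self.pixel_areas, column))

    def mean_factor(self, pixel_area: float) -> float:
        return self._interp(self.mean_ratio, pixel_area)

    def variance_factor(self, pixel_area: float) -> float:
        return self._interp(self.variance_ratio, pixel_area)

    @staticmethod
    def unity() -> "CorrectionTable":
        """A no-correction table (ratios identically 1)."""
        return CorrectionTable([1e-4, 1.0], [1.0, 1.0], [1.0, 1.0], {"kind": "unity"})

    def to_tsv(self) -> str:
        buf = io.StringIO()
        for k, v in sorted(self.meta.items()):
            buf.write(f"# {k}: {v}\n")
        buf.write("pixel_area\tmean_ratio\tvariance_ratio\n")
        for a, m, v in zip(self.pixel_areas, self.mean_ratio, self.variance_ratio):
            buf.write(f"{a:.8g}\t{m:.8g}\t{v:.8g}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "CorrectionTable":
        meta, rows = {}, []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("pixel_area"):
                rows.append([float(v) for v in line.split("\t")])
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], meta)


_default_corrections: CorrectionTable | None = None


def default_correction_table() -> CorrectionTable:
    """The packaged calibration table (regenerable via ``icefield calibrate-ice``)."""
    global _default_corrections
    if _default_corrections is None:
        text = resources.files("icefield.data").joinpath("grf_correction_table.tsv").read_text()
        _default_corrections = CorrectionTable.from_tsv(text)
    return _default_corrections


def expected_moments(
    n_per_area: float,
    pixel_area: float,
    params: GRFIceParams | None = None,
    table: CorrectionTable | None = None,
) -> tuple[float, float]:
    """Corrected target (mean, variance) of slice pixel values.

    mean = v0_coeff * N * mean_ratio(pixel_area)     [eV·Å]
    variance = sigma0_sq * N * variance_ratio(pixel_area)   [(eV·Å)²]

    Both are linear in the areal density N.
    """
    if n_per_area < 0:
        raise ValueError("molecular areal density must be non-negative")
    if pixel_area <= 0:
        raise ValueError("pixel area must be positive")
    params = params or GRFIceParams()
    table = table or default_correction_table()
    mean = params.v0_coeff * n_per_area * table.mean_factor(pixel_area)
    variance = params.sigma0_sq * n_per_area * table.variance_factor(pixel_area)
    return mean, variance


def band_limit_mask(shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean Fourier-space mask keeping |q| <= 2/3 of Nyquist."""
    ky = np.fft.fftfreq(shape[0], pixel_size)
    kx = np.fft.fftfreq(shape[1], pixel_size)
    q = np.hypot(ky[:, None], kx[None, :])
    return q <= BAND_LIMIT_FRACTION / (2.0 * pixel_size)


def synthesize_grf_pair(
    spec: IceSliceSpec,
    params: GRFIceParams | None = None,
    table: CorrectionTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise two independent GRF ice slices (eV·Å per pixel).

    Fourier amplitudes follow sqrt(P(|q|)) inside the engine's frequency
    band, with uniformly distributed random phases and no Hermitian
    symmetry; the real and imaginary parts of the inverse transform are
    therefore two independent fields.  Each is affinely normalised to the
    corrected target moments.  N = 0 returns two zero fields.
    """
    params = params or GRFIceParams()
    table = table or default_correction_table()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    if spec.n_per_area == 0.0:
        return np.zeros((ny, nx)), np.zeros((ny, nx))
    mean, variance = expected_moments(spec.n_per_area, spec.pixel_size**2, params, table)
    ky = np.fft.fftfreq(ny, spec.pixel_size)
    kx = np.fft.fftfreq(nx, spec.pixel_size)
    q = np.hypot(ky[:, None], kx[None, :])
    amp = np.sqrt(power_spectrum_model(q, params))
    amp[q > BAND_LIMIT_FRACTION / (2.0 * spec.pixel_size)] = 0.0
    phases = rng.random((ny, nx))
    f = np.fft.ifft2(amp * np.exp(2j * np.pi * phases))
    out = []
    std = np.sqrt(variance)
    for comp in (f.real, f.imag):
        s = comp.std()
        if s == 0:
            out.append(np.full((ny, nx), mean))
        else:
            out.append((comp - comp.mean()) / s * std + mean)
    return out[0], out[1]


def apply_ice_to_slice(
    protein_slice: np.ndarray,
    ice_field: np.ndarray,
    mask: np.ndarray,
    v0_slice: float,
    threshold_fraction: float | None = None,
) -> np.ndarray:
    """Add GRF ice where the shape mask is true and the protein potential is weak.

    Ice is added at pixels with ``mask`` true AND
    ``protein_slice < threshold_fraction * v0_slice`` (strict inequality,
    so a zero threshold adds no ice to a non-negative slice); the protein
    potential is untouched elsewhere.
    """
    if threshold_fraction is None:
        threshold_fraction = GRFIceParams().threshold_fraction
    protein_slice = np.asarray(protein_slice)
    if protein_slice.shape != np.shape(ice_field) or protein_slice.shape != np.shape(mask):
        raise ValueError("protein slice, ice field, and mask must share one shape")
    add = np.asarray(mask, bool) & (protein_slice < threshold_fraction * v0_slice)
    out = protein_slice.copy()
    out[add] += np.asarray(ice_field)[add]
    return out


def campbell_variance_coefficient(
    pixel_size: float = 0.05,
    extent: float = 8.0,
    table: physics.ScatteringTable | None = None,
    molecule_mode: str = "point",
) -> float:
    """Variance of the projected ice potential per unit areal density.

    By Campbell's theorem, a field built from independently positioned
    molecules has pointwise variance N * ∬ V_mol(r)² d²r.  The integral
    is evaluated on a fine grid (default 0.05 Å) using the same truncated
    radial potentials the rasteriser uses.  In "point" mode the two
    hydrogens sit on the oxygen; in "rigid" mode the orientation-averaged
    cross terms are included analytically.
    """
    table = table or physics.default_scattering_table()
    n = int(round(extent / pixel_size))
    x = (np.arange(n) - n / 2 + 0.5) * pixel_size
    X, Y = np.meshgrid(x, x)
    R = np.hypot(X, Y)
    rO, vO = table.lookup("O")
    rH, vH = table.lookup("H")
    VO = np.interp(R, rO, vO, right=0.0)
    VH = np.interp(R, rH, vH, right=0.0)
    if molecule_mode == "point":
        V = VO + 2.0 * VH
        return float(np.sum(V**2) * pixel_size**2)
    if molecule_mode != "rigid":
        raise ValueError("molecule_mode must be 'point' or 'rigid'")
    # rigid: E[∬ V²] = ∬V_O² + 2∬V_H² + orientation-averaged cross terms,
    # evaluated in Fourier space where the spherical average is sinc(2πqd).
    from .sample import HOH_ANGLE_DEG, OH_BOND

    d_oh = OH_BOND
    d_hh = 2.0 * OH_BOND * np.sin(np.deg2rad(HOH_ANGLE_DEG) / 2.0)

    def integrand(q):
        fo = table.fe("O", q)
        fh = table.fe("H", q)
        k = 2.0 * np.pi * q
        sinc = lambda x: np.sinc(x / np.pi)
        coherent = fo**2 + 2.0 * fh**2 + 4.0 * fo * fh * sinc(k * d_oh) + 2.0 * fh**2 * sinc(k * d_hh)
        return KAPPA_V_A2**2 * coherent * 2.0 * np.pi * q

    val, _ = quad(integrand, 0.0, 60.0, limit=400)
    return float(val)


def calibrate_correction_table(
    pixel_sizes,
    params: GRFIceParams | None = None,
    seed: int = 0,
    density: float = 0.94,
    slice_thickness: float = 5.0,
    box_xy: float = 80.0,
    n_boxes: int = 4,
    molecule_mode: str = "rigid",
    enforce_monotone: bool = True,
    max_rel_se: float = 0.02,
) -> CorrectionTable:
    """Measure mean/variance correction ratios against the analytic targets.

    For each pixel size, several seeded water boxes are generated,
    rasterised slice by slice with the engine's truncated/interpolated
    supersampled potentials and band-limited exactly as the multislice
    engine does.  The mean ratio divides the per-pixel mean by
    v0_coeff*N; the variance ratio divides the variance of the
    *accumulated* stack by n_slices*sigma0_sq*N, so that the
    slice-independent GRF reproduces the accumulated-phase statistics of
    the correlated water (whose slices are slightly anticorrelated by
    excluded volume).  Monte-Carlo jitter in the ratio columns is cleaned
    up by an isotonic (non-increasing) pass.

    Raises RuntimeError if the relative standard error of a variance
    estimate exceeds ``max_rel_se``.
    """
    from .sample import WaterBoxSpec, generate_water_box

    params = params or GRFIceParams()
    pixel_sizes = np.asarray(sorted(pixel_sizes), dtype=float)
    table = physics.default_scattering_table()
    rho_n = density * 6.02214076e23 / (18.015 * 1e24)
    n_per_area = rho_n * slice_thickness

    mean_ratios, var_ratios = [], []
    for px in pixel_sizes:
        n = int(round(box_xy / px))
        n -= n % 2
        Lxy = n * px
        # coarser pixels leave fewer samples per field, so average more boxes
        boxes_here = max(n_boxes, int(np.ceil(n_boxes * (px / 0.35) ** 2)))
        m_ratios, v_ratios = [], []
        n_sl = 3
        for b in range(boxes_here):
            spec = WaterBoxSpec(
                box=(Lxy, Lxy, n_sl * slice_thickness),
                density=density,
                molecule_mode=molecule_mode,
                seed=(seed * 1000003 + b) % (2**31),
            )
            atoms = generate_water_box(spec)
            # the box is periodic: fold hydrogens protruding past the z
            # faces back in, so no potential is lost at the stack edges
            atoms.xyz[:, 2] %= spec.box[2]
            mask = band_limit_mask((n, n), px)
            total = np.zeros((n, n))
            for k in range(n_sl):
                field = physics.projected_potential(
                    atoms, px, (n, n),
                    z_window=(k * slice_thickness, (k + 1) * slice_thickness),
                    table=table, wrap=True,
                )
                total += np.fft.ifft2(mask * np.fft.fft2(field)).real
            # normalise by the REALISED areal density, so the ratio measures
            # rasterisation/band-transfer loss rather than the Poisson
            # fluctuation of the molecule count.  The variance ratio is
            # taken from the accumulated stack, var(sum)/n_slices: water
            # slices are anticorrelated across boundaries (excluded
            # volume), and the slice-independent GRF must reproduce the
            # accumulated-phase statistics the multislice engine sees.
            n_real = atoms.count("O") / (Lxy * Lxy * n_sl)
            m_ratios.append(total.mean() / n_sl / (params.v0_coeff * n_real))
            v_ratios.append(total.var() / n_sl / (params.sigma0_sq * n_real))
        v_ratios = np.asarray(v_ratios)
        rel_se = v_ratios.std(ddof=1) / np.sqrt(len(v_ratios)) / v_ratios.mean()
        if rel_se > max_rel_se:
            raise RuntimeError(
                f"variance estimate at pixel {px} Å has relative SE {rel_se:.3f} > {max_rel_se}"
            )
        mean_ratios.append(np.mean(m_ratios))
        var_ratios.append(np.mean(v_ratios))

    mean_ratios = np.asarray(mean_ratios)
    var_ratios = np.asarray(var_ratios)
    if enforce_monotone:
        # isotonic clean-up: ratios must not increase with pixel area; the
        # mean column is additionally clamped to <= 1 (area-averaged
        # rasterisation is unbiased up to truncation loss, so values above
        # 1 are Monte-Carlo jitter)
        mean_ratios = np.minimum.accumulate(np.minimum(mean_ratios, 1.0))
        var_ratios = np.minimum.accumulate(var_ratios)
    meta = {
        "seed": seed,
        "density_g_cm3": density,
        "slice_thickness_A": slice_thickness,
        "molecule_mode": molecule_mode,
        "box_xy_A": box_xy,
        "n_boxes": n_boxes,
        "band_limit_fraction": BAND_LIMIT_FRACTION,
    }
    return CorrectionTable(pixel_sizes**2, mean_ratios, var_ratios, meta)
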