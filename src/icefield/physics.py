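"""Electron optics and atomic electron-scattering factors.

This module provides the electron-optical constants of the beam
(relativistic wavelength and interaction parameter), tabulated electron
scattering factors, and the conversion of atomic coordinates into
projected-potential slices — the quantity whose phase the multislice
transmission function applies.

Conventions
-----------
* Spatial frequency ``q`` is in cycles/Å.  The tabulated five-Gaussian
  parameterisation is written in terms of ``s = sin(theta)/lambda = q/2``.
* The projected potential of a single atom integrates over the plane to
  ``kappa * fe(0)`` (the zero-frequency identity), with ``kappa`` in V·Å².
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .constants import ELECTRON_REST_ENERGY_KEV, KAPPA_V_A2

__all__ = [
    "BeamParameters",
    "ScatteringTable",
    "electron_wavelength",
    "interaction_parameter",
    "default_scattering_table",
    "mean_ice_potential",
    "projected_potential",
]

_PLANCK_EV = 4.135667696e-15  # eV s


def _check_energy(energy_kev: float) -> None:
    if not np.isfinite(energy_kev) or energy_kev <= 0:
        raise ValueError(f"beam energy must be positive, got {energy_kev} keV")


def electron_wavelength(energy_kev: float) -> float:
    """Relativistic de Broglie wavelength of the beam electron, in Å.

    lambda = h c / sqrt(E (E + 2 m c^2)) with E the kinetic energy.
    """
    _check_energy(energy_kev)
    e_ev = energy_kev * 1e3
    rest_ev = ELECTRON_REST_ENERGY_KEV * 1e3
    hc_ev_A = _PLANCK_EV * 2.99792458e18  # h*c in eV·Å
    return hc_ev_A / np.sqrt(e_ev * (e_ev + 2.0 * rest_ev))


def relativistic_factor(energy_kev: float) -> float:
    """Lorentz factor gamma = 1 + E / (m c^2)."""
    _check_energy(energy_kev)
    return 1.0 + energy_kev / ELECTRON_REST_ENERGY_KEV


def interaction_parameter(energy_kev: float) -> float:
    """Beam-specimen interaction parameter sigma, in rad·V⁻¹·Å⁻¹.

    sigma = 2 pi m_rel q_e lambda / h^2; multiplying sigma by a projected
    potential in V·Å gives the phase shift in radians.
    """
    _check_energy(energy_kev)
    lam = electron_wavelength(energy_kev)
    e_ev = energy_kev * 1e3
    rest_ev = ELECTRON_REST_ENERGY_KEV * 1e3
    # Closed form equivalent to 2 pi m_rel q_e lambda / h^2 in eV/Å units.
    return (2.0 * np.pi / (lam * e_ev)) * (rest_ev + e_ev) / (2.0 * rest_ev + e_ev)


@dataclass(frozen=True)
class BeamParameters:
    """Electron-optical constants of the illumination.

    Attributes
    ----------
    energy_kev:
        Kinetic energy of the beam electrons.
    wavelength:
        Relativistic de Broglie wavelength, Å.
    sigma:
        Interaction parameter, rad·V⁻¹·Å⁻¹.
    gamma:
        Relativistic (Lorentz) factor, dimensionless.
    """

    energy_kev: float
    wavelength: float
    sigma: float
    gamma: float

    @classmethod
    def from_energy(cls, energy_kev: float) -> "BeamParameters":
        return cls(
            energy_kev=float(energy_kev),
            wavelength=electron_wavelength(energy_kev),
            sigma=interaction_parameter(energy_kev),
            gamma=relativistic_factor(energy_kev),
        )


class UnsupportedElementError(KeyError):
    """Raised when an element symbol is absent from the scattering table."""


class ScatteringTable:
    """Five-Gaussian electron scattering factors and projected potentials.

    The factors are read from a packaged plain-text table
    (``data/electron_form_factors.tsv``).  ``fe(q)`` is positive and
    non-increasing for q >= 0, and ``fe(0)`` is finite for every element.

    Parameters
    ----------
    truncation_radius:
        Radius (Å) beyond which an atom's projected potential is treated
        as zero when rasterising.  Must be at least twice the pixel size
        at use time.
    """

    def __init__(self, truncation_radius: float = 3.0, lut_points: int = 4096):
        if truncation_radius <= 0:
            raise ValueError("truncation_radius must be positive")
        self.truncation_radius = float(truncation_radius)
        self._coeffs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        text = resources.files("icefield.data").joinpath("electron_form_factors.tsv").read_text()
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("element"):
                continue
            parts = line.split("\t")
            sym = parts[0]
            vals = np.array([float(v) for v in parts[1:]])
            self._coeffs[sym] = (vals[:5], vals[5:])
        self._lut_r = np.linspace(0.0, self.truncation_radius, lut_points)
        self._lut: dict[str, np.ndarray] = {}

    @property
    def elements(self) -> list[str]:
        return sorted(self._coeffs)

    def _ab(self, element: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self._coeffs[element]
        except KeyError:
            raise UnsupportedElementError(
                f"element {element!r} is not in the scattering-factor table"
            ) from None

    def fe(self, element: str, q) -> np.ndarray | float:
        """Electron scattering factor fe(q), in Å, for q in cycles/Å."""
        a, b = self._ab(element)
        q = np.asarray(q, dtype=float)
        if np.any(q < 0):
            raise ValueError("spatial frequency q must be non-negative")
        s2 = (q / 2.0) ** 2
        out = np.sum(a[:, None] * np.exp(-np.outer(b, np.ravel(s2))), axis=0)
        return out.reshape(np.shape(q)) if np.shape(q) else float(out[0])

    def projected_potential_radial(self, element: str, r) -> np.ndarray:
        """Projected (z-integrated) potential of one atom at planar radius r.

        The 2D Fourier pair of the Gaussian parameterisation:
        V_proj(r) = kappa * sum_i a_i (4 pi / b_i) exp(-4 pi^2 r^2 / b_i),
        in V·Å.  No truncation is applied here.
        """
        a, b = self._ab(element)
        r2 = np.ravel(np.asarray(r, dtype=float)) ** 2
        out = KAPPA_V_A2 * np.sum(
            a[:, None] * (4.0 * np.pi / b[:, None]) * np.exp(-4.0 * np.pi**2 * np.outer(1.0 / b, r2)),
            axis=0,
        )
        return out.reshape(np.shape(r))

    def lookup(self, element: str) -> tuple[np.ndarray, np.ndarray]:
        """Fine radial lookup table (r, V_proj(r)) truncated at the cutoff."""
        if element not in self._lut:
            self._ab(element)
            self._lut[element] = self.projected_potential_radial(element, self._lut_r)
        return self._lut_r, self._lut[element]


_default_table: ScatteringTable | None = None


def default_scattering_table() -> ScatteringTable:
    """Shared package-default scattering table (3 Å truncation)."""
    global _default_table
    if _default_table is None:
        _default_table = ScatteringTable()
    return _default_table


def mean_ice_potential(n_per_area: float, table: ScatteringTable | None = None) -> float:
    """Expected amorphous-ice potential per unit area, eV·Å.

    V0 = N * kappa * (fe_O(0) + 2 fe_H(0)), linear in the molecular areal
    density N (molecules·Å⁻²).  The coefficient evaluates to ~145.59.
    """
    if n_per_area < 0:
        raise ValueError("molecular areal density must be non-negative")
    table = table or default_scattering_table()
    coeff = KAPPA_V_A2 * (table.fe("O", 0.0) + 2.0 * table.fe("H", 0.0))
    return coeff * n_per_area


def projected_potential(
    atoms,
    pixel_size: float,
    shape: tuple[int, int],
    z_window: tuple[float, float] | None = None,
    table: ScatteringTable | None = None,
    supersample: int = 2,
    wrap: bool = False,
) -> np.ndarray:
    """Rasterise atoms into a 2D projected-potential field, V·Å.

    Each atom whose z coordinate lies in the half-open ``z_window``
    contributes its full (z-integrated) projected potential, evaluated on
    a ``supersample``-times finer grid through a linearly interpolated
    radial lookup, truncated at the table's truncation radius, and
    area-averaged down to the requested grid.  Pixel centres sit at
    ``(i + 0.5) * pixel_size``.

    Parameters
    ----------
    atoms:
        An object with ``elements`` (array of symbols) and ``xyz``
        ((n, 3) array, Å) attributes.
    pixel_size:
        Output pixel size, Å; must be positive and at most half the
        truncation radius.
    shape:
        (ny, nx) of the output field.
    z_window:
        Optional [z0, z1) selection on atom z coordinates.
    wrap:
        If true, stamps wrap periodically across the field edges
        (appropriate for periodic water boxes); otherwise out-of-field
        contributions are clipped away.
    """
    table = table or default_scattering_table()
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    if table.truncation_radius < 2.0 * pixel_size:
        raise ValueError("truncation radius must be at least twice the pixel size")
    ny, nx = int(shape[0]), int(shape[1])
    if ny <= 0 or nx <= 0:
        raise ValueError("grid shape must be positive in both dimensions")
    ss = int(supersample)
    if ss < 1:
        raise ValueError("supersample must be >= 1")

    fine = pixel_size / ss
    fnx, fny = nx * ss, ny * ss
    field = np.zeros(fny * fnx)

    elements = np.asarray(atoms.elements)
    xyz = np.asarray(atoms.xyz, dtype=float)
    if xyz.size and z_window is not None:
        z0, z1 = z_window
        sel = (xyz[:, 2] >= z0) & (xyz[:, 2] < z1)
        elements, xyz = elements[sel], xyz[sel]

    S = int(np.ceil(table.truncation_radius / fine))
    off = np.arange(-S, S + 1)
    ox, oy = np.meshgrid(off, off)

    for sym in np.unique(elements):
        r_lut, v_lut = table.lookup(sym)
        pts = xyz[elements == sym]
        for c0 in range(0, len(pts), 2048):
            chunk = pts[c0 : c0 + 2048]
            ix = np.floor(chunk[:, 0] / fine).astype(int)
            iy = np.floor(chunk[:, 1] / fine).astype(int)
            gx = ix[:, None, None] + ox
            gy = iy[:, None, None] + oy
            cx = (gx + 0.5) * fine
            cy = (gy + 0.5) * fine
            rr = np.hypot(cx - chunk[:, 0, None, None], cy - chunk[:, 1, None, None])
            vals = np.interp(rr.ravel(), r_lut, v_lut, right=0.0)
            vals[rr.ravel() > table.truncation_radius] = 0.0
            if wrap:
                gx = np.mod(gx, fnx)
                gy = np.mod(gy, fny)
                idx = (gy * fnx + gx).ravel()
            else:
                inb = (gx >= 0) & (gx < fnx) & (gy >= 0) & (gy < fny)
                idx = (np.clip(gy, 0, fny - 1) * fnx + np.clip(gx, 0, fnx - 1)).ravel()
                vals = np.where(inb.ravel(), vals, 0.0)
            field += np.bincount(idx, weights=vals, minlength=fny * fnx)

    field = field.reshape(fny, fnx)
    if ss > 1:
        field = field.reshape(ny, ss, nx, ss).mean(axis=(1, 3))
    return field
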