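"""Tilt-series simulation, CTF phase flipping, and weighted back projection.

Geometry: the beam travels along +z and the sample is tilted about +y
(right-handed positive angles), so every image row (fixed y) together
with its counterparts across the tilt series forms an independent 2D
parallel-beam problem in the (x, z) plane.  WBP ramp-filters each image
along x and back-projects with bilinear interpolation; the reconstructed
volume has the same voxel size as the image pixels and the zero-tilt
field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import grf as grf_mod
from . import multislice as ms
from . import physics, sample, stats

__all__ = [
    "TiltSeries",
    "simulate_tilt_series",
    "ctf_phase_flip",
    "wbp_reconstruct",
    "score_reconstruction",
    "build_potential_volume",
    "simulate_projection",
]


@dataclass
class TiltSeries:
    """Ordered images with their tilt angles and shared optics metadata."""

    images: np.ndarray  # (n_angles, ny, nx)
    angles: np.ndarray  # degrees, strictly monotonic
    pixel_size: float
    optics: ms.OpticsConfig = field(default_factory=ms.OpticsConfig)
    beam: physics.BeamParameters | None = None
    dose: float = 0.0

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3 or len(self.images) != len(self.angles):
            raise ValueError("need one image per tilt angle")
        d = np.diff(self.angles)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("tilt angles must be strictly monotonic")


def build_potential_volume(
    atoms: sample.AtomSet,
    pixel_size: float,
    shape: tuple[int, int],
    depth: float,
    slice_thickness: float = 5.0,
    z0: float = 0.0,
    table: physics.ScatteringTable | None = None,
    wrap: bool = False,
) -> ms.PotentialVolume:
    """Slice an atom set along z and rasterise each slice."""
    n_slices = max(1, int(round(depth / slice_thickness)))
    slices = [
        physics.projected_potential(
            atoms,
            pixel_size,
            shape,
            z_window=(z0 + i * slice_thickness, z0 + (i + 1) * slice_thickness),
            table=table,
            wrap=wrap,
        )
        for i in range(n_slices)
    ]
    return ms.PotentialVolume(slices, pixel_size, slice_thickness, z0)


def _grf_volume(
    shape: tuple[int, int],
    pixel_size: float,
    depth: float,
    slice_thickness: float,
    density: float,
    ice_shape: sample.SampleShape | None,
    tilt_angle: float,
    params: grf_mod.GRFIceParams,
    table: grf_mod.CorrectionTable,
    rng: np.random.Generator,
    protein_volume: ms.PotentialVolume | None = None,
    z0: float = 0.0,
) -> ms.PotentialVolume:
    """Stack of GRF ice slices, optionally masked by a (tilted) sample shape
    and combined with a protein potential via the V0/3 threshold rule."""
    n_slices = max(1, int(round(depth / slice_thickness)))
    n_per_area = sample.water_number_density(density) * slice_thickness
    v0_slice = params.v0_coeff * n_per_area
    slices = []
    pending: list[np.ndarray] = []
    for i in range(n_slices):
        if not pending:
            spec = grf_mod.IceSliceSpec(n_per_area, pixel_size, shape, seed=0)
            pair = grf_mod.synthesize_grf_pair(spec, params, table, rng=rng)
            pending = [pair[0], pair[1]]
        ice = pending.pop(0)
        z_win = (z0 + i * slice_thickness, z0 + (i + 1) * slice_thickness)
        if ice_shape is None:
            mask = np.ones(shape, dtype=bool)
        else:
            mask = sample.shape_mask(ice_shape, pixel_size, shape, z_win, tilt_angle)
        protein = protein_volume.slices[i] if protein_volume is not None else np.zeros(shape)
        slices.append(
            grf_mod.apply_ice_to_slice(protein, ice, mask, v0_slice, params.threshold_fraction)
        )
    return ms.PotentialVolume(slices, pixel_size, slice_thickness, z0)


def simulate_projection(
    volume: ms.PotentialVolume,
    beam: physics.BeamParameters,
    optics: ms.OpticsConfig,
    det: ms.DetectorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """exit wave → CTF → (optional) Poisson detection for one orientation."""
    wave = ms.exit_wave(volume, beam)
    intensity = ms.apply_ctf(wave, optics)
    if det is None or det.dose == 0:
        return intensity
    return ms.detect(intensity, volume.pixel_size, det, rng=rng).astype(float)


def simulate_tilt_series(
    angles,
    pixel_size: float,
    shape: tuple[int, int],
    depth: float,
    beam: physics.BeamParameters,
    optics: ms.OpticsConfig,
    det: ms.DetectorConfig | None = None,
    atoms: sample.AtomSet | None = None,
    ice_model: str = "none",
    density: float = 0.94,
    ice_shape: sample.SampleShape | None = None,
    slice_thickness: float = 5.0,
    grf_params: grf_mod.GRFIceParams | None = None,
    correction_table: grf_mod.CorrectionTable | None = None,
    seed: int = 0,
    rotation_center=None,
) -> TiltSeries:
    """Simulate a tilt series about +y; deterministic given the seed.

    For each angle the atomistic sample (if any) is rigidly rotated and
    re-rasterised; GRF ice is regenerated on the fly for every image
    (fresh fields per projection, masked by the tilted sample shape).
    """
    angles = np.asarray(angles, dtype=float)
    grf_params = grf_params or grf_mod.GRFIceParams()
    correction_table = correction_table or grf_mod.default_correction_table()
    ss = np.random.SeedSequence(seed)
    images = []
    extent_z = depth
    for j, ang in enumerate(angles):
        child = np.random.default_rng(ss.spawn(1)[0])
        protein_vol = None
        if atoms is not None and len(atoms):
            rotated = sample.rotate_atoms(atoms, "y", ang, center=rotation_center)
            protein_vol = build_potential_volume(
                rotated, pixel_size, shape, extent_z, slice_thickness
            )
        if ice_model == "grf":
            vol = _grf_volume(
                shape, pixel_size, extent_z, slice_thickness, density, ice_shape,
                ang, grf_params, correction_table, child, protein_vol,
            )
        elif protein_vol is not None:
            vol = protein_vol
        else:
            raise ValueError("nothing to simulate: no atoms and no GRF ice")
        det_j = None
        if det is not None and det.dose > 0:
            det_j = det
        images.append(
            simulate_projection(vol, beam, optics, det_j, rng=child)
        )
    return TiltSeries(np.array(images), angles, pixel_size, optics, beam,
                      det.dose if det else 0.0)


def ctf_phase_flip(
    images: np.ndarray,
    pixel_size: float,
    wavelength: float,
    optics: ms.OpticsConfig,
) -> np.ndarray:
    """Multiply each image's Fourier coefficients by sign(CTF).

    Zero-valued CTF bins pass unchanged; applying the flip twice is the
    identity.
    """
    images = np.asarray(images, dtype=float)
    squeeze = images.ndim == 2
    if squeeze:
        images = images[None]
    out = np.empty_like(images)
    ny, nx = images.shape[-2:]
    q = np.hypot(
        np.fft.fftfreq(ny, pixel_size)[:, None], np.fft.fftfreq(nx, pixel_size)[None, :]
    )
    s = np.sign(ms.ctf_1d(q, wavelength, optics))
    s[s == 0] = 1.0
    for i in range(images.shape[0]):
        out[i] = np.fft.ifft2(np.fft.fft2(images[i]) * s).real
    return out[0] if squeeze else out


def _ramp_filter(images: np.ndarray) -> np.ndarray:
    """Ramp (|k|) filter along the x axis of each image."""
    nx = images.shape[-1]
    ramp = np.abs(np.fft.fftfreq(nx))
    return np.fft.ifft(np.fft.fft(images, axis=-1) * ramp, axis=-1).real


def wbp_reconstruct(ts: TiltSeries, zero_mean: bool = True) -> np.ndarray:
    """Weighted back projection of a tilt series into an (nz, ny, nx) volume.

    Each image is ramp-filtered along x and smeared back along its
    viewing direction; nz equals nx (the zero-tilt field of view).  With
    ``zero_mean`` the mean of each image is removed first, which avoids a
    bowl artefact from the sharp field-of-view edge of bright-field
    images whose background is 1, not 0.
    """
    if len(ts.images) < 2:
        raise ValueError("need at least two tilt angles to reconstruct")
    imgs = ts.images - ts.images.mean(axis=(1, 2), keepdims=True) if zero_mean else ts.images
    filt = _ramp_filter(imgs)
    n_ang, ny, nx = filt.shape
    nz = nx
    # voxel-centre coordinates relative to the rotation axis (centre of FOV)
    xs = np.arange(nx) - (nx - 1) / 2.0
    zs = np.arange(nz) - (nz - 1) / 2.0
    Z, X = np.meshgrid(zs, xs, indexing="ij")
    vol = np.zeros((nz, ny, nx))
    for img, ang in zip(filt, ts.angles):
        th = np.deg2rad(ang)
        # sample tilted by +th  ==  detector x axis rotated by -th in (x,z)
        u = X * np.cos(th) + Z * np.sin(th) + (nx - 1) / 2.0
        u0 = np.floor(u).astype(int)
        w = u - u0
        valid0 = (u0 >= 0) & (u0 <= nx - 1)
        valid1 = (u0 + 1 >= 0) & (u0 + 1 <= nx - 1)
        c0 = np.clip(u0, 0, nx - 1)
        c1 = np.clip(u0 + 1, 0, nx - 1)
        contrib = (
            img[:, c0.ravel()].reshape(ny, nz, nx) * ((1.0 - w) * valid0).ravel().reshape(nz, nx)
            + img[:, c1.ravel()].reshape(ny, nz, nx) * (w * valid1).ravel().reshape(nz, nx)
        )
        vol += np.transpose(contrib, (1, 0, 2))
    return vol * (np.pi / (2.0 * n_ang))


def reproject(volume: np.ndarray, angles, pixel_size: float = 1.0) -> np.ndarray:
    """Line-integral projections of a volume along tilted z (consistency checks)."""
    from scipy.ndimage import map_coordinates

    nz, ny, nx = volume.shape
    xs = np.arange(nx) - (nx - 1) / 2.0
    zs = np.arange(nz) - (nz - 1) / 2.0
    out = np.zeros((len(angles), ny, nx))
    for j, ang in enumerate(np.asarray(angles, dtype=float)):
        th = np.deg2rad(ang)
        X, Zp = np.meshgrid(xs, zs, indexing="ij")  # detector x, integration path
        xr = X * np.cos(th) - Zp * np.sin(th) + (nx - 1) / 2.0
        zr = X * np.sin(th) + Zp * np.cos(th) + (nz - 1) / 2.0
        for iy in range(ny):
            vals = map_coordinates(volume[:, iy, :], [zr.ravel(), xr.ravel()], order=1)
            out[j, iy] = vals.reshape(nx, nz).sum(axis=1) * pixel_size
    return out


def score_reconstruction(
    volume: np.ndarray,
    reference: np.ndarray,
    voxel_size: float = 1.0,
    resolution_cutoff: float | None = 3.0,
    n_shells: int | None = None,
) -> tuple[stats.FSCCurve, float]:
    """FSC curve against a reference map plus the FSC average to a stated
    resolution (Å); ``resolution_cutoff=None`` means all shells."""
    curve = stats.fsc_curve(volume, reference, n_shells=n_shells, voxel_size=voxel_size)
    max_freq = None if resolution_cutoff is None else 1.0 / resolution_cutoff
    return curve, stats.fsc_average(curve, max_frequency=max_freq)
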