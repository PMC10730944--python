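"""Atomic-coordinate handling, synthetic water boxes, and sample shaping.

The water generator stands in for molecular-dynamics water models: it
places molecules by seeded rejection sampling with a cell list, enforcing
a minimum O–O distance, and reproduces a requested mass density exactly
(by construction the molecule count inverts rho = Mr * N / (N_A * V)).
It does not reproduce the hydrogen-bond network or the detailed radial
distribution function of simulated water; see the methods note for what
that does and does not affect.

Coordinate conventions: right-handed Cartesian axes in Å, beam along +z,
tilt = rotation about +y; voxel centres at (i + 0.5) * pixel; half-open
intervals wherever a boundary is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial.transform import Rotation

from .constants import MR_WATER, N_AVOGADRO, water_number_density

__all__ = [
    "AtomSet",
    "WaterBoxSpec",
    "SampleShape",
    "read_atoms",
    "write_xyz",
    "write_pdb",
    "generate_water_box",
    "measure_density",
    "trim_to_slab",
    "rotate_atoms",
    "shape_mask",
]

_WATER_RESIDUES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O"}

# Rigid three-site water geometry: O-H bond and H-O-H angle.
OH_BOND = 0.9572
HOH_ANGLE_DEG = 104.52


@dataclass
class AtomSet:
    """Element symbols plus Cartesian coordinates in Å."""

    elements: np.ndarray
    xyz: np.ndarray
    occupancy: np.ndarray | None = None

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.size == 0:
            self.xyz = self.xyz.reshape(0, 3)
        if self.xyz.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if len(self.elements) != len(self.xyz):
            raise ValueError("elements and coordinates differ in length")
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.xyz)

    def select(self, mask: np.ndarray) -> "AtomSet":
        occ = self.occupancy[mask] if self.occupancy is not None else None
        return AtomSet(self.elements[mask], self.xyz[mask], occ)

    def concat(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(
            np.concatenate([self.elements, other.elements]),
            np.vstack([self.xyz, other.xyz]),
        )

    def count(self, element: str) -> int:
        return int(np.sum(self.elements == element))


def empty_atomset() -> AtomSet:
    return AtomSet(np.array([], dtype=object), np.zeros((0, 3)))


def read_atoms(path, fmt: str | None = None, drop_waters: bool = False) -> AtomSet:
    """Read an AtomSet from PDB, mmCIF, or XYZ.

    Hydrogens are always retained; waters are retained unless
    ``drop_waters`` is set.  The format is inferred from the extension
    when ``fmt`` is None.
    """
    path = str(path)
    if fmt is None:
        low = path.lower()
        if low.endswith((".pdb", ".ent")):
            fmt = "pdb"
        elif low.endswith((".cif", ".mmcif")):
            fmt = "mmcif"
        elif low.endswith(".xyz"):
            fmt = "xyz"
        else:
            raise ValueError(f"cannot infer format of {path!r}; pass fmt=")
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise IOError(f"failed to parse {path!r}: {exc}") from exc
    elements, coords, occ = [], [], []
    for model in st:
        for chain in model:
            for residue in chain:
                if drop_waters and residue.name.upper() in _WATER_RESIDUES:
                    continue
                for atom in residue:
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    occ.append(atom.occ)
        break  # first model only
    return AtomSet(np.array(elements, dtype=object), np.array(coords).reshape(-1, 3), np.array(occ))


def _read_xyz(path: str) -> AtomSet:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise IOError(f"{path!r} is empty")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise IOError(f"{path!r} line 1: expected an atom count") from exc
    elements, coords = [], []
    for i, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise IOError(f"{path!r} line {i}: expected 'element x y z'")
        elements.append(parts[0])
        try:
            coords.append([float(v) for v in parts[1:4]])
        except ValueError as exc:
            raise IOError(f"{path!r} line {i}: bad coordinate") from exc
    if len(elements) != n:
        raise IOError(f"{path!r}: header promises {n} atoms, found {len(elements)}")
    return AtomSet(np.array(elements, dtype=object), np.array(coords))


def write_xyz(atoms: AtomSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(atoms)}\nwritten by icefield\n")
        for el, (x, y, z) in zip(atoms.elements, atoms.xyz):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def write_pdb(atoms: AtomSet, path) -> None:
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "UNK"
    res.seqid = gemmi.SeqId(1, " ")
    for i, (el, (x, y, z)) in enumerate(zip(atoms.elements, atoms.xyz), start=1):
        atom = gemmi.Atom()
        atom.name = str(el)
        atom.element = gemmi.Element(str(el))
        atom.pos = gemmi.Position(x, y, z)
        atom.serial = i
        res.add_atom(atom)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass
class WaterBoxSpec:
    """Specification for a synthetic water box.

    ``molecule_mode`` is either "rigid" (two hydrogens at the fixed TIP3P
    bond geometry, seeded random orientation) or "point" (hydrogens
    co-located with the oxygen, used by variance oracles).

    The default exclusion distance of 2.65 Å makes the rejection-sampled
    structure emulate low-density amorphous ice: the mean nearest-
    neighbour O–O spacing comes out at ~2.8 Å and the structure-factor
    maximum falls at 1/2.88 Å⁻¹, the reciprocal of the LDA mean O–O
    distance.  The physical closest-approach floor (~2.2 Å) can be
    requested explicitly.
    """

    box: tuple[float, float, float]
    density: float = 0.94
    min_oo_distance: float = 2.65
    molecule_mode: str = "rigid"
    seed: int = 0

    def __post_init__(self):
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValueError("box dimensions must be three positive lengths")
        if not (0.0 < self.density <= 1.2):
            raise ValueError("density must be in (0, 1.2] g/cm^3")
        mean_spacing = water_number_density(self.density) ** (-1.0 / 3.0)
        if self.min_oo_distance >= mean_spacing:
            raise ValueError(
                f"min_oo_distance {self.min_oo_distance} exceeds the mean spacing "
                f"{mean_spacing:.2f} implied by the density"
            )
        if self.molecule_mode not in ("rigid", "point"):
            raise ValueError("molecule_mode must be 'rigid' or 'point'")

    @property
    def n_molecules(self) -> int:
        vol = self.box[0] * self.box[1] * self.box[2]
        return int(round(self.density * vol * N_AVOGADRO / (MR_WATER * 1e24)))


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place the requested molecules."""


def _place_oxygens(spec: WaterBoxSpec, rng: np.random.Generator) -> np.ndarray:
    """Batched rejection sampling with periodic minimum-image exclusion.

    Candidates are proposed in blocks; each block is pruned against the
    already-accepted points and against itself with periodic KD-trees, so
    densities near the walls match the bulk.  Deterministic given the rng.
    """
    from scipy.spatial import cKDTree

    n = spec.n_molecules
    dmin = spec.min_oo_distance
    L = np.asarray(spec.box, dtype=float)
    accepted = np.empty((n, 3))
    placed = 0
    max_rounds = 4000
    for _ in range(max_rounds):
        if placed >= n:
            break
        m = int(min(max(8192, 4 * (n - placed)), 65536))
        cand = rng.random((m, 3)) * L
        if placed:
            tree = cKDTree(accepted[:placed], boxsize=L)
            d, _ = tree.query(cand, k=1, distance_upper_bound=dmin)
            cand = cand[np.isinf(d)]
        if len(cand) == 0:
            continue
        ctree = cKDTree(cand, boxsize=L)
        pairs = ctree.query_pairs(dmin, output_type="ndarray")
        valid = np.ones(len(cand), dtype=bool)
        for i, j in pairs:
            if valid[i]:
                valid[j] = False
        cand = cand[valid]
        take = min(len(cand), n - placed)
        accepted[placed : placed + take] = cand[:take]
        placed += take
    if placed < n:
        raise PackingError(
            f"placed only {placed}/{n} molecules; density {spec.density} with "
            f"min O-O {spec.min_oo_distance} Å is too dense to pack"
        )
    return accepted


def generate_water_box(spec: WaterBoxSpec) -> AtomSet:
    """Generate a synthetic water box; deterministic given the spec seed.

    The molecule count is ``round(rho * V * N_A / Mr)``; all O–O pairwise
    distances (minimum image) are at least ``min_oo_distance``.
    """
    rng = np.random.default_rng(spec.seed)
    oxy = _place_oxygens(spec, rng)
    n = len(oxy)
    if spec.molecule_mode == "point":
        elements = np.array(["O", "H", "H"] * n, dtype=object)
        xyz = np.repeat(oxy, 3, axis=0)
        return AtomSet(elements, xyz)
    half = np.deg2rad(HOH_ANGLE_DEG) / 2.0
    template = np.array(
        [
            [OH_BOND * np.sin(half), 0.0, OH_BOND * np.cos(half)],
            [-OH_BOND * np.sin(half), 0.0, OH_BOND * np.cos(half)],
        ]
    )
    rot = Rotation.random(n, rng=rng).as_matrix()
    hyd = np.einsum("nij,kj->nki", rot, template) + oxy[:, None, :]
    elements = np.empty(3 * n, dtype=object)
    elements[0::3] = "O"
    elements[1::3] = "H"
    elements[2::3] = "H"
    xyz = np.empty((3 * n, 3))
    xyz[0::3] = oxy
    xyz[1::3] = hyd[:, 0]
    xyz[2::3] = hyd[:, 1]
    return AtomSet(elements, xyz)


def measure_density(atoms: AtomSet, volume_A3: float) -> float:
    """Mass density (g·cm⁻³) of a pure-water AtomSet in a given volume.

    rho = Mr * N_water / (N_A * V), counting water molecules as O atoms.
    """
    if volume_A3 <= 0:
        raise ValueError("volume must be positive")
    n_water = atoms.count("O")
    return MR_WATER * n_water / (N_AVOGADRO * volume_A3 * 1e-24)


def trim_to_slab(atoms: AtomSet, z_center: float, thickness: float) -> AtomSet:
    """Keep atoms with z in [z_center - t/2, z_center + t/2)."""
    if thickness < 0:
        raise ValueError("thickness must be non-negative")
    z = atoms.xyz[:, 2] if len(atoms) else np.zeros(0)
    mask = (z >= z_center - thickness / 2.0) & (z < z_center + thickness / 2.0)
    return atoms.select(mask)


_AXES = {"x": (1.0, 0.0, 0.0), "y": (0.0, 1.0, 0.0), "z": (0.0, 0.0, 1.0)}


def rotate_atoms(atoms: AtomSet, axis, angle_deg: float, center=None) -> AtomSet:
    """Rigid rotation about an axis through ``center`` (default centroid)."""
    if isinstance(axis, str):
        try:
            axis = _AXES[axis.lower()]
        except KeyError:
            raise ValueError(f"unknown axis name {axis!r}") from None
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / norm
    if len(atoms) == 0:
        return atoms
    c = np.mean(atoms.xyz, axis=0) if center is None else np.asarray(center, dtype=float)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    xyz = rot.apply(atoms.xyz - c) + c
    return AtomSet(atoms.elements.copy(), xyz, atoms.occupancy)


@dataclass
class SampleShape:
    """Geometric envelope that delimits where amorphous ice exists.

    kinds:
      * ``cuboid``: dimensions (lx, ly, lz), centred at ``center``.
      * ``slab``: infinite in x/y, thickness ``dimensions[2]`` in z.
      * ``cylinder``: axis along y; dimensions (radius, length).
      * ``natural_cylinder``: cylinder whose axis offset (in x and z) and
        radius vary along y as cubic splines through the given knots.
        Knot positions are in the centred axial coordinate (0 at the
        shape centre), and the radius spline is a deviation added to the
        nominal radius ``dimensions[0]``.
    """

    kind: str
    dimensions: tuple
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_knots: tuple | None = None  # (y positions, x offsets, z offsets)
    radius_knots: tuple | None = None  # (y positions, radii)
    _splines: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in ("cuboid", "slab", "cylinder", "natural_cylinder"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind in ("cuboid", "slab") and any(d <= 0 for d in self.dimensions):
            raise ValueError("cuboid/slab dimensions must be positive")
        if self.kind in ("cylinder", "natural_cylinder") and self.dimensions[0] <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.kind == "natural_cylinder":
            if self.axis_knots is None or self.radius_knots is None:
                raise ValueError("natural_cylinder needs axis_knots and radius_knots")
            ky, kx, kz = (np.asarray(v, float) for v in self.axis_knots)
            ry, rr = (np.asarray(v, float) for v in self.radius_knots)
            if np.any(rr + self.dimensions[0] <= 0):
                raise ValueError("radius spline makes the radius non-positive")
            self._splines = (
                CubicSpline(ky, kx),
                CubicSpline(ky, kz),
                CubicSpline(ry, rr),
            )

    def _eval_splines(self, y: np.ndarray):
        sx, sz, sr = self._splines
        lo = max(sx.x[0], sz.x[0], sr.x[0])
        hi = min(sx.x[-1], sz.x[-1], sr.x[-1])
        if np.any(y < lo) or np.any(y > hi):
            raise ValueError("spline knots do not cover the requested axial extent")
        return sx(y), sz(y), sr(y)


def shape_mask(
    shape: SampleShape,
    pixel_size: float,
    grid_shape: tuple[int, int],
    z_slice: tuple[float, float],
    tilt_angle_deg: float = 0.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Boolean (ny, nx) mask: True where the tilted shape covers the voxel centre.

    The voxel centre tested is (x_c, y_c, z_c) with z_c the mid-plane of
    the slice.  Tilting rotates the *shape* about +y through its centre
    (equivalently, voxel centres are rotated by the inverse).
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    ny, nx = grid_shape
    x = origin[0] + (np.arange(nx) + 0.5) * pixel_size
    y = origin[1] + (np.arange(ny) + 0.5) * pixel_size
    zc = 0.5 * (z_slice[0] + z_slice[1])
    X, Y = np.meshgrid(x, y)
    Z = np.full_like(X, zc)
    cx, cy, cz = shape.center
    # inverse rotation of sample tilt about +y (right-handed)
    th = np.deg2rad(-tilt_angle_deg)
    Xr = (X - cx) * np.cos(th) + (Z - cz) * np.sin(th)
    Zr = -(X - cx) * np.sin(th) + (Z - cz) * np.cos(th)
    Yr = Y - cy

    if shape.kind == "cuboid":
        lx, ly, lz = shape.dimensions
        return (
            (Xr >= -lx / 2) & (Xr < lx / 2)
            & (Yr >= -ly / 2) & (Yr < ly / 2)
            & (Zr >= -lz / 2) & (Zr < lz / 2)
        )
    if shape.kind == "slab":
        lz = shape.dimensions[2]
        return (Zr >= -lz / 2) & (Zr < lz / 2)
    if shape.kind == "cylinder":
        radius, length = shape.dimensions
        return (Xr**2 + Zr**2 < radius**2) & (Yr >= -length / 2) & (Yr < length / 2)
    # natural cylinder: spline-varying axis offset and radius along y
    radius, length = shape.dimensions
    inside_y = (Yr >= -length / 2) & (Yr < length / 2)
    mask = np.zeros_like(inside_y)
    if np.any(inside_y):
        offx, offz, dr = shape._eval_splines(Yr[inside_y])
        rad = radius + dr
        mask[inside_y] = (Xr[inside_y] - offx) ** 2 + (Zr[inside_y] - offz) ** 2 < rad**2
    return mask
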