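"""Atom I/O, the synthetic water generator, and sample geometry."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from icefield import sample
from icefield.constants import MR_WATER, N_AVOGADRO


class TestReadAtoms:
    def test_pdb_fixture(self, tiny_pdb):
        atoms = sample.read_atoms(tiny_pdb)
        assert len(atoms) == 11
        assert atoms.elements[0] == "C"
        assert np.allclose(atoms.xyz[0], [1.0, 2.0, 3.0])

    def test_drop_waters(self, tiny_pdb):
        atoms = sample.read_atoms(tiny_pdb, drop_waters=True)
        assert len(atoms) == 2
        assert set(atoms.elements) == {"C", "N"}

    def test_missing_file(self, tmp_path):
        with pytest.raises((IOError, ValueError)):
            sample.read_atoms(tmp_path / "nope.pdb")

    def test_xyz_roundtrip(self, tmp_path):
        atoms = sample.AtomSet(
            np.array(["O", "H"], dtype=object), np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        )
        path = tmp_path / "a.xyz"
        sample.write_xyz(atoms, path)
        back = sample.read_atoms(path)
        assert list(back.elements) == ["O", "H"]
        assert np.allclose(back.xyz, atoms.xyz)

    def test_garbled_xyz(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\ncomment\nO 1.0 2.0\n")
        with pytest.raises(IOError, match="line 3"):
            sample.read_atoms(path)

    def test_pdb_write_read(self, tmp_path):
        atoms = sample.AtomSet(
            np.array(["C", "O"], dtype=object), np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        )
        path = tmp_path / "w.pdb"
        sample.write_pdb(atoms, path)
        back = sample.read_atoms(path)
        assert len(back) == 2
        assert np.allclose(back.xyz, atoms.xyz, atol=1e-3)


class TestWaterBox:
    def test_molecule_count_inverts_density_relation(self):
        spec = sample.WaterBoxSpec(box=(100.0, 100.0, 100.0), density=0.94, seed=0)
        expected = 0.94 * 1e6 * N_AVOGADRO / (MR_WATER * 1e24)
        assert abs(spec.n_molecules - expected) <= 1.0
        assert abs(spec.n_molecules - 31422) <= 1

    def test_determinism(self):
        spec = sample.WaterBoxSpec(box=(30.0, 30.0, 20.0), density=0.94, seed=7)
        a = sample.generate_water_box(spec)
        b = sample.generate_water_box(spec)
        assert np.array_equal(a.xyz, b.xyz)

    def test_min_distance_and_geometry(self, small_water_box):
        atoms, spec = small_water_box
        o = atoms.xyz[np.asarray(atoms.elements) == "O"]
        tree = cKDTree(o, boxsize=spec.box)
        d, _ = tree.query(o, k=2)
        assert d[:, 1].min() >= spec.min_oo_distance - 1e-9
        # rigid geometry: every O has two H at the fixed bond length
        h = atoms.xyz[np.asarray(atoms.elements) == "H"]
        assert len(h) == 2 * len(o)
        oh = np.linalg.norm(h - np.repeat(o, 2, axis=0), axis=1)
        assert np.allclose(oh, sample.OH_BOND, atol=1e-9)

    def test_emulates_lda_spacing(self, small_water_box):
        """Mean nearest-neighbour O-O spacing tracks the LDA value (2.88 Å)."""
        atoms, spec = small_water_box
        o = atoms.xyz[np.asarray(atoms.elements) == "O"]
        d, _ = cKDTree(o, boxsize=spec.box).query(o, k=2)
        assert 2.65 <= d[:, 1].mean() <= 2.95

    def test_density_round_trip(self, small_water_box):
        atoms, spec = small_water_box
        vol = spec.box[0] * spec.box[1] * spec.box[2]
        assert sample.measure_density(atoms, vol) == pytest.approx(0.94, rel=0.002)

    def test_point_mode_colocates_hydrogens(self):
        spec = sample.WaterBoxSpec(box=(25.0, 25.0, 25.0), molecule_mode="point", seed=1)
        atoms = sample.generate_water_box(spec)
        xyz = atoms.xyz.reshape(-1, 3, 3)
        assert np.allclose(xyz[:, 0], xyz[:, 1]) and np.allclose(xyz[:, 0], xyz[:, 2])

    def test_infeasible_packing(self):
        with pytest.raises(ValueError):
            sample.WaterBoxSpec(box=(20.0, 20.0, 20.0), density=1.0, min_oo_distance=3.2)

    def test_invalid_density(self):
        with pytest.raises(ValueError):
            sample.WaterBoxSpec(box=(20.0, 20.0, 20.0), density=1.5)


class TestMeasureDensity:
    def test_zero_molecules(self):
        empty = sample.AtomSet(np.array([], dtype=object), np.zeros((0, 3)))
        assert sample.measure_density(empty, 1000.0) == 0.0

    def test_reference_values(self):
        class Counted:
            def __init__(self, n):
                self.n = n

            def count(self, el):
                return self.n if el == "O" else 0

        assert sample.measure_density(Counted(31422), 100.0**3) == pytest.approx(0.94, abs=1e-3)
        assert sample.measure_density(Counted(12_999_204), 735.0**3) == pytest.approx(0.979, abs=1e-3)

    def test_zero_volume(self):
        empty = sample.AtomSet(np.array([], dtype=object), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            sample.measure_density(empty, 0.0)


class TestTrimToSlab:
    def test_identity_when_thick(self, small_water_box):
        atoms, spec = small_water_box
        out = sample.trim_to_slab(atoms, spec.box[2] / 2, 10 * spec.box[2])
        assert len(out) == len(atoms)

    def test_zero_thickness(self, small_water_box):
        atoms, _ = small_water_box
        assert len(sample.trim_to_slab(atoms, 5.0, 0.0)) == 0

    def test_half_open_boundaries(self):
        atoms = sample.AtomSet(
            np.array(["O", "O", "O"], dtype=object),
            np.array([[0, 0, 1.0], [0, 0, 2.0], [0, 0, 3.0]]),
        )
        out = sample.trim_to_slab(atoms, 2.0, 2.0)  # [1, 3)
        assert np.allclose(sorted(out.xyz[:, 2]), [1.0, 2.0])

    def test_uniform_retention_fraction(self):
        rng = np.random.default_rng(3)
        n = 4000
        atoms = sample.AtomSet(np.array(["O"] * n, dtype=object), rng.random((n, 3)) * 50.0)
        kept = sample.trim_to_slab(atoms, 25.0, 25.0)
        p = len(kept) / n
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / n)


class TestRotateAtoms:
    def test_zero_and_full_turn(self, small_water_box):
        atoms, _ = small_water_box
        sub = atoms.select(np.arange(len(atoms)) < 90)
        assert np.allclose(sample.rotate_atoms(sub, "y", 0.0).xyz, sub.xyz, atol=1e-12)
        assert np.allclose(sample.rotate_atoms(sub, "y", 360.0).xyz, sub.xyz, atol=1e-9)

    def test_isometry(self):
        rng = np.random.default_rng(11)
        atoms = sample.AtomSet(np.array(["C"] * 12, dtype=object), rng.random((12, 3)) * 10)
        rot = sample.rotate_atoms(atoms, [1.0, 2.0, -0.5], 73.4)
        assert np.allclose(pdist(rot.xyz), pdist(atoms.xyz), atol=1e-9)

    def test_zero_axis_rejected(self):
        atoms = sample.AtomSet(np.array(["C"], dtype=object), np.array([[1.0, 1.0, 1.0]]))
        with pytest.raises(ValueError):
            sample.rotate_atoms(atoms, [0, 0, 0], 10.0)


class TestShapeMask:
    def test_cuboid_exact(self):
        shape = sample.SampleShape("cuboid", (4.0, 6.0, 10.0), center=(8.0, 8.0, 5.0))
        mask = sample.shape_mask(shape, 1.0, (16, 16), (0.0, 10.0))
        X = (np.arange(16) + 0.5)[None, :].repeat(16, 0)
        Y = (np.arange(16) + 0.5)[:, None].repeat(16, 1)
        expected = (np.abs(X - 8) < 2.0) & (np.abs(Y - 8) < 3.0)
        assert np.array_equal(mask, expected)

    def test_cylinder_rotation_about_own_axis(self):
        shape = sample.SampleShape("cylinder", (5.0, 12.0), center=(8.0, 8.0, 8.0))
        base = sample.shape_mask(shape, 1.0, (16, 16), (6.0, 8.0))
        for ang in (17.0, 90.0, 243.0):
            rot = sample.shape_mask(shape, 1.0, (16, 16), (6.0, 8.0), tilt_angle_deg=ang)
            assert np.array_equal(base, rot)

    def test_natural_cylinder_degenerates_to_cylinder(self):
        y_knots = [-8.0, 0.0, 8.0]  # centred axial coordinate
        shape = sample.SampleShape(
            "natural_cylinder",
            (5.0, 12.0),
            center=(8.0, 8.0, 8.0),
            axis_knots=(y_knots, [0.0] * 3, [0.0] * 3),
            radius_knots=(y_knots, [0.0] * 3),
        )
        ideal = sample.SampleShape("cylinder", (5.0, 12.0), center=(8.0, 8.0, 8.0))
        for zwin in [(0.0, 2.0), (6.0, 8.0)]:
            assert np.array_equal(
                sample.shape_mask(shape, 0.5, (32, 32), zwin),
                sample.shape_mask(ideal, 0.5, (32, 32), zwin),
            )

    def test_cylinder_masked_volume(self):
        """Summed over z slices, the mask volume is pi r^2 * axial extent."""
        r, px = 20.0, 0.5
        shape = sample.SampleShape("cylinder", (r, 100.0), center=(32.0, 32.0, 32.0))
        volume = 0.0
        for iz in range(128):
            mask = sample.shape_mask(shape, px, (128, 128), (iz * px, (iz + 1) * px))
            volume += mask.sum() * px**3
        expected = np.pi * r**2 * 64.0  # grid spans the full axial extent
        shell = 2 * np.pi * r * 64.0 * px  # one voxel-shell of the lateral surface
        assert abs(volume - expected) < shell

    def test_tilt_mirror_symmetry(self):
        """Images at +theta and -theta of an axis-aligned shape mirror in x."""
        shape = sample.SampleShape("cylinder", (5.0, 20.0), center=(8.0, 8.0, 8.0))
        shape2 = sample.SampleShape("cuboid", (6.0, 6.0, 6.0), center=(8.0, 8.0, 8.0))
        for sh in (shape, shape2):
            plus = sample.shape_mask(sh, 0.5, (32, 32), (2.0, 2.5), tilt_angle_deg=30.0)
            minus = sample.shape_mask(sh, 0.5, (32, 32), (2.0, 2.5), tilt_angle_deg=-30.0)
            assert np.array_equal(plus, minus[:, ::-1])

    def test_spline_out_of_range(self):
        shape = sample.SampleShape(
            "natural_cylinder",
            (5.0, 40.0),
            center=(8.0, 8.0, 8.0),
            axis_knots=([-4.0, 0.0, 4.0], [0.0] * 3, [0.0] * 3),
            radius_knots=([-4.0, 0.0, 4.0], [0.0] * 3),
        )
        with pytest.raises(ValueError):
            sample.shape_mask(shape, 1.0, (16, 16), (7.0, 9.0))
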