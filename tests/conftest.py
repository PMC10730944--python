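import numpy as np
import pytest

from icefield import physics, sample


@pytest.fixture(scope="session")
def beam300():
    return physics.BeamParameters.from_energy(300.0)


@pytest.fixture(scope="session")
def scattering_table():
    return physics.default_scattering_table()


@pytest.fixture(scope="session")
def small_water_box():
    """A 60x60x15 Å rigid water box shared across tests (read-only)."""
    spec = sample.WaterBoxSpec(box=(60.0, 60.0, 15.0), density=0.94, seed=42)
    return sample.generate_water_box(spec), spec


@pytest.fixture
def tiny_pdb(tmp_path):
    """Two protein atoms plus three waters (9 water atoms) as a PDB file."""
    lines = [
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C",
        "ATOM      2  N   ALA A   1       2.500   2.000   3.000  1.00  0.00           N",
    ]
    serial = 3
    for i, (x, y, z) in enumerate([(10.0, 10.0, 10.0), (14.0, 10.0, 10.0), (18.0, 10.0, 10.0)]):
        for name, el, (dx, dy, dz) in [
            ("O", "O", (0, 0, 0)),
            ("H1", "H", (0.96, 0, 0)),
            ("H2", "H", (-0.24, 0.93, 0)),
        ]:
            lines.append(
                f"HETATM{serial:5d} {name:<4s} HOH A{100 + i:4d}    "
                f"{x + dx:8.3f}{y + dy:8.3f}{z + dz:8.3f}  1.00  0.00          "
                f"{el:>2s}"
            )
            serial += 1
    lines.append("END")
    path = tmp_path / "fixture.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
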