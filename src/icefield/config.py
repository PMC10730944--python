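"""Run configuration: YAML parsing, validation, and seeded substreams.

A RunConfig collects everything a simulation run needs — beam, imaging
optics, sample description, ice model, tilt scheme, and the master seed.
Unknown keys are rejected and out-of-range values produce errors naming
the offending key.  One master seed spawns named substreams (water box,
per-slice GRF, per-image detector noise) so partial pipelines can be
reproduced independently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .grf import GRFIceParams

__all__ = ["RunConfig", "load_config", "save_config", "substream", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class BeamSection:
    energy_kev: float = 300.0


@dataclass
class ImagingSection:
    pixel_size: float = 1.0
    slice_thickness: float = 5.0
    defocus: float = 0.0
    cs_mm: float = 0.0
    aperture: float | None = None
    focal_spread: float = 0.0
    source_spread: float = 0.0
    dose: float = 0.0
    shape: tuple[int, int] = (64, 64)


@dataclass
class SampleSection:
    atoms_path: str | None = None
    drop_waters: bool = False
    ice_model: str = "none"  # none | atomistic | grf
    density: float = 0.94
    depth: float = 50.0
    water_seed_box: tuple[float, float, float] | None = None
    min_oo_distance: float = 2.65
    molecule_mode: str = "rigid"
    shape_kind: str | None = None
    shape_dimensions: tuple | None = None
    threshold_fraction: float = GRFIceParams.threshold_fraction


@dataclass
class TiltSection:
    start: float = -60.0
    stop: float = 60.0
    step: float = 3.0

    def angles(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


@dataclass
class RunConfig:
    beam: BeamSection = field(default_factory=BeamSection)
    imaging: ImagingSection = field(default_factory=ImagingSection)
    sample: SampleSection = field(default_factory=SampleSection)
    tilt: TiltSection = field(default_factory=TiltSection)
    seed: int = 0
    output_dir: str = "."


_SECTIONS = {"beam": BeamSection, "imaging": ImagingSection, "sample": SampleSection,
             "tilt": TiltSection}


def _build_section(cls, mapping, path):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section '{path}'")
    coerced = {}
    for k, v in mapping.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def _validate(cfg: RunConfig) -> None:
    checks = [
        ("beam.energy_kev", cfg.beam.energy_kev > 0),
        ("imaging.pixel_size", cfg.imaging.pixel_size > 0),
        ("imaging.slice_thickness", cfg.imaging.slice_thickness > 0),
        ("imaging.dose", cfg.imaging.dose >= 0),
        ("imaging.shape", all(s > 0 for s in cfg.imaging.shape)),
        ("sample.density", 0 < cfg.sample.density <= 1.2),
        ("sample.depth", cfg.sample.depth > 0),
        ("sample.ice_model", cfg.sample.ice_model in ("none", "atomistic", "grf")),
        ("sample.molecule_mode", cfg.sample.molecule_mode in ("rigid", "point")),
        ("sample.threshold_fraction", cfg.sample.threshold_fraction >= 0),
        ("tilt.step", cfg.tilt.step != 0),
    ]
    for key, ok in checks:
        if not ok:
            raise ConfigError(f"invalid value for '{key}'")


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path!r}: config must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed", "output_dir"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    cfg = RunConfig(seed=int(raw.get("seed", 0)), output_dir=str(raw.get("output_dir", ".")),
                    **kwargs)
    _validate(cfg)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    def section_dict(obj):
        out = {}
        for f in fields(obj):
            v = getattr(obj, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    doc = {name: section_dict(getattr(cfg, name)) for name in _SECTIONS}
    doc["seed"] = cfg.seed
    doc["output_dir"] = cfg.output_dir
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from the master seed."""
    digest = hashlib.sha256(name.encode()).digest()
    child = int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, child]))
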