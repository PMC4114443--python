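"""Run configuration: schema, defaults and YAML round-tripping.

A :class:`RunConfig` gathers every knob of an end-to-end run — physics,
per-stage phantom table, GLCM settings, PCA thresholds, cross-validation
settings and the explicit seeds of every random stage.  Validation happens
before any stage executes: a missing seed or an unphysical value rejects
the configuration outright.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError
from .phantom import (DEFAULT_STAGE_TABLE, STAGE_ORDER, Stage, StageTextureSpec,
                      TissueConstants, validate_stage_table)
from .physics import PhysicsConfig, wavelength_from_energy

REQUIRED_SEEDS = ("phantom", "noise", "roi", "cv")


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 16
    distance: int = 1
    symmetric: bool = True
    n_rois: int = 20
    roi_size: int = 50

    def __post_init__(self) -> None:
        if self.levels < 2 or self.levels > 256:
            raise ConfigError("glcm.levels must be in [2, 256]")
        if self.distance < 1:
            raise ConfigError("glcm.distance must be >= 1")
        if self.n_rois < 1 or self.roi_size < 2:
            raise ConfigError("glcm.n_rois and glcm.roi_size must be positive")


@dataclass(frozen=True)
class PCAConfig:
    ccr_threshold: float = 0.80
    score_threshold: float = 8.5
    score_mode: str = "raw"
    sign_convention: str = "anchor"

    def __post_init__(self) -> None:
        if not 0 < self.ccr_threshold < 1:
            raise ConfigError("pca.ccr_threshold must be in (0, 1)")
        if self.score_mode not in ("raw", "standardized"):
            raise ConfigError("pca.score_mode must be 'raw' or 'standardized'")
        if self.sign_convention not in ("anchor", "loading_sum"):
            raise ConfigError("pca.sign_convention must be 'anchor' or 'loading_sum'")


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("cv.k must be >= 2")
        if self.C <= 0:
            raise ConfigError("cv.C must be positive")


@dataclass(frozen=True)
class Seeds:
    phantom: int
    noise: int
    roi: int
    cv: int


@dataclass
class RunConfig:
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    tissue: TissueConstants = field(default_factory=TissueConstants)
    stages: Mapping[Stage, StageTextureSpec] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_TABLE))
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    pca: PCAConfig = field(default_factory=PCAConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    seeds: Seeds = field(default_factory=lambda: Seeds(11, 12, 13, 14))
    grid_size: int = 256
    grid_height: int = 256
    n_angles: int = 180
    quantization: str = "fixed"
    invert_display: bool = True
    ref_high_factor: float = 2.2
    mask_erosion_px: int = 16

    def __post_init__(self) -> None:
        if self.grid_size < 64 or self.grid_height < 64:
            raise ConfigError("grid_size and grid_height must be >= 64")
        if self.n_angles < 2:
            raise ConfigError("n_angles must be >= 2")
        if self.quantization not in ("minmax", "fixed"):
            raise ConfigError("quantization must be 'minmax' or 'fixed'")
        if self.ref_high_factor <= 0:
            raise ConfigError("ref_high_factor must be positive")
        if self.mask_erosion_px < 0:
            raise ConfigError("mask_erosion_px must be nonnegative")
        missing = [s.value for s in STAGE_ORDER if s not in self.stages]
        if missing:
            raise ConfigError(f"stage table missing stage(s): {missing}")
        validate_stage_table(self.stages)

    def to_dict(self) -> dict:
        return {
            "physics": {
                "energy_kev": self.physics.energy_kev,
                "propagation_distance": self.physics.propagation_distance,
                "pixel_size": self.physics.pixel_size,
                "photon_count": self.physics.photon_count,
            },
            "tissue": asdict(self.tissue),
            "phantom": {s.value: asdict(self.stages[s]) for s in STAGE_ORDER},
            "glcm": asdict(self.glcm),
            "pca": asdict(self.pca),
            "cv": asdict(self.cv),
            "seeds": asdict(self.seeds),
            "grid_size": self.grid_size,
            "grid_height": self.grid_height,
            "n_angles": self.n_angles,
            "quantization": self.quantization,
            "invert_display": self.invert_display,
            "ref_high_factor": self.ref_high_factor,
            "mask_erosion_px": self.mask_erosion_px,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build_section(cls, mapping: dict, name: str):
    try:
        return cls(**mapping)
    except TypeError as exc:
        raise ConfigError(f"bad '{name}' section: {exc}") from exc


def from_dict(raw: Mapping) -> RunConfig:
    """Build and validate a RunConfig from a plain mapping (e.g. parsed YAML)."""
    raw = dict(raw)
    known = {"physics", "tissue", "phantom", "glcm", "pca", "cv", "seeds",
             "grid_size", "grid_height", "n_angles", "quantization",
             "invert_display", "ref_high_factor", "mask_erosion_px"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    phys_raw = dict(raw.get("physics", {}))
    if "energy_kev" in phys_raw:
        phys_raw["wavelength"] = wavelength_from_energy(phys_raw.pop("energy_kev"))
    physics = _build_section(PhysicsConfig, phys_raw, "physics")
    tissue = _build_section(TissueConstants, dict(raw.get("tissue", {})), "tissue")

    stages_raw = raw.get("phantom")
    if stages_raw is None:
        stages = dict(DEFAULT_STAGE_TABLE)
    else:
        stages = {}
        for key, spec_raw in stages_raw.items():
            stage = Stage(key)
            spec = _build_section(StageTextureSpec, dict(spec_raw), f"phantom.{key}")
            stages[stage] = spec

    seeds_raw = raw.get("seeds")
    if seeds_raw is None:
        raise ConfigError("config must provide a 'seeds' section with explicit "
                          f"seeds for {REQUIRED_SEEDS}")
    missing = [k for k in REQUIRED_SEEDS if k not in seeds_raw]
    if missing:
        raise ConfigError(f"seeds section missing: {missing}")
    seeds = Seeds(**{k: int(seeds_raw[k]) for k in REQUIRED_SEEDS})

    return RunConfig(
        physics=physics,
        tissue=tissue,
        stages=stages,
        glcm=_build_section(GLCMConfig, dict(raw.get("glcm", {})), "glcm"),
        pca=_build_section(PCAConfig, dict(raw.get("pca", {})), "pca"),
        cv=_build_section(CVConfig, dict(raw.get("cv", {})), "cv"),
        seeds=seeds,
        grid_size=int(raw.get("grid_size", 256)),
        grid_height=int(raw.get("grid_height", 256)),
        n_angles=int(raw.get("n_angles", 180)),
        quantization=str(raw.get("quantization", "fixed")),
        invert_display=bool(raw.get("invert_display", True)),
        ref_high_factor=float(raw.get("ref_high_factor", 2.2)),
        mask_erosion_px=int(raw.get("mask_erosion_px", 16)),
    )


def from_yaml(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return from_dict(raw)


def default_config() -> RunConfig:
    """The shipped default configuration (stage table, seeds, protocol sizes)."""
    with resources.files("phasetex.data").joinpath("default_config.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return from_dict(raw)
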