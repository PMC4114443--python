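"""Stage-labelled refractive-index phantoms of a gastric wall.

The generator emulates air-filled mouse gastric specimens over six disease
stages (normal plus 3/5/7/9/11 days of tumor development).  A specimen
cross-section is an annulus — gastric wall around an air-filled lumen —
whose wall thickness, boundary roughness and intra-wall texture variance
grow monotonically with stage, mirroring the qualitative radiological
progression of early gastric cancer (wall thickening, surface unevenness,
hyperplasic nodules).

Two products are offered:

* :func:`make_stage_phantom` — a 2-D cross-section slice (CT input).
* :func:`make_stage_volume` — a quasi-3-D tubular specimen (a stack of
  correlated cross-sections) whose projection along the beam gives a 2-D
  radiograph suitable for 50x50-pixel texture ROIs.

Tissue constants are order-of-magnitude soft-tissue values (water-like
electron density, soft-tissue attenuation at 13 keV); they live in
:class:`TissueConstants`, not in code paths, and are deliberately labelled
as nominal — no quantitative delta/beta for gastric wall or tumor exists.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .errors import DomainError, GeometryError
from .physics import PhysicsConfig, delta_from_electron_density, beta_from_mu


class Stage(str, enum.Enum):
    """Specimen stage: normal or days elapsed since tumor-cell implantation."""

    NORMAL = "normal"
    D3 = "d3"
    D5 = "d5"
    D7 = "d7"
    D9 = "d9"
    D11 = "d11"

    @property
    def index(self) -> int:
        return STAGE_ORDER.index(self)


STAGE_ORDER = (Stage.NORMAL, Stage.D3, Stage.D5, Stage.D7, Stage.D9, Stage.D11)


@dataclass(frozen=True)
class TissueConstants:
    """Nominal gastric-wall tissue optics at the working energy.

    ``electron_density`` is water-like (3.34e29 m^-3); ``attenuation_mu`` is a
    soft-tissue linear attenuation coefficient at 13 keV (~250 m^-1).  Both are
    order-of-magnitude stand-ins: the resulting delta/beta ratio (~700) keeps
    the phase channel dominant, as it is for light-element tissue.
    """

    electron_density: float = 3.34e29
    attenuation_mu: float = 250.0

    def delta(self, cfg: PhysicsConfig) -> float:
        return delta_from_electron_density(self.electron_density, cfg)

    def beta(self, cfg: PhysicsConfig) -> float:
        return beta_from_mu(self.attenuation_mu, cfg)


@dataclass(frozen=True)
class StageTextureSpec:
    """Geometry and texture parameters of one stage's phantom.

    wall_thickness and roughness_amplitude must be nondecreasing along the
    stage sequence normal -> d11 (enforced by :func:`validate_stage_table`).

    :param wall_thickness: mean radial wall thickness (m).
    :param roughness_amplitude: standard deviation of the intra-wall delta
        fluctuation field (delta units, i.e. dimensionless decrement).
    :param roughness_correlation_length: correlation length of that field (m).
    :param nodule_count: number of discrete hyperplasic nodules on the inner
        wall (0 for normal/d3).
    :param seed: base seed; generation is a pure function of (stage, size,
        spec, cfg).
    :param boundary_amplitude: standard deviation of the radial perturbation
        of the wall boundaries (m); models surface unevenness.
    """

    wall_thickness: float
    roughness_amplitude: float
    roughness_correlation_length: float
    nodule_count: int
    seed: int
    boundary_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0:
            raise GeometryError("wall_thickness must be positive")
        if self.roughness_amplitude < 0 or self.boundary_amplitude < 0:
            raise DomainError("roughness amplitudes must be nonnegative")
        if self.roughness_correlation_length <= 0:
            raise DomainError("roughness_correlation_length must be positive")
        if self.nodule_count < 0:
            raise DomainError("nodule_count must be nonnegative")


# Default per-stage table.  Thickness grows ~2.5x over the stage sequence
# (hundreds of um, plausible for a mouse gastric wall at 9 um pixels);
# texture amplitude is quoted as a fraction of tissue delta in the comment
# and stored in absolute delta units; boundary roughness grows from ~1 to
# ~9 detector pixels.  All values were fixed at design time.
_DELTA_TISSUE_13KEV = 1.3633e-06  # water-like delta at 13 keV, for the table below

DEFAULT_STAGE_TABLE: Mapping[Stage, StageTextureSpec] = {
    #                      thickness  tex. amp (frac of delta)   corr len  nodules  seed  boundary amp
    Stage.NORMAL: StageTextureSpec(250e-6, 0.05 * _DELTA_TISSUE_13KEV, 30e-6, 0, 1000, 9e-6),
    Stage.D3:     StageTextureSpec(290e-6, 0.09 * _DELTA_TISSUE_13KEV, 30e-6, 0, 1001, 18e-6),
    Stage.D5:     StageTextureSpec(330e-6, 0.14 * _DELTA_TISSUE_13KEV, 30e-6, 1, 1002, 30e-6),
    Stage.D7:     StageTextureSpec(370e-6, 0.20 * _DELTA_TISSUE_13KEV, 30e-6, 2, 1003, 45e-6),
    Stage.D9:     StageTextureSpec(420e-6, 0.27 * _DELTA_TISSUE_13KEV, 30e-6, 3, 1004, 63e-6),
    Stage.D11:    StageTextureSpec(470e-6, 0.35 * _DELTA_TISSUE_13KEV, 30e-6, 4, 1005, 81e-6),
}


def validate_stage_table(table: Mapping[Stage, StageTextureSpec]) -> None:
    """Check the monotonicity invariant of a per-stage parameter table."""
    specs = [table[s] for s in STAGE_ORDER if s in table]
    for a, b in zip(specs, specs[1:]):
        if b.wall_thickness < a.wall_thickness:
            raise GeometryError("wall_thickness must be nondecreasing across stages")
        if b.roughness_amplitude < a.roughness_amplitude:
            raise DomainError("roughness_amplitude must be nondecreasing across stages")


@dataclass
class RefractiveMap:
    """Per-pixel (or per-voxel) delta and beta grids of a simulated specimen.

    Grids are 2-D ``(rows, cols)`` cross-sections or 3-D ``(height, rows,
    cols)`` volumes; ``wall_mask`` marks gastric-wall pixels on the same grid.
    """

    delta_grid: np.ndarray
    beta_grid: np.ndarray
    pixel_size: float
    stage_label: Stage
    wall_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_grid.size == 0:
            raise DomainError("refractive map is empty")
        if self.delta_grid.shape != self.beta_grid.shape:
            raise DomainError("delta and beta grids must share a shape")
        if self.wall_mask.shape != self.delta_grid.shape:
            raise DomainError("wall_mask must match the grid shape")
        if not self.wall_mask.any():
            raise GeometryError("wall_mask is empty")
        if np.any(self.delta_grid < 0) or np.any(self.beta_grid < 0):
            raise DomainError("delta and beta must be nonnegative everywhere")

    @property
    def ndim(self) -> int:
        return self.delta_grid.ndim

    def central_slice(self) -> "RefractiveMap":
        """The central 2-D cross-section of a 3-D map (identity for 2-D)."""
        if self.ndim == 2:
            return self
        h = self.delta_grid.shape[0] // 2
        return RefractiveMap(
            delta_grid=np.array(self.delta_grid[h]),
            beta_grid=np.array(self.beta_grid[h]),
            pixel_size=self.pixel_size,
            stage_label=self.stage_label,
            wall_mask=np.array(self.wall_mask[h]),
            meta=dict(self.meta, central_slice_of=self.delta_grid.shape[0]),
        )


def _polar_grids(size: int):
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    r = np.hypot(y - c, x - c)
    theta = np.arctan2(y - c, x - c)
    return r, theta


def _boundary_profile(theta: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Random smooth radial perturbation r(theta) from Fourier coefficients.

    ``coeffs`` has shape (n_harmonics, 2) of (cos, sin) amplitudes for
    harmonics k = 2..n_harmonics+1 (k=0,1 excluded to keep area and center).
    """
    out = np.zeros_like(theta)
    for i, (a, b) in enumerate(coeffs):
        k = i + 2
        out += a * np.cos(k * theta) + b * np.sin(k * theta)
    return out


_N_HARMONICS = 6


def _draw_boundary_coeffs(rng: np.random.Generator, amplitude: float) -> np.ndarray:
    # Split total variance evenly across harmonics and cos/sin parts.
    scale = amplitude / np.sqrt(2 * _N_HARMONICS)
    return rng.normal(0.0, scale, size=(_N_HARMONICS, 2))


def _check_geometry(size: int, spec: StageTextureSpec, cfg: PhysicsConfig,
                    outer_radius_frac: float) -> tuple[float, float]:
    if size < 64:
        raise GeometryError(f"phantom size must be >= 64 pixels, got {size}")
    r_outer = outer_radius_frac * size * cfg.pixel_size
    t_px = spec.wall_thickness / cfg.pixel_size
    if spec.wall_thickness >= r_outer:
        raise GeometryError(
            f"wall thickness {spec.wall_thickness:.3g} m exceeds the phantom "
            f"outer radius {r_outer:.3g} m")
    if t_px < 2:
        raise GeometryError("wall thinner than 2 pixels; increase size or thickness")
    return r_outer, t_px


def _wall_occupancy(r: np.ndarray, r_in: np.ndarray, r_out: np.ndarray,
                    pixel_size: float) -> np.ndarray:
    """Partial-volume wall occupancy in [0, 1].

    A binary in/out mask would voxelize the wall surface into single-pixel
    phase steps of tens of radians, flooding the projection with artificial
    high-frequency speckle; a linear ramp one pixel wide across each
    boundary gives the smooth edge profile of a real tissue surface while
    keeping genuine edge enhancement at the borders.
    """
    inner = np.clip((r - r_in) / pixel_size + 0.5, 0.0, 1.0)
    outer = np.clip((r_out - r) / pixel_size + 0.5, 0.0, 1.0)
    return inner * outer


def _nodule_profile(theta: np.ndarray, rng: np.random.Generator, count: int,
                    depth: float, width_rad: float = 0.18) -> np.ndarray:
    """Inward bumps on the inner boundary: local wall thickening (hyperplasia)."""
    prof = np.zeros_like(theta)
    centers = rng.uniform(-np.pi, np.pi, size=count)
    for th0 in centers:
        d = np.angle(np.exp(1j * (theta - th0)))  # wrapped angular distance
        prof += depth * np.exp(-0.5 * (d / width_rad) ** 2)
    return prof


def make_stage_phantom(stage: Stage, size: int, spec: StageTextureSpec | None = None,
                       cfg: PhysicsConfig | None = None,
                       tissue: TissueConstants | None = None,
                       outer_radius_frac: float = 0.40) -> RefractiveMap:
    """Generate a 2-D annular cross-section phantom for one stage.

    The wall is the region between two roughness-perturbed circles; inside it,
    delta is the nominal tissue value plus a stationary Gaussian random field
    (zero mean inside the wall, standard deviation ``spec.roughness_amplitude``,
    correlation length ``spec.roughness_correlation_length``).  beta carries the
    same relative fluctuation (density fluctuations modulate phase and
    absorption together).  The lumen and exterior are air (delta = beta = 0).

    Identical arguments produce bit-identical grids.
    """
    stage = Stage(stage)
    cfg = cfg or PhysicsConfig()
    tissue = tissue or TissueConstants()
    spec = spec or DEFAULT_STAGE_TABLE[stage]
    r_outer, _ = _check_geometry(size, spec, cfg, outer_radius_frac)
    rng = np.random.default_rng([int(spec.seed), stage.index, 2])

    r, theta = _polar_grids(size)
    r = r * cfg.pixel_size

    out_coeffs = _draw_boundary_coeffs(rng, spec.boundary_amplitude)
    in_coeffs = _draw_boundary_coeffs(rng, spec.boundary_amplitude)
    r_out = r_outer + _boundary_profile(theta, out_coeffs)
    r_in = (r_outer - spec.wall_thickness) + _boundary_profile(theta, in_coeffs)
    if spec.nodule_count:
        r_in = r_in - _nodule_profile(theta, rng, spec.nodule_count,
                                      depth=0.8 * spec.wall_thickness)
    r_in = np.clip(r_in, 2 * cfg.pixel_size, None)
    occ = _wall_occupancy(r, r_in, r_out, cfg.pixel_size)
    wall = occ > 0.5
    if not wall.any():
        raise GeometryError("generated wall mask is empty; check geometry")

    sigma_px = spec.roughness_correlation_length / cfg.pixel_size
    fluct = gaussian_filter(rng.standard_normal((size, size)), sigma=sigma_px)
    fluct = fluct - fluct[wall].mean()
    sd = fluct[wall].std()
    if sd > 0:
        fluct = fluct / sd  # unit std inside the wall

    delta_t = tissue.delta(cfg)
    beta_t = tissue.beta(cfg)
    rel = 1.0 + (spec.roughness_amplitude / delta_t) * fluct
    np.clip(rel, 0.0, None, out=rel)
    delta = delta_t * occ * rel
    beta = beta_t * occ * rel

    return RefractiveMap(delta, beta, cfg.pixel_size, stage, wall,
                         meta={"seed": spec.seed, "size": size,
                               "outer_radius_frac": outer_radius_frac})


def make_stage_volume(stage: Stage, size: int, height: int,
                      spec: StageTextureSpec | None = None,
                      cfg: PhysicsConfig | None = None,
                      tissue: TissueConstants | None = None,
                      outer_radius_frac: float = 0.40) -> RefractiveMap:
    """Generate a quasi-3-D tubular specimen: ``(height, size, size)`` grids.

    Each horizontal slice is an annulus whose boundary-perturbation Fourier
    coefficients drift smoothly along the tube axis (correlation ~1/6 of the
    height), so the projected radiograph shows an extended, gently varying
    organ silhouette.  The intra-wall fluctuation field is 3-D correlated
    with the same in-plane correlation length.  Stored as float32.
    """
    stage = Stage(stage)
    cfg = cfg or PhysicsConfig()
    tissue = tissue or TissueConstants()
    spec = spec or DEFAULT_STAGE_TABLE[stage]
    if height < 64:
        raise GeometryError(f"volume height must be >= 64 pixels, got {height}")
    r_outer, _ = _check_geometry(size, spec, cfg, outer_radius_frac)
    rng = np.random.default_rng([int(spec.seed), stage.index, 3])

    r, theta = _polar_grids(size)
    r = (r * cfg.pixel_size).astype(np.float32)

    # Boundary coefficients drifting along the tube axis.
    axial_sigma = height / 6.0
    def axial_coeffs(amplitude: float) -> np.ndarray:
        raw = rng.standard_normal((height, _N_HARMONICS, 2))
        smooth = gaussian_filter1d(raw, sigma=axial_sigma, axis=0)
        smooth /= max(smooth.std(), 1e-12)
        return smooth * (amplitude / np.sqrt(2 * _N_HARMONICS))

    out_coeffs = axial_coeffs(spec.boundary_amplitude)
    in_coeffs = axial_coeffs(spec.boundary_amplitude)
    # Gentle axial modulation of the outer radius (+-4%) so the silhouette
    # is an organ-like tube rather than a perfect cylinder.
    radius_mod = gaussian_filter1d(rng.standard_normal(height), sigma=axial_sigma)
    radius_mod /= max(radius_mod.std(), 1e-12)
    radius_mod = 1.0 + 0.04 * radius_mod

    nodule_theta = rng.uniform(-np.pi, np.pi, size=spec.nodule_count)
    nodule_y = rng.uniform(0.2 * height, 0.8 * height, size=spec.nodule_count)
    nodule_extent = 0.15 * height

    occ = np.empty((height, size, size), dtype=np.float32)
    for y in range(height):
        r_out = r_outer * radius_mod[y] + _boundary_profile(theta, out_coeffs[y])
        r_in = (r_outer * radius_mod[y] - spec.wall_thickness
                + _boundary_profile(theta, in_coeffs[y]))
        for th0, y0 in zip(nodule_theta, nodule_y):
            d = np.angle(np.exp(1j * (theta - th0)))
            axial = np.exp(-0.5 * ((y - y0) / nodule_extent) ** 2)
            r_in = r_in - 0.8 * spec.wall_thickness * axial * np.exp(-0.5 * (d / 0.18) ** 2)
        r_in = np.clip(r_in, 2 * cfg.pixel_size, None)
        occ[y] = _wall_occupancy(r, r_in, r_out, cfg.pixel_size)
    wall = occ > 0.5
    if not wall.any():
        raise GeometryError("generated wall mask is empty; check geometry")

    sigma_px = spec.roughness_correlation_length / cfg.pixel_size
    fluct = gaussian_filter(
        rng.standard_normal((height, size, size)).astype(np.float32),
        sigma=sigma_px)
    inside = fluct[wall]
    fluct -= inside.mean()
    sd = inside.std()
    if sd > 0:
        fluct /= sd

    delta_t = tissue.delta(cfg)
    beta_t = tissue.beta(cfg)
    rel = 1.0 + (spec.roughness_amplitude / delta_t) * fluct
    np.clip(rel, 0.0, None, out=rel)
    delta = (delta_t * occ * rel).astype(np.float32)
    beta = (beta_t * occ * rel).astype(np.float32)

    return RefractiveMap(delta, beta, cfg.pixel_size, stage, wall,
                         meta={"seed": spec.seed, "size": size, "height": height,
                               "outer_radius_frac": outer_radius_frac})
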