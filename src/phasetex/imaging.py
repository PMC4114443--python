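"""In-line (propagation-based) phase-contrast projection imaging.

A monochromatic plane wave of unit amplitude crosses the specimen; the exit
field at each detector bin is

    u(x) = exp(-i * (2 pi / lambda) * Int delta dz) * exp(-(2 pi / lambda) * Int beta dz),

i.e. a thin-object transmission built from line integrals of the refractive
decrements along parallel rays.  Free-space propagation over the
specimen-to-detector distance (85 cm by default) is computed with a
band-limited angular-spectrum kernel — exact for free space, no paraxial
approximation — and converts phase gradients into intensity fringes (edge
enhancement), the contrast mechanism of in-line phase imaging.  Detection
scales intensity to an expected photon count, applies Poisson noise and
quantizes linearly to 8 bits.

Geometry: parallel beams, rotation about the grid center, angles in degrees
counter-clockwise, detector axis horizontal at 0 degrees; line integrals use
bilinear interpolation (the same convention as :func:`skimage.transform.radon`,
so sinograms round-trip exactly through the FBP module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import radon

from .errors import ConfigError, DomainError, SamplingError
from .phantom import RefractiveMap
from .physics import PhysicsConfig


@dataclass
class ComplexField:
    """A coherent scalar wavefield sampled on the detector grid (1-D or 2-D)."""

    data: np.ndarray
    pixel_size: float
    wavelength: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if not np.all(np.isfinite(self.data)):
            raise DomainError("wavefield contains non-finite values")

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2

    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class ProjectionImage:
    """A projection image: 8-bit levels after quantization, floats before."""

    data: np.ndarray
    angle: float
    pixel_size: float
    meta: dict = field(default_factory=dict)


@dataclass
class Sinogram:
    """Ordered stack of 1-D projections, one row per rotation angle.

    ``data`` has shape (n_angles, n_detector_bins); ``angles`` are strictly
    increasing, uniformly spaced, in [0, 180) degrees.
    """

    data: np.ndarray
    angles: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        _check_angles(self.angles)
        if self.data.shape[0] != self.angles.size:
            raise DomainError("sinogram row count must match the angle list")


def _check_angles(angles: np.ndarray) -> None:
    if angles.ndim != 1 or angles.size < 1:
        raise DomainError("angles must be a 1-D, nonempty sequence")
    if np.any(angles < 0) or np.any(angles >= 180):
        raise DomainError("angles must lie in [0, 180) degrees")
    if angles.size > 1:
        steps = np.diff(angles)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise DomainError("angles must be strictly increasing and uniformly spaced")


def uniform_angles(n: int) -> np.ndarray:
    """n uniformly spaced view angles covering [0, 180) degrees."""
    if n < 1:
        raise DomainError("need at least one angle")
    return np.linspace(0.0, 180.0, n, endpoint=False)


def paper_angles() -> np.ndarray:
    """The acquisition protocol's angle grid: 0.1-degree steps over [0, 180)."""
    return np.arange(0.0, 180.0, 0.1)


def line_integrals(rmap: RefractiveMap, angle: float) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-ray path integrals of delta and beta at one view angle (m).

    For a 2-D map the result is a pair of 1-D detector rows; for a 3-D
    volume, a pair of 2-D images (height x detector).
    """
    if not 0 <= angle < 180:
        raise DomainError(f"angle must be in [0, 180), got {angle}")
    px = rmap.pixel_size
    if rmap.ndim == 2:
        th = np.array([angle], dtype=float)
        pd = radon(rmap.delta_grid.astype(float), theta=th)[:, 0] * px
        pb = radon(rmap.beta_grid.astype(float), theta=th)[:, 0] * px
        return pd, pb
    delta, beta = rmap.delta_grid, rmap.beta_grid
    if angle != 0.0:
        # -angle with axes=(2, 1) matches skimage.transform.radon's convention.
        delta = ndimage.rotate(delta, -angle, axes=(2, 1), reshape=False, order=1)
        beta = ndimage.rotate(beta, -angle, axes=(2, 1), reshape=False, order=1)
    pd = delta.sum(axis=1, dtype=np.float64) * px
    pb = beta.sum(axis=1, dtype=np.float64) * px
    return pd, pb


def transmit(rmap: RefractiveMap, angle: float, cfg: PhysicsConfig) -> ComplexField:
    """Exit wavefield of a unit-amplitude plane wave after the specimen."""
    path_delta, path_beta = line_integrals(rmap, angle)
    k = 2.0 * np.pi / cfg.wavelength
    u = np.exp(-k * path_beta) * np.exp(-1j * k * path_delta)
    return ComplexField(u, rmap.pixel_size, cfg.wavelength)


def aliasing_limit(n: int, pixel_size: float, wavelength: float) -> float:
    """Maximum propagation distance for alias-free single-FFT angular spectrum."""
    return n * pixel_size**2 / wavelength


def fresnel_propagate(fld: ComplexField, z: float) -> ComplexField:
    """Free-space propagation by a band-limited angular-spectrum kernel.

    ``z = 0`` returns a bit-identical copy.  Negative ``z`` applies the exact
    inverse kernel (back-propagation).  Frequencies beyond the band limit
    1 / (lambda * sqrt((2 * z * df)^2 + 1)) are suppressed to avoid kernel
    aliasing; the classical sampling bound z <= N * dx^2 / lambda is checked
    and violation raises :class:`SamplingError` with an advisory.
    """
    if fld.data.ndim not in (1, 2):
        raise DomainError("field must be 1-D or 2-D")
    if z == 0:
        return ComplexField(fld.data.copy(), fld.pixel_size, fld.wavelength)
    lam, dx = fld.wavelength, fld.pixel_size
    n_min = min(fld.data.shape)
    z_max = aliasing_limit(n_min, dx, lam)
    if abs(z) > z_max:
        raise SamplingError(
            f"|z| = {abs(z):.3g} m exceeds the angular-spectrum aliasing bound "
            f"{z_max:.3g} m for N = {n_min}, dx = {dx:.3g} m, lambda = {lam:.3g} m; "
            f"pad the field or reduce the propagation distance")

    axes_f = [np.fft.fftfreq(n, d=dx) for n in fld.data.shape]
    if fld.data.ndim == 1:
        f2 = axes_f[0] ** 2
        df = 1.0 / (fld.data.shape[0] * dx)
        band = np.abs(axes_f[0]) <= 1.0 / (lam * np.sqrt((2 * z * df) ** 2 + 1))
    else:
        fy, fx = np.meshgrid(axes_f[0], axes_f[1], indexing="ij")
        f2 = fy**2 + fx**2
        dfy = 1.0 / (fld.data.shape[0] * dx)
        dfx = 1.0 / (fld.data.shape[1] * dx)
        band = ((np.abs(fy) <= 1.0 / (lam * np.sqrt((2 * z * dfy) ** 2 + 1)))
                & (np.abs(fx) <= 1.0 / (lam * np.sqrt((2 * z * dfx) ** 2 + 1))))

    arg = 1.0 - (lam**2) * f2
    propagating = arg > 0
    kz = np.where(propagating, np.sqrt(np.clip(arg, 0, None)), 0.0)
    kernel = np.where(propagating & band,
                      np.exp(2j * np.pi / lam * z * kz), 0.0)
    spec = np.fft.fftn(fld.data)
    out = np.fft.ifftn(spec * kernel)
    return ComplexField(out, dx, lam)


def quantize_to_uint8(intensity: np.ndarray, mode: str = "minmax",
                      ref_range: tuple[float, float] | None = None,
                      invert: bool = False) -> tuple[np.ndarray, dict]:
    """Linear quantization of an intensity image to 256 gray levels.

    ``minmax`` rescales each image by its own extrema (a constant image maps
    to the top level 255); ``fixed`` uses ``ref_range = (lo, hi)`` so gray
    levels are comparable across images.  ``invert=True`` applies the
    radiographic display polarity (attenuating structure rendered bright,
    as in a clinical film where bone is white).  The applied scaling is
    returned as metadata because texture features depend on it.
    """
    intensity = np.asarray(intensity, dtype=float)
    if mode == "minmax":
        lo, hi = float(intensity.min()), float(intensity.max())
        if hi <= lo:
            return np.full(intensity.shape, 255, dtype=np.uint8), {
                "mode": "minmax", "lo": lo, "hi": hi, "invert": invert,
                "degenerate": True}
    elif mode == "fixed":
        if ref_range is None:
            raise ConfigError("fixed quantization requires ref_range=(lo, hi)")
        lo, hi = map(float, ref_range)
        if hi <= lo:
            raise ConfigError("ref_range must satisfy hi > lo")
    else:
        raise ConfigError(f"unknown quantization mode {mode!r}")
    scaled = np.clip((intensity - lo) / (hi - lo), 0.0, 1.0)
    levels = np.rint(scaled * 255).astype(np.uint8)
    if invert:
        levels = (255 - levels).astype(np.uint8)
    return levels, {"mode": mode, "lo": lo, "hi": hi, "invert": invert,
                    "degenerate": False}


def acquire_projection(rmap: RefractiveMap, angle: float, cfg: PhysicsConfig,
                       seed: int | None = None, noise: bool = True,
                       quantization: str = "minmax",
                       ref_range: tuple[float, float] | None = None,
                       invert: bool = False, quantize: bool = True) -> ProjectionImage:
    """Simulate one detected projection image.

    intensity = |propagate(transmit(map, angle), z)|^2, scaled to the expected
    per-pixel photon count, Poisson-sampled (seeded) and linearly quantized to
    8 bits.  ``noise=False`` gives the infinite-photon-count limit;
    ``quantize=False`` returns the float photon-count image.
    """
    if not cfg.photon_count > 0:
        raise ConfigError("photon_count must be positive")
    fld = fresnel_propagate(transmit(rmap, angle, cfg), cfg.propagation_distance)
    expected = fld.intensity * cfg.photon_count
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    meta = {"angle": angle, "z": cfg.propagation_distance,
            "wavelength": cfg.wavelength, "photon_count": cfg.photon_count,
            "noise": noise, "seed": seed, "stage": rmap.stage_label.value}
    if not quantize:
        meta["quantization"] = None
        return ProjectionImage(counts, angle, rmap.pixel_size, meta)
    levels, qmeta = quantize_to_uint8(counts, mode=quantization,
                                      ref_range=ref_range, invert=invert)
    meta["quantization"] = qmeta
    return ProjectionImage(levels, angle, rmap.pixel_size, meta)


def acquire_sinogram(rmap: RefractiveMap, angles: np.ndarray, cfg: PhysicsConfig,
                     seed: int | None = None, noise: bool = True) -> Sinogram:
    """Simulate a full rotation series: one central detector row per angle.

    For a 3-D map the central slice is used.  Rows are detected photon counts
    (not 8-bit quantized), so -log preprocessing against the blank-scan level
    ``cfg.photon_count`` remains meaningful for reconstruction.
    """
    angles = np.asarray(angles, dtype=float)
    _check_angles(angles)
    slab = rmap.central_slice() if rmap.ndim == 3 else rmap
    k = 2.0 * np.pi / cfg.wavelength
    px = slab.pixel_size
    pd = radon(slab.delta_grid.astype(float), theta=angles) * px  # (ndet, nang)
    pb = radon(slab.beta_grid.astype(float), theta=angles) * px
    rng = np.random.default_rng(seed)
    rows = np.empty((angles.size, slab.delta_grid.shape[0]), dtype=float)
    for i in range(angles.size):
        u = np.exp(-k * pb[:, i]) * np.exp(-1j * k * pd[:, i])
        fld = fresnel_propagate(ComplexField(u, px, cfg.wavelength),
                                cfg.propagation_distance)
        expected = fld.intensity * cfg.photon_count
        rows[i] = rng.poisson(expected) if noise else expected
    meta = {"I0": cfg.photon_count, "z": cfg.propagation_distance,
            "wavelength": cfg.wavelength, "noise": noise, "seed": seed,
            "stage": slab.stage_label.value}
    return Sinogram(rows, angles, px, meta)
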