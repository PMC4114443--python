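"""X-ray optical constants for weakly refracting media.

For hard X-rays the complex refractive index of a material is written

    n = 1 - delta - i * beta,

where ``delta`` (the refractive decrement) governs the phase shift a wave
accumulates in the material and ``beta`` governs absorption.  For light
elements at ~10 keV, ``delta`` exceeds ``beta`` by roughly three orders of
magnitude, which is why propagation-based phase contrast resolves soft
tissue that absorption radiography cannot.

The two decrements map onto measurable quantities:

    delta = rho_e * r_e * lambda**2 / (2 * pi)      (electron density rho_e)
    mu    = 4 * pi * beta / lambda                  (linear attenuation)
    P     = 2 * pi * delta / lambda                 (phase shift per length)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError

#: Classical electron radius (m).
R_E = 2.8179403262e-15

#: h * c expressed in keV * m, so that wavelength_m = HC_KEV_M / energy_keV.
HC_KEV_M = 1.2398419843320026e-09


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength (m) for a beam energy in keV (13 keV -> ~0.954 A)."""
    if energy_kev <= 0:
        raise ConfigError(f"beam energy must be positive, got {energy_kev} keV")
    return HC_KEV_M / energy_kev


def energy_from_wavelength(wavelength: float) -> float:
    """Photon energy (keV) for a wavelength in meters."""
    if wavelength <= 0:
        raise ConfigError(f"wavelength must be positive, got {wavelength} m")
    return HC_KEV_M / wavelength


@dataclass(frozen=True)
class PhysicsConfig:
    """Beamline and detector geometry of the imaging experiment.

    Defaults follow the synchrotron setup the pipeline emulates: a 13 keV
    monochromatic beam, an 85 cm specimen-to-detector propagation distance
    and a 9 um detector pixel.  ``photon_count`` is the expected number of
    detected photons per pixel for an unattenuated ray and sets the Poisson
    noise level.
    """

    wavelength: float = HC_KEV_M / 13.0
    electron_radius: float = R_E
    propagation_distance: float = 0.85
    pixel_size: float = 9e-6
    photon_count: float = 1e4

    def __post_init__(self) -> None:
        for name in ("wavelength", "electron_radius", "propagation_distance",
                     "pixel_size", "photon_count"):
            value = getattr(self, name)
            if not value > 0:
                raise ConfigError(f"PhysicsConfig.{name} must be positive, got {value!r}")

    @property
    def energy_kev(self) -> float:
        return energy_from_wavelength(self.wavelength)

    @classmethod
    def from_energy(cls, energy_kev: float, **kwargs) -> "PhysicsConfig":
        return cls(wavelength=wavelength_from_energy(energy_kev), **kwargs)


def delta_from_electron_density(rho_e, cfg: PhysicsConfig):
    """Refractive decrement delta = rho_e * r_e * lambda^2 / (2 pi).

    ``rho_e`` is the electron density in m^-3 (scalar or array, >= 0).
    """
    rho = np.asarray(rho_e, dtype=float)
    if np.any(rho < 0):
        raise DomainError("electron density must be nonnegative")
    out = rho * cfg.electron_radius * cfg.wavelength**2 / (2.0 * math.pi)
    return out if out.ndim else float(out)


def mu_from_beta(beta, cfg: PhysicsConfig):
    """Linear attenuation coefficient mu = 4 pi beta / lambda (m^-1)."""
    b = np.asarray(beta, dtype=float)
    if np.any(b < 0):
        raise DomainError("beta must be nonnegative")
    out = 4.0 * math.pi * b / cfg.wavelength
    return out if out.ndim else float(out)


def beta_from_mu(mu, cfg: PhysicsConfig):
    """Inverse of :func:`mu_from_beta`: beta = mu * lambda / (4 pi)."""
    m = np.asarray(mu, dtype=float)
    if np.any(m < 0):
        raise DomainError("mu must be nonnegative")
    out = m * cfg.wavelength / (4.0 * math.pi)
    return out if out.ndim else float(out)


def phase_shift_from_delta(delta, cfg: PhysicsConfig):
    """Phase shift per unit length P = 2 pi delta / lambda (rad/m)."""
    d = np.asarray(delta, dtype=float)
    out = 2.0 * math.pi * d / cfg.wavelength
    return out if out.ndim else float(out)
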