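"""Forward model: transmission, Fresnel propagation, detection, sinograms."""

import numpy as np
import pytest

from phasetex import (ComplexField, PhysicsConfig, Stage, acquire_projection,
                      acquire_sinogram, fresnel_propagate, paper_angles,
                      transmit, uniform_angles)
from phasetex.errors import DomainError, SamplingError
from phasetex.imaging import Sinogram, aliasing_limit, quantize_to_uint8

from conftest import make_map


def _disk_map(n=128, r_px=30, delta=1e-7, beta=0.0, pixel_size=9e-6):
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    inside = np.hypot(y - c, x - c) < r_px
    return make_map(delta * inside, beta * inside, pixel_size=pixel_size, mask=inside)


class TestTransmit:
    def test_vacuum_gives_unit_field(self, vacuum_map, physics):
        fld = transmit(vacuum_map, 0.0, physics)
        assert np.allclose(fld.data, 1.0, atol=1e-12)

    def test_pure_phase_object_has_unit_amplitude(self, physics):
        rmap = _disk_map(delta=2e-7, beta=0.0)
        fld = transmit(rmap, 30.0, physics)
        assert np.allclose(np.abs(fld.data), 1.0, atol=1e-9)

    def test_single_pixel_absorber_beer_lambert(self, physics):
        """Intensity along the absorber's ray equals exp(-mu * t), t one pixel."""
        beta = np.zeros((65, 65))
        beta[32, 32] = 1e-9
        rmap = make_map(np.zeros_like(beta), beta)
        fld = transmit(rmap, 0.0, physics)
        mu = 4 * np.pi * 1e-9 / physics.wavelength
        t = rmap.pixel_size
        assert np.abs(fld.data[32]) ** 2 == pytest.approx(np.exp(-mu * t), rel=1e-6)
        off = np.delete(np.abs(fld.data), 32)
        assert np.allclose(off, 1.0, atol=1e-9)

    def test_empty_map_rejected(self, physics):
        with pytest.raises(DomainError):
            make_map(np.zeros((0, 0)), np.zeros((0, 0)))


class TestFresnelPropagate:
    def test_zero_distance_is_identity(self):
        rng = np.random.default_rng(0)
        fld = ComplexField(rng.standard_normal((32, 32))
                           + 1j * rng.standard_normal((32, 32)), 9e-6, 1e-10)
        out = fresnel_propagate(fld, 0.0)
        assert np.array_equal(out.data, fld.data)

    def test_plane_wave_is_eigenfunction(self):
        fld = ComplexField(np.full(256, 1.0 + 0j), 9e-6, 1e-10)
        out = fresnel_propagate(fld, 0.5)
        # unchanged up to a global phase
        phase = out.data[0] / abs(out.data[0])
        assert np.allclose(out.data / phase, 1.0, atol=1e-9)

    def test_gaussian_beam_spreading_matches_closed_form(self):
        """Propagated 1/e half-width follows w(z) = w0 sqrt(1 + (lambda z / pi w0^2)^2)."""
        lam, dx, w0 = 633e-9, 10e-6, 80e-6
        n = 2048
        x = (np.arange(n) - n / 2) * dx
        fld = ComplexField(np.exp(-(x / w0) ** 2), dx, lam)
        z = 0.03
        out = fresnel_propagate(fld, z)
        amp = np.abs(out.data)
        # measured width from the second moment of |u|^2 (Gaussian: <x^2> = w^2/4)
        w_meas = 2 * np.sqrt((x**2 * amp**2).sum() / (amp**2).sum())
        w_true = w0 * np.sqrt(1 + (lam * z / (np.pi * w0**2)) ** 2)
        assert w_meas == pytest.approx(w_true, rel=0.01)

    def test_energy_conservation_pure_phase(self, physics):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter
        phase = gaussian_filter(rng.standard_normal((256, 256)), 3) * 2.0
        fld = ComplexField(np.exp(1j * phase), physics.pixel_size, physics.wavelength)
        out = fresnel_propagate(fld, physics.propagation_distance)
        assert out.total_intensity() == pytest.approx(fld.total_intensity(), rel=1e-6)

    def test_reciprocity(self, physics):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter
        phase = gaussian_filter(rng.standard_normal((128, 128)), 2)
        fld = ComplexField(np.exp(1j * phase), physics.pixel_size, physics.wavelength)
        back = fresnel_propagate(fresnel_propagate(fld, 0.85), -0.85)
        rms = np.sqrt(np.mean(np.abs(back.data - fld.data) ** 2))
        assert rms < 1e-8

    def test_aliasing_bound_is_enforced(self):
        fld = ComplexField(np.ones(64), 1e-6, 1e-10)
        z_max = aliasing_limit(64, 1e-6, 1e-10)
        with pytest.raises(SamplingError):
            fresnel_propagate(fld, 2 * z_max)


class TestDetection:
    def test_edge_fringes_appear_only_after_propagation(self, physics):
        """The hallmark of in-line phase contrast: a pure-phase disk is invisible
        at contact (z = 0) and shows boundary fringes at z = 0.85 m."""
        rmap = _disk_map(n=256, r_px=60, delta=2e-8)
        at_contact = PhysicsConfig(wavelength=physics.wavelength,
                                   propagation_distance=1e-12,
                                   pixel_size=physics.pixel_size)
        img0 = acquire_projection(rmap, 0.0, at_contact, noise=False, quantize=False)
        img85 = acquire_projection(rmap, 0.0, physics, noise=False, quantize=False)
        assert img85.data.std() > 10 * img0.data.std()
        # edge contrast: bright/dark excursion at the boundary
        assert img85.data.max() > 1.02 * at_contact.photon_count
        assert img85.data.min() < 0.98 * at_contact.photon_count

    def test_vacuum_map_quantizes_to_top_level(self, vacuum_map, physics):
        img = acquire_projection(vacuum_map, 0.0, physics, noise=False)
        assert img.data.dtype == np.uint8
        assert np.all(img.data == 255)

    def test_noise_draw_is_seeded(self, physics):
        rmap = _disk_map(beta=1e-9)
        a = acquire_projection(rmap, 0.0, physics, seed=7)
        b = acquire_projection(rmap, 0.0, physics, seed=7)
        c = acquire_projection(rmap, 0.0, physics, seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_quantization_modes(self):
        img = np.array([[0.0, 5.0], [10.0, 10.0]])
        levels, meta = quantize_to_uint8(img, "minmax")
        assert levels[0, 0] == 0 and levels[1, 0] == 255
        inv, _ = quantize_to_uint8(img, "minmax", invert=True)
        assert np.array_equal(inv, 255 - levels)
        fixed, meta = quantize_to_uint8(img, "fixed", ref_range=(0.0, 20.0))
        assert fixed[1, 1] == round(255 * 0.5)
        const, meta = quantize_to_uint8(np.full((3, 3), 4.2), "minmax")
        assert np.all(const == 255) and meta["degenerate"]


class TestSinogram:
    def test_symmetric_phantom_has_identical_rows(self, physics):
        """All projections of a rotationally symmetric object agree up to the
        pixel-grid discretization of the rotated line integrals."""
        from scipy.ndimage import gaussian_filter
        n, r_px = 128, 30
        c = (n - 1) / 2.0
        y, x = np.mgrid[0:n, 0:n]
        occ = gaussian_filter(np.clip(r_px - np.hypot(y - c, x - c) + 0.5, 0, 1), 1.0)
        rmap = make_map(5e-8 * occ, 5e-10 * occ, mask=occ > 0.5)
        sino = acquire_sinogram(rmap, uniform_angles(8), physics, noise=False)
        spread = np.abs(sino.data - sino.data[0]).max()
        assert spread < 0.03 * physics.photon_count

    def test_vacuum_sinogram_is_constant(self, vacuum_map, physics):
        sino = acquire_sinogram(vacuum_map, uniform_angles(4), physics, noise=False)
        assert np.allclose(sino.data, physics.photon_count, rtol=1e-9)

    def test_nonuniform_angles_rejected(self, vacuum_map, physics):
        with pytest.raises(DomainError):
            acquire_sinogram(vacuum_map, np.array([0.0, 1.0, 3.0]), physics)
        with pytest.raises(DomainError):
            acquire_sinogram(vacuum_map, np.array([0.0, 90.0, 180.0]), physics)

    def test_acquisition_protocol_angle_grid(self):
        ang = paper_angles()
        assert ang.size == 1800
        assert ang[0] == 0.0 and ang[-1] == pytest.approx(179.9)
        assert np.allclose(np.diff(ang), 0.1)

    def test_row_count_must_match_angles(self):
        with pytest.raises(DomainError):
            Sinogram(np.zeros((3, 8)), uniform_angles(4), 9e-6)
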