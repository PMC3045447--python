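"""Wave-optics forward model: line integrals, transmission, propagation."""

import numpy as np
import pytest
from scipy.special import fresnel

from xpcilung.forward_model import (
    BeamGeometry, PhaseAbsorptionMaps, ProjectionSet, acquire_ct,
    bin_to_detector, energy_to_wavelength, project_mu_phi,
    propagate_angular_spectrum, propagate_weak_object, transmission,
)
from xpcilung.materials import build_material_table
from xpcilung.phantom import RefractiveVolume

LAM18_UM = energy_to_wavelength(18.0) * 1.0e-4
Z_UM = 1.2e6


class TestWavelength:
    def test_known_values(self):
        assert energy_to_wavelength(18.0) == pytest.approx(0.68880, abs=5e-6)
        assert energy_to_wavelength(12.39842) == pytest.approx(1.0, abs=1e-5)
        assert energy_to_wavelength(36.0) == pytest.approx(
            energy_to_wavelength(18.0) / 2.0)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            energy_to_wavelength(0.0)

    def test_geometry_hc_product_invariant(self):
        g = BeamGeometry(energy_keV=18.0)
        assert g.wavelength_angstrom * g.energy_keV == pytest.approx(
            12.3984, abs=5e-4)


def uniform_volume(delta, beta, n=32, pitch=4.0):
    return RefractiveVolume(delta=np.full((n, n, n), delta, np.float32),
                            beta=np.full((n, n, n), beta, np.float32),
                            pitch_um=pitch, energy_keV=18.0)


class TestProjection:
    def test_vacuum_volume_projects_to_zero(self):
        geom = BeamGeometry()
        maps = project_mu_phi(uniform_volume(0.0, 0.0), 30.0, geom)
        assert np.all(maps.mu == 0)
        assert np.all(maps.phi == 0)

    def test_uniform_slab_matches_closed_form(self):
        """mu = (4 pi / lambda) beta t and phi = -(2 pi / lambda) delta t
        for a homogeneous slab of thickness t at normal incidence."""
        t_um = 32 * 4.0
        table = build_material_table(18.0)
        d, b = table.delta("soft_tissue"), table.beta("soft_tissue")
        geom = BeamGeometry()
        maps = project_mu_phi(uniform_volume(d, b), 0.0, geom)
        mu_exp = 4.0 * np.pi / LAM18_UM * b * t_um
        phi_exp = -2.0 * np.pi / LAM18_UM * d * t_um
        assert maps.mu == pytest.approx(mu_exp, rel=1e-3)
        assert maps.phi == pytest.approx(phi_exp, rel=1e-3)
        assert np.all(maps.mu >= 0)
        assert np.all(maps.phi <= 0)

    @pytest.mark.parametrize("angle", [0.0, 37.0, 90.0])
    def test_cylinder_projects_to_chord_profile(self, angle):
        """A uniform cylinder projects to 2 sqrt(R^2 - s^2) at any angle."""
        n, pitch, R = 128, 4.0, 180.0
        c = (n - 1) / 2.0 * pitch + pitch / 2.0
        coords = (np.arange(n) + 0.5) * pitch
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        disk = ((yy - c) ** 2 + (xx - c) ** 2 <= R**2)
        beta = np.broadcast_to(disk * 5.5e-10, (8, n, n)).astype(np.float32)
        vol = RefractiveVolume(delta=np.zeros_like(beta), beta=beta.copy(),
                               pitch_um=pitch, energy_keV=18.0)
        maps = project_mu_phi(vol, angle, BeamGeometry())
        s = coords - c
        chord = 2.0 * np.sqrt(np.clip(R**2 - s**2, 0.0, None))
        expected = 4.0 * np.pi / LAM18_UM * 5.5e-10 * chord
        inner = np.abs(s) < 0.7 * R
        measured = maps.mu[4]
        assert measured[inner] == pytest.approx(expected[inner], rel=0.02)

    def test_phase_is_linear_in_delta(self):
        vol1 = uniform_volume(3.0e-7, 0.0)
        vol2 = uniform_volume(6.0e-7, 0.0)
        g = BeamGeometry()
        p1 = project_mu_phi(vol1, 10.0, g).phi
        p2 = project_mu_phi(vol2, 10.0, g).phi
        np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-6)


class TestTransmission:
    def test_identity_for_empty_maps(self):
        maps = PhaseAbsorptionMaps(mu=np.zeros((8, 8)), phi=np.zeros((8, 8)),
                                   pitch_um=1.0, angle_deg=0.0)
        np.testing.assert_array_equal(transmission(maps), np.ones((8, 8)))

    def test_beer_lambert_intensity(self):
        """mu = 2 ln 2 halves the amplitude: intensity 1/4."""
        maps = PhaseAbsorptionMaps(mu=np.full((4, 4), 2.0 * np.log(2.0)),
                                   phi=np.zeros((4, 4)), pitch_um=1.0,
                                   angle_deg=0.0)
        q = transmission(maps)
        np.testing.assert_allclose(np.abs(q) ** 2, 0.25, rtol=1e-12)

    def test_pure_phase_object_invisible_at_contact_plane(self):
        maps = PhaseAbsorptionMaps(mu=np.zeros((4, 4)),
                                   phi=np.full((4, 4), -np.pi),
                                   pitch_um=1.0, angle_deg=0.0)
        q = transmission(maps)
        np.testing.assert_allclose(q, -1.0, rtol=1e-12)
        np.testing.assert_allclose(np.abs(q) ** 2, 1.0, rtol=1e-12)


def gaussian_phase_maps(n=256, pitch=2.0, amplitude=-0.05, sigma=40.0):
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    phi = amplitude * np.exp(-(yy**2 + xx**2) * pitch**2 / (2 * sigma**2))
    return PhaseAbsorptionMaps(mu=np.zeros((n, n)), phi=phi, pitch_um=pitch,
                               angle_deg=0.0)


class TestPropagation:
    def test_zero_distance_is_the_identity_on_intensity(self):
        maps = gaussian_phase_maps()
        w = transmission(maps)
        out = propagate_angular_spectrum(w, LAM18_UM, 0.0, maps.pitch_um)
        np.testing.assert_array_equal(out, np.abs(w) ** 2)

    def test_uniform_wave_is_an_eigenfunction(self):
        w = np.ones((64, 64), complex)
        out = propagate_angular_spectrum(w, LAM18_UM, Z_UM, 2.0)
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_free_space_propagation_conserves_energy(self):
        maps = gaussian_phase_maps()
        w = transmission(maps)
        out = propagate_angular_spectrum(w, LAM18_UM, Z_UM, maps.pitch_um)
        total_in = float(np.sum(np.abs(w) ** 2))
        assert float(out.sum()) == pytest.approx(total_in, rel=1e-3)

    def test_undersampled_grid_is_rejected_with_the_pitch_bound(self):
        w = np.ones((64, 64), complex)
        with pytest.raises(ValueError, match="pitch"):
            propagate_angular_spectrum(w, LAM18_UM, Z_UM, 13.0)

    def test_phase_edge_fringe_position_matches_fresnel_closed_form(self):
        """The first diffraction maximum of a half-plane phase edge agrees
        with the Fresnel-integral solution within one sample."""
        n, pitch = 2048, 1.0
        phi0 = -0.5
        x = (np.arange(n) - (n - 1) / 2.0) * pitch
        step = x >= 0.0
        phi = np.where(step, phi0, 0.0)
        w2 = np.broadcast_to(np.exp(1j * phi), (16, n)).copy()
        intensity = propagate_angular_spectrum(w2, LAM18_UM, Z_UM, pitch)[8]
        # closed form: E(x) = propagated unit half-plane via Fresnel C, S
        v = x * np.sqrt(2.0 / (LAM18_UM * Z_UM))
        S, C = fresnel(v)
        E = ((1.0 - 1j) / 2.0) * ((0.5 + C) + 1j * (0.5 + S))
        U = 1.0 + (np.exp(1j * phi0) - 1.0) * E
        ref = np.abs(U) ** 2
        near = np.abs(x) < 50.0
        i_sim = np.argmax(np.where(near, intensity, -np.inf))
        i_ref = np.argmax(np.where(near, ref, -np.inf))
        assert abs(i_sim - i_ref) <= 1

    def test_weak_object_propagator_matches_exact_in_the_weak_limit(self):
        """RMS discrepancy below 1% of the image contrast for a smooth,
        weak phase object."""
        maps = gaussian_phase_maps(amplitude=-0.05)
        exact = propagate_angular_spectrum(
            transmission(maps), LAM18_UM, Z_UM, maps.pitch_um)
        weak = propagate_weak_object(maps, LAM18_UM, Z_UM)
        contrast = exact.max() - exact.min()
        rms = float(np.sqrt(np.mean((exact - weak) ** 2)))
        assert rms < 0.01 * contrast

    def test_weak_object_trivial_limits(self):
        maps = PhaseAbsorptionMaps(mu=np.zeros((32, 32)),
                                   phi=np.zeros((32, 32)),
                                   pitch_um=2.0, angle_deg=0.0)
        np.testing.assert_allclose(
            propagate_weak_object(maps, LAM18_UM, Z_UM), 1.0, atol=1e-12)
        mu = np.random.default_rng(0).uniform(0.0, 0.05, (32, 32))
        maps2 = PhaseAbsorptionMaps(mu=mu, phi=np.zeros_like(mu),
                                    pitch_um=2.0, angle_deg=0.0)
        np.testing.assert_allclose(
            propagate_weak_object(maps2, LAM18_UM, 0.0), 1.0 - mu, atol=1e-9)

    def test_air_tissue_cylinder_shows_edge_enhancement_only_downstream(self):
        """Overshoot-undershoot pair straddles the geometric edge at
        z = 1.2 m and is absent at the contact plane."""
        table = build_material_table(18.0)
        d, b = table.delta("soft_tissue"), table.beta("soft_tissue")
        n, pitch, R = 1024, 2.0, 200.0
        x = (np.arange(n) - (n - 1) / 2.0) * pitch
        chord = 2.0 * np.sqrt(np.clip(R**2 - x**2, 0.0, None))
        mu = np.broadcast_to(4 * np.pi / LAM18_UM * b * chord, (16, n)).copy()
        phi = np.broadcast_to(-2 * np.pi / LAM18_UM * d * chord, (16, n)).copy()
        maps = PhaseAbsorptionMaps(mu=mu, phi=phi, pitch_um=pitch, angle_deg=0.0)
        w = transmission(maps)
        at_z = propagate_angular_spectrum(w, LAM18_UM, Z_UM, pitch)[8]
        at_0 = propagate_angular_spectrum(w, LAM18_UM, 0.0, pitch)[8]
        near_edge = np.abs(np.abs(x) - R) < 30.0
        background = 1.0
        assert at_z[near_edge].max() > 1.1 * background     # overshoot
        assert at_z[near_edge].min() < 0.9 * at_0[near_edge].min()  # undershoot
        # contact plane: pure attenuation, intensity within [min chord, 1]
        assert at_0[near_edge].max() <= background + 1e-9


class TestDetectorAndAcquisition:
    def test_area_weighted_binning_preserves_the_mean(self, rng):
        img = rng.uniform(size=(130, 130))
        binned, offsets = bin_to_detector(img, 2.0, 13.0)
        assert binned.shape == (20, 20)
        assert binned.mean() == pytest.approx(img[:130, :130].mean(), rel=0.05)
        assert offsets[0] == pytest.approx((260 - 20 * 13) / 2.0)

    def test_single_vacuum_view_without_noise_equals_the_flat_field(self):
        vol = uniform_volume(0.0, 0.0, n=64, pitch=2.0)
        geom = BeamGeometry(n_angles=1, photons_per_pixel=0.0)
        with pytest.warns(UserWarning, match="noise disabled"):
            ps = acquire_ct(vol, geom, seed=0)
        np.testing.assert_allclose(ps.images[0], ps.flat, rtol=1e-6)

    def test_default_experiment_angle_grid(self):
        g = BeamGeometry()
        assert g.n_angles == 1296
        assert len(g.angles_deg) == 1296
        assert np.diff(g.angles_deg)[0] == pytest.approx(180.0 / 1296.0)
        assert g.angles_deg[-1] < 180.0

    def test_acquisition_is_deterministic_under_a_fixed_seed(self):
        table = build_material_table(18.0)
        vol = uniform_volume(table.delta("soft_tissue"),
                             table.beta("soft_tissue"), n=32, pitch=4.0)
        geom = BeamGeometry(n_angles=3)
        a = acquire_ct(vol, geom, seed=42)
        b = acquire_ct(vol, geom, seed=42)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.flat, b.flat)

    def test_angles_must_increase_within_the_half_turn(self):
        flat = np.ones((4, 4), np.float32)
        imgs = np.ones((2, 4, 4), np.float32)
        with pytest.raises(ValueError, match="angles"):
            ProjectionSet(images=imgs, angles_deg=np.array([0.0, 190.0]),
                          flat=flat, geometry=BeamGeometry(n_angles=2))
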