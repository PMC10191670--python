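"""Zernike wavefronts, Fourier PSFs and spectrally weighted kernels."""

import numpy as np
import pytest
from scipy.special import j1

from opticorr.exceptions import SamplingError, ValidationError
from opticorr.spectra import SpectralCurve
from opticorr.wavefront import (
    OpticalConfig,
    Prescription,
    ZernikeCoefficients,
    build_lms_kernel,
    build_psf_stack,
    delta_lms_kernel,
    osa_index,
    osa_to_nm,
    prescription_to_zernike,
    psf_for_primary,
    psf_for_wavelength,
    psf_second_moment,
    pupil_wavefront,
    zernike_value,
)


class TestZernike:
    def test_piston_is_one(self, rng):
        rho = rng.uniform(0, 1, 20)
        theta = rng.uniform(0, 2 * np.pi, 20)
        assert np.allclose(zernike_value(0, 0, rho, theta), 1.0)

    def test_defocus_closed_form(self):
        assert zernike_value(2, 0, 1.0, 0.3) == pytest.approx(np.sqrt(3))
        assert zernike_value(2, 0, 0.0, 1.1) == pytest.approx(-np.sqrt(3))

    def test_orthonormality_by_quadrature(self):
        """Numerical inner products of the first 10 polynomials over the unit
        disc must reproduce the identity within quadrature error."""
        n_r, n_t = 400, 400
        r_edges = np.linspace(0, 1, n_r + 1)
        r = 0.5 * (r_edges[:-1] + r_edges[1:])
        t = (np.arange(n_t) + 0.5) * 2 * np.pi / n_t
        R, T = np.meshgrid(r, t, indexing="ij")
        dA = (r_edges[1:] ** 2 - r_edges[:-1] ** 2)[:, None] / 2 * (2 * np.pi / n_t)
        basis = [zernike_value(*osa_to_nm(j), R, T) for j in range(10)]
        gram = np.array([[(a * b * dA).sum() / np.pi for b in basis] for a in basis])
        assert np.abs(gram - np.eye(10)).max() <= 1e-3

    def test_invalid_parity_rejected(self):
        with pytest.raises(ValidationError):
            zernike_value(2, 1, 0.5, 0.0)

    def test_osa_index_round_trip(self):
        for j in range(21):
            n, m = osa_to_nm(j)
            assert osa_index(n, m) == j


class TestPrescriptionConversion:
    def test_zero_prescription_is_zero(self):
        c = prescription_to_zernike(Prescription(0.0, 0.0, 0.0), 4.0)
        assert len(c) == 0

    def test_pure_sphere_defocus_magnitude(self):
        """-1.5 D sphere over a 4 mm pupil gives c(2,0) = +0.866 um, i.e. a
        wavefront whose paraboloid curvature is -1.5 D of vergence."""
        c = prescription_to_zernike(Prescription(-1.5, 0.0, 0.0), 4.0)
        assert c.get_nm(2, 0) == pytest.approx(0.866, abs=1e-3)
        # recover the dioptric power from the reconstructed wavefront:
        # W(r) = -M r^2 / 2  (in metres) for a pure-defocus eye
        r_pupil = 2e-3
        rho = np.linspace(0, 1, 101)
        w_um = c.get_nm(2, 0) * np.sqrt(3) * (2 * rho**2 - 1)
        poly = np.polyfit((rho * r_pupil) ** 2, w_um * 1e-6, 1)
        vergence = -2.0 * poly[0]
        assert vergence == pytest.approx(-1.5, rel=1e-6)

    def test_cylinder_axis_sign_flip(self):
        """Rotating a cylinder by 90 degrees negates the J0 astigmatism."""
        c0 = prescription_to_zernike(Prescription(0.0, -1.0, 0.0), 4.0)
        c90 = prescription_to_zernike(Prescription(0.0, -1.0, 90.0), 4.0)
        assert c0.get_nm(2, 2) == pytest.approx(-c90.get_nm(2, 2))
        assert abs(c0.get_nm(2, 2)) > 0

    def test_axis_wraps_into_range(self):
        assert Prescription(0.0, -1.0, 270.0).axis_deg == 90.0


class TestPupilWavefront:
    def test_zero_coefficients_zero_inside(self):
        w = pupil_wavefront(ZernikeCoefficients(), 64)
        inside = ~np.isnan(w)
        assert inside.any()
        assert np.all(w[inside] == 0.0)

    def test_defocus_map_matches_polynomial(self):
        w = pupil_wavefront(ZernikeCoefficients({osa_index(2, 0): 1.0}), 64)
        x = np.linspace(-1, 1, 64)
        X, Y = np.meshgrid(x, x)
        rho = np.hypot(X, Y)
        expected = np.sqrt(3) * (2 * rho**2 - 1)
        inside = ~np.isnan(w)
        assert np.allclose(w[inside], expected[inside], atol=1e-12)

    def test_linearity_in_coefficients(self):
        a = ZernikeCoefficients({3: 0.5, 4: -0.2})
        b = ZernikeCoefficients({4: 0.7, 5: 0.1})
        w = pupil_wavefront(a + b, 64)
        wa, wb = pupil_wavefront(a, 64), pupil_wavefront(b, 64)
        inside = ~np.isnan(w)
        assert np.allclose(w[inside], (wa + wb)[inside], atol=1e-12)


def airy_config(wavelength_nm=550.0, grid_px=128, pupil_mm=4.0, pad=2):
    """Sampling geometry that resolves the Airy core and contains its tails."""
    pitch = (wavelength_nm * 1e-9) / (3.2 * pupil_mm * 1e-3)
    return OpticalConfig(
        pupil_diameter_mm=pupil_mm,
        grid_px=grid_px,
        field_extent_deg=np.degrees(grid_px * pitch),
        pad_factor=pad,
    )


class TestMonochromaticPSF:
    def test_airy_pattern_oracle(self):
        """Zero aberration must reproduce the analytic circular-aperture Airy
        pattern to within 1% of peak (RMSE) on a 128x128 grid."""
        lam, D = 550.0, 4.0
        cfg = airy_config(lam, 128, D)
        psf = psf_for_wavelength(ZernikeCoefficients(), lam, cfg)
        n = cfg.grid_px
        idx = (np.arange(n) - n // 2) * cfg.pixel_pitch_rad
        X, Y = np.meshgrid(idx, idx)
        v = np.pi * (D * 1e-3) * np.hypot(X, Y) / (lam * 1e-9)
        airy = np.where(v == 0, 1.0, (2 * j1(np.maximum(v, 1e-12)) / np.maximum(v, 1e-12)) ** 2)
        airy /= airy.sum()
        rmse = np.sqrt(np.mean((psf - airy) ** 2)) / airy.max()
        assert rmse <= 0.01

    def test_normalised_and_nonnegative(self, coarse_optics):
        coeffs = prescription_to_zernike(Prescription(-1.0, -0.5, 30.0), 2.0)
        psf = psf_for_wavelength(coeffs, 550.0, coarse_optics)
        assert psf.min() >= 0
        assert psf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_defocus_blur_grows_monotonically(self):
        """PSF second moment strictly increases with defocus magnitude and
        approaches the geometric blur-disc prediction r^2/2."""
        moments = []
        for dpt in (0.5, 1.0, 1.5):
            coeffs = prescription_to_zernike(Prescription(-dpt, 0.0, 0.0), 4.0)
            psf = psf_for_wavelength(coeffs, 550.0, OpticalConfig())
            moments.append(psf_second_moment(psf, OpticalConfig().pixel_pitch_rad))
        assert moments[0] < moments[1] < moments[2]
        geom = (0.002 * 1.5) ** 2 / 2  # blur-disc radius R = (D/2)*|defocus|
        assert moments[2] == pytest.approx(geom, rel=0.15)

    def test_defocus_psf_radially_symmetric(self):
        cfg = airy_config(550.0, 64)
        coeffs = prescription_to_zernike(Prescription(-0.25, 0.0, 0.0), 4.0)
        psf = psf_for_wavelength(coeffs, 550.0, cfg)
        core = psf[1:, 1:]  # symmetric about the grid centre pixel
        assert np.abs(core - core[::-1, ::-1]).max() <= 1e-6 * psf.max()

    def test_astigmatism_axis0_mirror_symmetric(self):
        cfg = airy_config(550.0, 64, pupil_mm=2.0)
        coeffs = prescription_to_zernike(Prescription(0.0, -0.5, 0.0), 2.0)
        psf = psf_for_wavelength(coeffs, 550.0, cfg)
        core = psf[1:, 1:]
        assert np.abs(core - core[::-1, :]).max() <= 1e-6 * psf.max()
        assert np.abs(core - core[:, ::-1]).max() <= 1e-6 * psf.max()

    def test_wavelength_outside_range_rejected(self, coarse_optics):
        with pytest.raises(ValidationError):
            psf_for_wavelength(ZernikeCoefficients(), 380.0, coarse_optics)

    def test_blur_exceeding_grid_raises_sampling_error(self):
        cfg = OpticalConfig(grid_px=32, field_extent_deg=0.05)
        coeffs = prescription_to_zernike(Prescription(-3.0, 0.0, 0.0), 4.0)
        with pytest.raises(SamplingError) as exc:
            psf_for_wavelength(coeffs, 550.0, cfg)
        assert exc.value.contained_energy < 0.99

    def test_grid_convergence_of_second_moment(self):
        """Doubling grid_px (fixed field) changes the second moment < 1%."""
        coeffs = prescription_to_zernike(Prescription(-1.0, 0.0, 0.0), 2.0)
        m = []
        for n in (64, 128):
            cfg = OpticalConfig(pupil_diameter_mm=2.0, grid_px=n,
                                field_extent_deg=np.degrees(6.4e-3),
                                wavelength_step_nm=50.0)
            psf = psf_for_wavelength(coeffs, 550.0, cfg)
            m.append(psf_second_moment(psf, cfg.pixel_pitch_rad))
        assert abs(m[1] - m[0]) / m[0] < 0.01


class TestPolychromaticPSF:
    def test_single_spike_equals_monochromatic(self, coarse_optics):
        grid = coarse_optics.wavelength_grid
        spec = np.zeros_like(grid)
        spec[10] = 1.0
        coeffs = prescription_to_zernike(Prescription(-1.0, 0.0, 0.0), 2.0)
        poly = psf_for_primary(SpectralCurve(grid, spec), coeffs, coarse_optics)
        mono = psf_for_wavelength(coeffs, grid[10], coarse_optics)
        assert np.allclose(poly, mono, rtol=0, atol=1e-15)

    def test_two_spikes_average(self, coarse_optics):
        grid = coarse_optics.wavelength_grid
        spec = np.zeros_like(grid)
        spec[5] = 1.0
        spec[20] = 1.0
        coeffs = prescription_to_zernike(Prescription(-1.0, 0.0, 0.0), 2.0)
        poly = psf_for_primary(SpectralCurve(grid, spec), coeffs, coarse_optics)
        mono = 0.5 * (
            psf_for_wavelength(coeffs, grid[5], coarse_optics)
            + psf_for_wavelength(coeffs, grid[20], coarse_optics)
        )
        assert np.allclose(poly, mono, rtol=0, atol=1e-14)

    def test_gaussian_primary_brute_force_oracle(self, coarse_optics):
        """Spectrally weighted PSF equals explicit per-wavelength
        accumulation to 1e-12 relative."""
        grid = coarse_optics.wavelength_grid
        spec = np.exp(-0.5 * ((grid - 530.0) / 15.0) ** 2)
        curve = SpectralCurve(grid, spec)
        coeffs = prescription_to_zernike(Prescription(-0.5, 0.0, 0.0), 2.0)
        poly = psf_for_primary(curve, coeffs, coarse_optics)
        w = spec / spec.sum()
        acc = np.zeros_like(poly)
        for lam, wi in zip(grid, w):
            if wi:
                acc += wi * psf_for_wavelength(coeffs, lam, coarse_optics)
        acc /= acc.sum()
        assert np.allclose(poly, acc, rtol=1e-12, atol=0)

    def test_zero_spectrum_rejected(self, coarse_optics):
        grid = coarse_optics.wavelength_grid
        with pytest.raises(ValidationError):
            psf_for_primary(SpectralCurve(grid, np.zeros_like(grid)),
                            ZernikeCoefficients(), coarse_optics)


class TestLMSKernel:
    @pytest.mark.parametrize("mode", ["resolved", "aggregated"])
    def test_mass_conservation(self, display_cones, coarse_optics, mode):
        """Per-(primary, cone) spatial sums reproduce the LMS matrix."""
        display, cones = display_cones
        coeffs = prescription_to_zernike(Prescription(-1.5, 0.0, 0.0), 2.0)
        kernel = build_lms_kernel(display, cones, coeffs, coarse_optics, mode=mode)
        mass = kernel.data.sum(axis=(1, 2))
        assert np.abs(mass - kernel.matrix.entries.T).max() <= 1e-9

    def test_delta_kernel_factorisation(self, lms_matrix):
        kernel = delta_lms_kernel(lms_matrix, 5)
        for c in range(3):
            for k in range(3):
                slab = kernel.data[c, :, :, k]
                assert slab[2, 2] == lms_matrix.entries[k, c]
                assert slab.sum() == pytest.approx(lms_matrix.entries[k, c])

    def test_monochromatic_primaries_factorise(self, display_cones, coarse_optics):
        """With single-line primaries the resolved kernel is the outer
        product of each primary's monochromatic PSF with the cone
        sensitivities at that line."""
        from opticorr.spectra import DisplaySpectra, compute_lms_matrix

        _, cones = display_cones
        grid = coarse_optics.wavelength_grid
        lines = (20, 13, 6)  # 600 / 530 / 460 nm on the 10 nm grid
        curves = []
        for i in lines:
            v = np.zeros_like(grid)
            v[i] = 1.0
            curves.append(SpectralCurve(grid, v))
        display = DisplaySpectra(*curves)
        coeffs = prescription_to_zernike(Prescription(-1.0, 0.0, 0.0), 2.0)
        kernel = build_lms_kernel(display, cones, coeffs, coarse_optics)
        cones_g = cones.on_common_grid(grid)
        matrix = compute_lms_matrix(display.on_common_grid(grid), cones_g)
        for c, i in enumerate(lines):
            mono = psf_for_wavelength(coeffs, grid[i], coarse_optics)
            for k in range(3):
                expected = matrix.entries[k, c] * mono
                assert np.allclose(kernel.data[c, :, :, k], expected, atol=1e-12)

    def test_resolved_matches_aggregated_when_psf_wavelength_independent(
        self, display_cones
    ):
        """With a pinhole-free zero-aberration system the PSF still varies
        with wavelength (diffraction), so compare through the spectral sum:
        aggregated and resolved kernels must agree when the primary is a
        single line (only one wavelength contributes)."""
        display, cones = display_cones
        from opticorr.spectra import DisplaySpectra

        cfg = OpticalConfig(pupil_diameter_mm=2.0, grid_px=32,
                            field_extent_deg=1.375, wavelength_step_nm=10.0)
        grid = cfg.wavelength_grid
        curves = []
        for i in (20, 13, 6):
            v = np.zeros_like(grid)
            v[i] = 1.0
            curves.append(SpectralCurve(grid, v))
        mono_display = DisplaySpectra(*curves)
        coeffs = prescription_to_zernike(Prescription(-0.5, 0.0, 0.0), 2.0)
        k_res = build_lms_kernel(mono_display, cones, coeffs, cfg, mode="resolved")
        k_agg = build_lms_kernel(mono_display, cones, coeffs, cfg, mode="aggregated")
        assert np.allclose(k_res.data, k_agg.data, atol=1e-12)

    def test_psf_stack_slices_normalised(self, display_cones, coarse_optics):
        display, _ = display_cones
        coeffs = prescription_to_zernike(Prescription(1.0, 0.0, 0.0), 2.0)
        stack = build_psf_stack(display, coeffs, coarse_optics)
        assert np.allclose(stack.psfs.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert stack.psfs.min() >= 0
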