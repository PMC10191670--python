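"""Spectral curves, LMS conversion and the colour-opponency transform."""

import numpy as np
import pytest

from opticorr.exceptions import DegenerateInputError, ValidationError
from opticorr.spectra import (
    DEFAULT_GRID,
    SpectralCurve,
    SpectrumSamples,
    builtin_cone_fundamentals,
    compute_lms_matrix,
    fit_spectrum,
    lms_to_opponency,
    opponency_to_lms,
    read_cone_fundamentals_csv,
    read_display_spectra_csv,
    resample,
    rgb_to_lms,
    synth_display_spectra,
    write_cone_fundamentals_csv,
    write_display_spectra_csv,
)


class TestFitSpectrum:
    def test_exact_grid_samples_reproduced(self):
        grid = np.arange(400.0, 701.0, 1.0)
        vals = np.exp(-0.5 * ((grid - 550) / 30) ** 2)
        fitted = fit_spectrum(SpectrumSamples(grid, vals))
        assert np.mean(np.abs(fitted.values - vals / vals.max())) <= 0.02

    def test_constant_samples_normalise_to_one(self):
        w = np.array([400.0, 500.0, 600.0, 700.0])
        fitted = fit_spectrum(SpectrumSamples(w, np.full(4, 5.0)))
        assert np.allclose(fitted.values, 1.0)

    @pytest.mark.parametrize("backend", ["spline", "mlp"])
    def test_gaussian_profile_against_analytic_oracle(self, backend):
        """Samples every 10 nm from an analytic Gaussian must be fitted to
        MAE <= 0.02 against the Gaussian evaluated on the 1 nm grid."""
        w = np.arange(400.0, 701.0, 10.0)
        gauss = lambda x: np.exp(-0.5 * ((x - 530.0) / 25.0) ** 2)
        fitted = fit_spectrum(SpectrumSamples(w, 7.3 * gauss(w)), backend=backend, seed=0)
        mae = np.mean(np.abs(fitted.values - gauss(fitted.wavelengths_nm)))
        assert mae <= 0.02

    def test_normalisation_contract(self):
        w = np.arange(420.0, 690.0, 10.0)
        fitted = fit_spectrum(SpectrumSamples(w, np.cos(w / 40) + 1.1))
        assert fitted.values.max() == pytest.approx(1.0)
        assert fitted.values.min() >= 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(DegenerateInputError):
            SpectrumSamples(np.array([500.0, 510.0, 520.0]), np.ones(3))

    def test_non_finite_readings_rejected(self):
        w = np.array([400.0, 500.0, 600.0, 700.0])
        with pytest.raises(ValidationError):
            SpectrumSamples(w, np.array([1.0, np.nan, 1.0, 1.0]))


class TestResample:
    def test_identity_on_own_grid(self):
        c = SpectralCurve(np.array([400.0, 500.0, 600.0]), np.array([0.1, 0.9, 0.4]))
        out = resample(c, c.wavelengths_nm)
        assert np.array_equal(out.values, c.values)

    def test_midpoint_interpolation(self):
        c = SpectralCurve(np.array([500.0, 510.0]), np.array([0.2, 0.4]))
        assert resample(c, np.array([505.0])).values[0] == pytest.approx(0.3)

    def test_outside_support_is_zero(self):
        c = SpectralCurve(np.arange(400.0, 701.0), np.ones(301))
        assert resample(c, np.array([390.0])).values[0] == 0.0

    def test_empty_grid_rejected(self):
        c = SpectralCurve(np.array([400.0, 500.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValidationError):
            resample(c, np.array([]))


class TestLMSMatrix:
    def test_single_spike_entry(self):
        """A monochromatic primary picks out the cone sensitivity at its line."""
        grid = np.arange(400.0, 701.0, 1.0)
        spike = np.zeros(301)
        spike[200] = 1.0  # 600 nm
        disp = synth_display_spectra()
        red = SpectralCurve(grid, spike)
        display = type(disp)(red, disp.green, disp.blue)
        cones = builtin_cone_fundamentals()
        m = compute_lms_matrix(display, cones, normalize=False)
        l_at_600 = cones.l.values[200]
        assert m.raw[0, 0] == pytest.approx(l_at_600, rel=1e-12)

    def test_zero_primary_gives_zero_column(self, display_cones):
        display, cones = display_cones
        grid = display.red.wavelengths_nm
        zero_blue = SpectralCurve(grid, np.zeros_like(grid))
        display2 = type(display)(display.red, display.green, zero_blue)
        m = compute_lms_matrix(display2, cones, normalize=False)
        assert np.all(m.raw[:, 2] == 0.0)

    def test_brute_force_summation_oracle(self, display_cones):
        """Entries must match an explicit double loop over wavelengths."""
        display, cones = display_cones
        m = compute_lms_matrix(display, cones, normalize=False)
        expected = np.zeros((3, 3))
        for k, cone in enumerate(cones):
            for c, prim in enumerate(display):
                acc = 0.0
                for lam, cv, pv in zip(cone.wavelengths_nm, cone.values, prim.values):
                    acc += cv * pv * 1.0
                expected[k, c] = acc
        assert np.allclose(m.raw, expected, rtol=1e-12, atol=0)

    def test_white_normalisation_policy(self, lms_matrix):
        white = lms_matrix.entries @ np.ones(3)
        assert white.max() == pytest.approx(1.0)
        assert np.all(lms_matrix.entries >= 0)

    def test_grid_density_invariance(self):
        """Halving the wavelength step changes entries by < 0.5%."""
        coarse = DEFAULT_GRID
        fine = np.arange(400.0, 700.25, 0.5)
        m1 = compute_lms_matrix(synth_display_spectra(grid=coarse),
                                builtin_cone_fundamentals(grid=coarse))
        m2 = compute_lms_matrix(synth_display_spectra(grid=fine),
                                builtin_cone_fundamentals(grid=fine))
        rel = np.abs(m1.entries - m2.entries) / np.abs(m1.entries).max()
        assert rel.max() < 0.005

    def test_mismatched_grids_rejected(self):
        d1 = synth_display_spectra()
        cones = builtin_cone_fundamentals(grid=np.arange(400.0, 700.0, 2.0))
        with pytest.raises(ValidationError):
            compute_lms_matrix(d1, cones)


class TestRgbToLms:
    def test_identity_matrix(self, rng):
        from opticorr.spectra import LMSMatrix

        img = rng.uniform(0, 1, (8, 8, 3))
        out = rgb_to_lms(img, LMSMatrix(np.eye(3)))
        assert np.array_equal(out, img)

    def test_linearity(self, lms_matrix, rng):
        x = rng.uniform(0, 1, (8, 8, 3))
        y = rng.uniform(0, 1, (8, 8, 3))
        lhs = rgb_to_lms(0.3 * x + 0.6 * y, lms_matrix)
        rhs = 0.3 * rgb_to_lms(x, lms_matrix) + 0.6 * rgb_to_lms(y, lms_matrix)
        assert np.allclose(lhs, rhs, atol=1e-14)

    def test_white_pixel_maps_to_row_sums(self, lms_matrix):
        out = rgb_to_lms(np.ones((1, 1, 3)), lms_matrix)
        assert np.allclose(out[0, 0], lms_matrix.entries.sum(axis=1))


class TestOpponency:
    def test_achromatic_fixed_form(self):
        img = np.full((2, 2, 3), 0.7)
        out = lms_to_opponency(img)
        assert np.allclose(out, 0.7)

    def test_pure_l_substitution(self):
        out = lms_to_opponency(np.array([[[1.0, 0.0, 0.0]]]))
        assert np.allclose(out[0, 0], [-1.0, 1.0, 1 / 3])

    def test_round_trip_inverse(self, rng):
        img = rng.uniform(0, 1, (5, 5, 3))
        for third in ("mean", "sum"):
            back = opponency_to_lms(lms_to_opponency(img, third), third)
            assert np.allclose(back, img, atol=1e-12)


class TestSynthSpectra:
    def test_maxima_at_requested_peaks(self):
        d = synth_display_spectra((620.0, 530.0, 460.0), (15.0, 15.0, 15.0))
        for curve, peak in zip(d, (620.0, 530.0, 460.0)):
            assert curve.wavelengths_nm[np.argmax(curve.values)] == peak

    def test_seed_determinism(self):
        a = synth_display_spectra(seed=7, jitter_nm=5.0)
        b = synth_display_spectra(seed=7, jitter_nm=5.0)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.values, cb.values)
        c = synth_display_spectra(seed=8, jitter_nm=5.0)
        assert not np.array_equal(a.red.values, c.red.values)

    def test_integral_matches_truncated_gaussian(self):
        """Each primary's integral must match the closed-form Gaussian
        integral truncated to the 400-700 nm window within 0.1%."""
        from scipy.stats import norm

        peaks, widths = (620.0, 530.0, 460.0), (15.0, 12.0, 18.0)
        d = synth_display_spectra(peaks, widths)
        for curve, mu, sd in zip(d, peaks, widths):
            analytic = sd * np.sqrt(2 * np.pi) * (
                norm.cdf((700 - mu) / sd) - norm.cdf((400 - mu) / sd)
            )
            assert curve.integral() == pytest.approx(analytic, rel=1e-3)

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ValidationError):
            synth_display_spectra((380.0, 530.0, 460.0))


class TestOpponencyProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        lms=st.lists(
            st.floats(-10, 10, allow_nan=False, allow_infinity=False),
            min_size=3, max_size=3,
        ),
        third=st.sampled_from(["mean", "sum"]),
    )
    def test_roundtrip_any_finite_triple(self, lms, third):
        """The opponency transform is invertible for arbitrary finite LMS."""
        img = np.array(lms).reshape(1, 1, 3)
        back = opponency_to_lms(lms_to_opponency(img, third), third)
        assert np.allclose(back, img, atol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        nodes=st.lists(
            st.floats(0, 1, allow_nan=False), min_size=2, max_size=8
        ),
    )
    def test_resample_exact_at_original_nodes(self, nodes):
        """Linear resampling reproduces curve values exactly at the nodes."""
        w = 400.0 + 10.0 * np.arange(len(nodes))
        curve = SpectralCurve(w, np.array(nodes))
        dense = resample(curve, np.arange(w[0], w[-1] + 0.5, 0.5))
        again = resample(dense, w)
        assert np.allclose(again.values, curve.values, atol=1e-12)


class TestConeFundamentals:
    def test_peak_ordering_and_nonnegativity(self):
        cones = builtin_cone_fundamentals()
        peaks = [c.wavelengths_nm[np.argmax(c.values)] for c in cones]
        assert peaks[0] > peaks[1] > peaks[2]
        for c in cones:
            assert c.values.min() >= 0
            assert c.values.max() == pytest.approx(1.0)


class TestCsvIO:
    def test_display_roundtrip(self, tmp_path, display_cones):
        display, cones = display_cones
        p = tmp_path / "disp.csv"
        write_display_spectra_csv(display, p)
        back = read_display_spectra_csv(p)
        assert np.allclose(back.red.values, display.red.values)
        assert np.allclose(back.blue.values, display.blue.values)

    def test_cones_roundtrip(self, tmp_path, display_cones):
        _, cones = display_cones
        p = tmp_path / "cones.csv"
        write_cone_fundamentals_csv(cones, p)
        back = read_cone_fundamentals_csv(p)
        assert np.allclose(back.s.values, cones.s.values)

    def test_malformed_csv_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,L,M,S\n400,0.1,0.2,0.3\noops,0.2,0.3,0.4\n")
        with pytest.raises(ValidationError, match="line 3"):
            read_cone_fundamentals_csv(p)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("lambda,value\n400,1\n")
        with pytest.raises(ValidationError, match="expected columns"):
            read_display_spectra_csv(p)
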