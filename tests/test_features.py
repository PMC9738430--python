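import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    dft_periodogram,
    naive_anisotropy,
    naive_gradient_square_mean,
    naive_radial_average,
    naive_spatial_variance,
    sierpinski_carpet,
)
from phasepath.features import (
    AcquisitionConfig,
    anisotropy_factor,
    box_counting_dimension,
    extract_features,
    fit_von_karman,
    fractal_dimension,
    gradient_square_mean,
    intensity_to_phase,
    phase_spatial_variance,
    radial_power_spectrum,
    refractive_index_variance,
    scattering_coefficient,
)
from phasepath.phantoms import (
    FieldSpec,
    PhaseImage,
    field_to_phase,
    generate_von_karman_field,
    render_intensity_image,
    von_karman_spectrum,
)


def make_phase(phi: np.ndarray, px: float = 0.3225) -> PhaseImage:
    return PhaseImage(phi=np.asarray(phi, float), pixel_size=px)


class TestIntensityToPhase:
    def test_round_trip_with_recorded_calibration(self, small_phantom_phase):
        img = render_intensity_image(small_phantom_phase, gain=500.0, offset=1000.0, noise_sd=0.0)
        recovered, relative = intensity_to_phase(img)
        assert not relative
        assert np.max(np.abs(recovered.phi - small_phantom_phase.phi)) <= 0.5 / 500.0

    def test_offset_only_image_gives_zero_phase(self):
        counts = np.full((32, 32), 2048.0)
        phase, _ = intensity_to_phase(counts, gain=400.0, offset=2048.0, pixel_size=0.64)
        assert np.all(phase.phi == 0.0)

    def test_missing_calibration_raises_with_instruction(self):
        counts = np.full((32, 32), 100.0)
        with pytest.raises(ValueError, match="normalized"):
            intensity_to_phase(counts, pixel_size=0.64)

    def test_relative_mode_scales_riv_as_inverse_gain_squared(self, small_phantom_phase):
        acq = AcquisitionConfig(pixel_size=small_phantom_phase.pixel_size)
        img1 = render_intensity_image(small_phantom_phase, gain=200.0, offset=2048.0, noise_sd=0.0)
        p1, rel = intensity_to_phase(img1, gain=200.0, offset=2048.0)
        p2, _ = intensity_to_phase(img1, gain=400.0, offset=2048.0)
        assert rel is False
        r1 = refractive_index_variance(p1, acq)
        r2 = refractive_index_variance(p2, acq)
        assert r1 == pytest.approx(4 * r2, rel=1e-10)

    def test_normalized_mode_flags_relative(self, small_phantom_phase):
        img = render_intensity_image(small_phantom_phase, gain=400.0, offset=2048.0)
        phase, relative = intensity_to_phase(img, normalized=True)
        assert relative
        assert phase.phi.max() <= 1.0


class TestEstimatorsAgainstOracles:
    """Every estimator must equal the independently coded naive route."""

    def test_gradient_square_mean_matches_loop_oracle(self, small_phantom_phase):
        got = gradient_square_mean(small_phantom_phase)
        want = naive_gradient_square_mean(small_phantom_phase.phi, small_phantom_phase.pixel_size)
        assert got == pytest.approx(want, rel=1e-12)

    def test_spatial_variance_matches_loop_oracle(self, small_phantom_phase):
        got = phase_spatial_variance(small_phantom_phase)
        want = naive_spatial_variance(small_phantom_phase.phi)
        assert got == pytest.approx(want, rel=1e-12)

    def test_anisotropy_matches_direct_formula(self, small_phantom_phase, acq_20x):
        for form, outer in [("outer_square", True), ("no_square", False)]:
            got = anisotropy_factor(small_phantom_phase, acq_20x, form=form)
            want = naive_anisotropy(
                small_phantom_phase.phi, small_phantom_phase.pixel_size, acq_20x.k0, outer
            )
            assert got == pytest.approx(want, rel=1e-12)

    def test_radial_spectrum_matches_dft_oracle(self, small_phantom_phase):
        phi = small_phantom_phase.phi
        px = small_phantom_phase.pixel_size
        k_got, p_got = radial_power_spectrum(phi, px)
        spec2d = dft_periodogram(phi, px)
        k_want, p_want = naive_radial_average(spec2d, px)
        np.testing.assert_allclose(k_got, k_want, rtol=1e-10)
        np.testing.assert_allclose(p_got, p_want, rtol=1e-10)


class TestClosedFormCases:
    def test_uniform_phase_gives_zero_gradient_and_variance(self, acq_20x):
        phase = make_phase(np.full((32, 32), 1.7))
        assert gradient_square_mean(phase) == 0.0
        assert refractive_index_variance(phase, acq_20x) == 0.0
        assert phase_spatial_variance(phase) == pytest.approx(0.0, abs=1e-20)
        assert scattering_coefficient(phase, acq_20x) == pytest.approx(0.0, abs=1e-15)

    def test_linear_ramp_gradient_is_slope_squared(self):
        px = 0.5
        x = np.arange(64) * px
        phase = make_phase(np.tile(1.3 * x, (64, 1)), px=px)
        assert gradient_square_mean(phase) == pytest.approx(1.3**2, rel=1e-10)

    def test_ramp_riv_closed_form(self):
        # slope 1 rad/um at lambda=0.55 um: sigma_n^2 = (0.55 / 2 pi)^2
        px = 0.25
        x = np.arange(64) * px
        phase = make_phase(np.tile(x, (64, 1)), px=px)
        acq = AcquisitionConfig(pixel_size=px, wavelength=0.55)
        assert refractive_index_variance(phase, acq) == pytest.approx(
            (0.55 / (2 * np.pi)) ** 2, rel=1e-10
        )

    def test_checkerboard_variance_is_c_squared(self):
        c = 0.8
        board = c * (-1.0) ** (np.add.outer(np.arange(32), np.arange(32)))
        assert phase_spatial_variance(make_phase(board)) == pytest.approx(c**2, rel=1e-12)

    def test_scattering_coefficient_unit_conversion(self):
        # variance 0.5 rad^2 over L = 6 um = 0.006 mm -> 83.33 rad^2/mm
        c = np.sqrt(0.5)
        board = c * (-1.0) ** (np.add.outer(np.arange(32), np.arange(32)))
        acq = AcquisitionConfig(pixel_size=0.3225, thickness=6.0)
        assert scattering_coefficient(make_phase(board), acq) == pytest.approx(0.5 / 0.006, rel=1e-12)

    def test_halving_thickness_doubles_mu_s(self, small_phantom_phase):
        a1 = AcquisitionConfig(pixel_size=0.3225, thickness=6.0)
        a2 = AcquisitionConfig(pixel_size=0.3225, thickness=3.0)
        assert scattering_coefficient(small_phantom_phase, a2) == pytest.approx(
            2 * scattering_coefficient(small_phantom_phase, a1), rel=1e-12
        )

    def test_slowly_varying_phase_has_g_near_one(self, acq_20x):
        # long-wavelength sinusoid: tiny gradients, g -> 1 (forward scattering)
        n = 128
        x = np.arange(n) * acq_20x.pixel_size
        phi = 0.5 * np.sin(2 * np.pi * x / (n * acq_20x.pixel_size))
        phase = make_phase(np.tile(phi, (n, 1)), px=acq_20x.pixel_size)
        g = anisotropy_factor(phase, acq_20x)
        assert 0.99 < g <= 1.0

    def test_af_forms_agree_at_x_equal_one(self, acq_20x):
        # build a phase whose x = <|grad phi|^2> / (2 k0^2 var) equals exactly 1
        rng = np.random.default_rng(5)
        phi = rng.normal(size=(64, 64))
        phase = make_phase(phi, px=acq_20x.pixel_size)
        gsm = gradient_square_mean(phase)
        var = phase_spatial_variance(phase)
        x = gsm / (2 * acq_20x.k0**2 * var)
        # rescaling phi leaves x unchanged; instead rescale the pixel size so x = 1
        px_star = acq_20x.pixel_size * np.sqrt(x)
        phase1 = make_phase(phi, px=px_star)
        assert anisotropy_factor(phase1, acq_20x, form="outer_square") == pytest.approx(0.0, abs=1e-10)
        assert anisotropy_factor(phase1, acq_20x, form="no_square") == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_gives_nan_af(self, acq_20x):
        assert np.isnan(anisotropy_factor(make_phase(np.zeros((32, 32))), acq_20x))


class TestOffsetAndScaleInvariance:
    @settings(max_examples=20, deadline=None)
    @given(offset=st.floats(-10, 10, allow_nan=False))
    def test_constant_offset_changes_nothing(self, offset):
        rng = np.random.default_rng(77)
        phi = rng.normal(size=(64, 64))
        acq = AcquisitionConfig(pixel_size=0.3225)
        a = make_phase(phi)
        b = make_phase(phi + offset)
        assert refractive_index_variance(b, acq) == pytest.approx(
            refractive_index_variance(a, acq), rel=1e-9
        )
        assert scattering_coefficient(b, acq) == pytest.approx(
            scattering_coefficient(a, acq), rel=1e-9
        )
        assert anisotropy_factor(b, acq) == pytest.approx(anisotropy_factor(a, acq), rel=1e-9)

    def test_riv_scales_as_wavelength_squared(self, small_phantom_phase):
        r1 = refractive_index_variance(small_phantom_phase, AcquisitionConfig(pixel_size=0.3225, wavelength=0.55))
        r2 = refractive_index_variance(small_phantom_phase, AcquisitionConfig(pixel_size=0.3225, wavelength=1.10))
        assert r2 == pytest.approx(4 * r1, rel=1e-12)

    def test_riv_monotone_in_prescribed_field_variance(self):
        # strictly increasing over paired-seed levels <=> rank correlation 1
        acq = AcquisitionConfig(pixel_size=0.3225)
        levels = [0.002, 0.005, 0.01, 0.02, 0.04]
        estimates = []
        for s in levels:
            spec = FieldSpec((128, 128), 0.3225, s, outer_scale=10.0, exponent=1.5, seed=21)
            phase = field_to_phase(generate_von_karman_field(spec), 6.0, 0.55)
            estimates.append(refractive_index_variance(phase, acq))
        assert np.all(np.diff(estimates) > 0)


class TestSpectrumEstimation:
    def test_white_noise_spectrum_is_flat(self, rng):
        field = rng.normal(size=(256, 256))
        kappa, power = radial_power_spectrum(field, 0.3225)
        slope = np.polyfit(np.log(kappa), np.log(power), 1)[0]
        assert abs(slope) < 0.05

    def test_pure_sinusoid_concentrates_in_one_bin(self):
        n, px = 256, 0.5
        x = np.arange(n) * px
        k_star = 2 * np.pi * 16 / (n * px)
        field = np.tile(np.sin(k_star * x), (n, 1))
        kappa, power = radial_power_spectrum(field, px)
        peak = kappa[np.argmax(power)]
        assert peak == pytest.approx(k_star, rel=0.10)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            radial_power_spectrum(np.zeros((32, 32)), 0.5)


class TestVonKarmanFit:
    def test_noiseless_analytic_curve_recovered(self):
        kappa = np.geomspace(0.02, 5.0, 60)
        power = von_karman_spectrum(kappa, 0.01, 40.0, 1.3)
        fit = fit_von_karman(kappa, power, field_extent=330.0, pixel_size=0.3225)
        assert fit.converged
        assert fit.outer_scale == pytest.approx(40.0, rel=1e-3)
        assert fit.exponent == pytest.approx(1.3, rel=1e-3)
        assert fit.sigma_n2_fit == pytest.approx(0.01, rel=1e-3)

    def test_phantom_parameters_recovered(self, big_phantom_field):
        fld = big_phantom_field
        kappa, power = radial_power_spectrum(fld.values, fld.pixel_size)
        fit = fit_von_karman(kappa, power, field_extent=1024 * fld.pixel_size, pixel_size=fld.pixel_size)
        assert fit.converged
        assert fit.outer_scale == pytest.approx(20.0, rel=0.20)
        assert fit.exponent == pytest.approx(1.5, rel=0.10)

    def test_white_noise_flagged_not_converged(self, rng):
        field = rng.normal(size=(256, 256))
        kappa, power = radial_power_spectrum(field, 0.3225)
        fit = fit_von_karman(kappa, power, field_extent=256 * 0.3225, pixel_size=0.3225)
        assert not fit.converged

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_von_karman(np.array([0.1] * 5), np.array([1.0] * 5), 100.0, 0.5)


class TestFractalDimension:
    @pytest.mark.parametrize("m,df", [(1.3, 2.7), (1.01, 2.99), (3.0, 1.0)])
    def test_spectral_identity(self, m, df):
        from phasepath.features import SpectrumFit

        fit = SpectrumFit(outer_scale=10.0, exponent=m, sigma_n2_fit=0.01,
                          residual_rms=0.1, converged=True, kappa_band=(0.1, 1.0))
        assert fractal_dimension(fit) == pytest.approx(df, rel=1e-12)

    def test_non_converged_fit_gives_nan(self):
        from phasepath.features import SpectrumFit

        fit = SpectrumFit(outer_scale=10.0, exponent=1.3, sigma_n2_fit=0.01,
                          residual_rms=2.0, converged=False, kappa_band=(0.1, 1.0))
        assert np.isnan(fractal_dimension(fit))

    def test_box_counting_on_sierpinski_carpet(self):
        carpet = sierpinski_carpet(5)
        dim = box_counting_dimension(carpet)
        assert dim == pytest.approx(np.log(8) / np.log(3), abs=0.05)

    def test_box_counting_of_full_plane_is_two(self):
        assert box_counting_dimension(np.ones((256, 256), bool)) == pytest.approx(2.0, abs=1e-9)


class TestExtractFeatures:
    def test_composition_matches_individual_estimators(self, acq_20x):
        spec = FieldSpec((128, 128), 0.3225, 0.01, 20.0, 1.5, seed=4)
        phase = field_to_phase(generate_von_karman_field(spec), 6.0, 0.55)
        vec = extract_features(phase, acq_20x)
        assert vec.riv == refractive_index_variance(phase, acq_20x)
        assert vec.sc == scattering_coefficient(phase, acq_20x)
        assert vec.af == anisotropy_factor(phase, acq_20x)
        if vec.diagnostics is not None and vec.diagnostics.converged:
            assert vec.fd + vec.diagnostics.exponent == pytest.approx(4.0, abs=1e-12)

    def test_uniform_image_yields_flagged_record_not_exception(self, acq_20x):
        phase = make_phase(np.zeros((64, 64)))
        vec = extract_features(phase, acq_20x)
        assert vec.riv == 0.0
        assert vec.sc == 0.0
        assert np.isnan(vec.af)
        assert np.isnan(vec.fd)
        assert vec.warnings

    def test_batch_of_fixture_images_has_no_missing_core_values(self, tmp_path):
        from phasepath.phantoms import default_fixture_specs, write_fixture_set
        from phasepath.pipeline import extract_stage

        specs = default_fixture_specs(base_seed=8, shape=(128, 128), tissues=("liver", "brain"))
        write_fixture_set(specs, tmp_path)
        features = extract_stage({"seed": 8}, tmp_path / "manifest.csv", tmp_path / "features.csv")
        assert len(features) == 12
        assert features[["riv", "sc_rad2_per_mm", "af"]].notna().all().all()
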