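"""The GRF ice model: spectrum, correlation length, moments, synthesis."""

import numpy as np
import pytest
from scipy.integrate import quad

from icefield import grf, physics, stats
from icefield.constants import KAPPA_V_A2


@pytest.fixture(scope="module")
def params():
    return grf.GRFIceParams()


class TestPowerSpectrumModel:
    def test_matches_brute_force_two_term_sum(self, params):
        q = np.linspace(0.0, 3.0, 301)
        oracle = params.a1 * np.exp(-q**2 / (2 * params.s1**2)) + params.a2 * np.exp(
            -((q - params.m) ** 2) / (2 * params.s2**2)
        )
        assert np.allclose(grf.power_spectrum_model(q, params), oracle, rtol=1e-12)

    def test_reference_points(self, params):
        assert grf.power_spectrum_model(params.m, params) == pytest.approx(0.9788, abs=1e-3)
        assert grf.power_spectrum_model(0.0, params) == pytest.approx(0.1991, abs=1e-3)

    def test_vanishes_at_high_frequency(self, params):
        assert grf.power_spectrum_model(50.0, params) < 1e-12

    def test_negative_frequency_rejected(self, params):
        with pytest.raises(ValueError):
            grf.power_spectrum_model(-0.1, params)

    def test_default_weights_sum_to_one(self, params):
        assert params.a1 + params.a2 == pytest.approx(1.0, abs=1e-6)


class TestCorrelationLength:
    def test_lda_ice_value(self, params):
        # the fitted spectrum gives a sub-Ångström correlation length (~0.5 Å)
        assert grf.correlation_length(params) == pytest.approx(0.5, abs=0.1)

    def test_pure_gaussian_closed_form(self):
        # P = exp(-q^2/(2 s^2)) has ACF ∝ exp(-2 pi^2 s^2 r^2); the 1/e lag
        # is 1/(pi*s*sqrt(2))
        s = 0.4
        p = grf.GRFIceParams(a1=1.0, a2=0.0, s1=s, s2=0.081)
        assert grf.correlation_length(p) == pytest.approx(1.0 / (np.pi * s * np.sqrt(2)), rel=1e-3)

    def test_fourier_scaling_theorem(self, params):
        doubled = grf.GRFIceParams(
            a1=params.a1, a2=params.a2, s1=2 * params.s1, s2=2 * params.s2, m=2 * params.m
        )
        assert grf.correlation_length(doubled) == pytest.approx(
            grf.correlation_length(params) / 2, rel=1e-3
        )


class TestExpectedMoments:
    def test_zero_density(self, params):
        table = grf.CorrectionTable.unity()
        assert grf.expected_moments(0.0, 0.25, params, table) == (0.0, 0.0)

    def test_fine_pixel_limit_recovers_constants(self, params):
        table = grf.CorrectionTable.unity()
        mean, var = grf.expected_moments(1.0, 1e-4, params, table)
        assert mean == pytest.approx(145.59, rel=1e-6)
        assert var == pytest.approx(10195.82, rel=1e-6)

    def test_linearity_in_density(self, params):
        table = grf.default_correction_table()
        m1, v1 = grf.expected_moments(0.1, 0.25, params, table)
        m2, v2 = grf.expected_moments(0.2, 0.25, params, table)
        assert m2 == pytest.approx(2 * m1, rel=1e-12)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_invalid_inputs(self, params):
        with pytest.raises(ValueError):
            grf.expected_moments(-1.0, 0.25, params)
        with pytest.raises(ValueError):
            grf.expected_moments(1.0, 0.0, params)


class TestCorrectionTable:
    def test_packaged_table_contract(self):
        table = grf.default_correction_table()
        assert np.all(table.mean_ratio > 0) and np.all(table.mean_ratio <= 1.0)
        assert np.all(np.diff(table.mean_ratio) <= 1e-12)
        assert np.all(np.diff(table.variance_ratio) <= 1e-12)
        assert np.all(table.variance_ratio > 0)

    def test_interpolation_clamped(self):
        t = grf.CorrectionTable([0.1, 0.4], [1.0, 0.9], [0.8, 0.5])
        assert t.mean_factor(0.01) == 1.0
        assert t.variance_factor(5.0) == 0.5
        assert t.variance_factor(0.25) == pytest.approx(0.65)

    def test_tsv_roundtrip(self):
        t = grf.default_correction_table()
        back = grf.CorrectionTable.from_tsv(t.to_tsv())
        assert np.allclose(back.pixel_areas, t.pixel_areas)
        assert np.allclose(back.variance_ratio, t.variance_ratio)

    def test_calibration_determinism_and_monotonicity(self):
        kwargs = dict(seed=5, n_boxes=2, box_xy=30.0, max_rel_se=0.2)
        a = grf.calibrate_correction_table([0.4, 0.8], **kwargs)
        b = grf.calibrate_correction_table([0.4, 0.8], **kwargs)
        assert np.array_equal(a.variance_ratio, b.variance_ratio)
        assert a.variance_ratio[1] < a.variance_ratio[0]
        assert 0 < a.mean_ratio[0] <= 1.0


class TestSynthesis:
    def test_zero_density_returns_zero_fields(self, params):
        spec = grf.IceSliceSpec(0.0, 0.5, (32, 32), seed=1)
        a, b = grf.synthesize_grf_pair(spec, params, grf.CorrectionTable.unity())
        assert np.all(a == 0.0) and np.all(b == 0.0)

    def test_sample_moments_match_targets(self, params):
        table = grf.default_correction_table()
        spec = grf.IceSliceSpec(0.167, 0.5, (512, 512), seed=3)
        mean, var = grf.expected_moments(0.167, 0.25, params, table)
        a, b = grf.synthesize_grf_pair(spec, params, table)
        for f in (a, b):
            assert f.mean() == pytest.approx(mean, rel=0.02)
            assert f.var() == pytest.approx(var, rel=0.02)

    def test_pair_is_uncorrelated(self, params):
        spec = grf.IceSliceSpec(0.167, 0.5, (256, 256), seed=9)
        a, b = grf.synthesize_grf_pair(spec, params, grf.CorrectionTable.unity())
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert abs(r) < 3.0 / np.sqrt(a.size)

    def test_deterministic_given_seed(self, params):
        spec = grf.IceSliceSpec(0.167, 0.5, (64, 64), seed=21)
        a1, b1 = grf.synthesize_grf_pair(spec, params)
        a2, b2 = grf.synthesize_grf_pair(spec, params)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_spectrum_peak_at_oo_distance(self, params):
        spec = grf.IceSliceSpec(0.167, 0.5, (512, 512), seed=4)
        a, _ = grf.synthesize_grf_pair(spec, params, grf.CorrectionTable.unity())
        prof = stats.radial_power_spectrum(a, 0.5, n_bins=50)
        peak = stats.spectrum_peak(prof)
        assert abs(peak - 1.0 / 2.88) <= prof.bin_width

    def test_recovers_spectrum_shape(self, params):
        spec = grf.IceSliceSpec(0.167, 0.5, (512, 512), seed=6)
        a, _ = grf.synthesize_grf_pair(spec, params, grf.CorrectionTable.unity())
        prof = stats.radial_power_spectrum(a, 0.5, n_bins=100)
        sel = (prof.centers > 0.01) & (prof.centers < 0.5)  # up to Nyquist/2
        model = grf.power_spectrum_model(prof.centers[sel], params)
        corr = np.corrcoef(prof.power[sel], model)[0, 1]
        assert corr > 0.95

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError):
            grf.IceSliceSpec(0.1, 0.5, (33, 32), seed=0)


class TestApplyIce:
    def test_vacuum_protein_gets_ice_everywhere(self):
        ice = np.full((8, 8), 3.0)
        out = grf.apply_ice_to_slice(np.zeros((8, 8)), ice, np.ones((8, 8), bool), 10.0)
        assert np.allclose(out, 3.0)

    def test_strong_protein_untouched(self):
        protein = np.full((8, 8), 50.0)
        out = grf.apply_ice_to_slice(protein, np.full((8, 8), 3.0), np.ones((8, 8), bool), 10.0)
        assert np.array_equal(out, protein)

    def test_zero_threshold_boundary_semantics(self):
        protein = np.zeros((8, 8))
        out = grf.apply_ice_to_slice(
            protein, np.full((8, 8), 3.0), np.ones((8, 8), bool), 10.0, threshold_fraction=0.0
        )
        assert np.array_equal(out, protein)

    def test_mask_limits_ice(self):
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        out = grf.apply_ice_to_slice(np.zeros((8, 8)), np.full((8, 8), 2.0), mask, 10.0)
        assert np.all(out[:4] == 2.0) and np.all(out[4:] == 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            grf.apply_ice_to_slice(np.zeros((8, 8)), np.zeros((8, 9)), np.ones((8, 8), bool), 1.0)


class TestCampbellOracle:
    def test_grid_matches_analytic_parseval(self):
        """The 0.05 Å grid integral agrees with the closed-form Fourier-space
        integral of the squared molecular scattering factor."""
        table = physics.default_scattering_table()

        def integrand(q):
            fe_mol = table.fe("O", q) + 2 * table.fe("H", q)
            return KAPPA_V_A2**2 * fe_mol**2 * 2 * np.pi * q

        analytic, _ = quad(integrand, 0.0, 60.0, limit=400)
        grid_value = grf.campbell_variance_coefficient(pixel_size=0.05)
        assert grid_value == pytest.approx(analytic, rel=5e-3)

    def test_rigid_below_point(self):
        """Displacing the hydrogens reduces the coherent self-overlap."""
        point = grf.campbell_variance_coefficient(pixel_size=0.1)
        rigid = grf.campbell_variance_coefficient(pixel_size=0.1, molecule_mode="rigid")
        assert rigid < point
        assert rigid > 0
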