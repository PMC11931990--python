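"""Spectral decomposition, band integration and the two efficiency estimators."""

import numpy as np
import pytest

from agpfret import spectra as sp
from agpfret import synthetic_data as sd
from agpfret.exceptions import InvalidArgumentError

GRID = np.arange(400.0, 701.0, 1.0)


def gaussian_spectrum(center, sigma, amplitude, kind="emission"):
    return sp.Spectrum(GRID, amplitude * np.exp(-0.5 * ((GRID - center) / sigma) ** 2), kind)


class TestDecomposeMixture:
    donor = staticmethod(lambda: gaussian_spectrum(500, 18, 0.5, "absorbance"))
    acceptor = staticmethod(lambda: gaussian_spectrum(565, 25, 0.6, "absorbance"))

    def test_pure_donor_recovers_identity(self):
        d, a = self.donor(), self.acceptor()
        res = sp.decompose_mixture(d, d, a)
        assert res.coeff_donor == pytest.approx(1.0, abs=1e-10)
        assert res.coeff_acceptor == pytest.approx(0.0, abs=1e-10)
        assert res.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_mixture_recovered_exactly(self):
        d, a = self.donor(), self.acceptor()
        mix = sp.Spectrum(GRID, 0.3 * d.values + 0.7 * a.values, "absorbance")
        res = sp.decompose_mixture(mix, d, a)
        assert res.coeff_donor == pytest.approx(0.3, abs=1e-8)
        assert res.coeff_acceptor == pytest.approx(0.7, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        d, a = self.donor(), self.acceptor()
        rng = np.random.default_rng(11)
        mix_vals = 0.4 * d.values + 0.25 * a.values + rng.normal(0, 0.005, GRID.size)
        mix = sp.Spectrum(GRID, np.abs(mix_vals), "absorbance")
        res = sp.decompose_mixture(mix, d, a, nonnegative=False)
        X = np.column_stack([d.values, a.values])
        oracle = np.linalg.solve(X.T @ X, X.T @ mix.values)
        assert res.coeff_donor == pytest.approx(oracle[0], abs=1e-10)
        assert res.coeff_acceptor == pytest.approx(oracle[1], abs=1e-10)

    def test_noisy_mixture_within_tolerance(self):
        d, a = self.donor(), self.acceptor()
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.01 * d.values.max(), GRID.size)
        mix = sp.Spectrum(GRID, np.clip(0.3 * d.values + 0.7 * a.values + noise, 0, None), "absorbance")
        res = sp.decompose_mixture(mix, d, a)
        assert res.coeff_donor == pytest.approx(0.3, abs=0.02)
        assert res.coeff_acceptor == pytest.approx(0.7, abs=0.02)

    def test_collinear_references_raise(self):
        d = self.donor()
        doubled = sp.Spectrum(GRID, 2.0 * d.values, "absorbance")
        with pytest.raises(np.linalg.LinAlgError):
            sp.decompose_mixture(d, d, doubled)

    def test_disjoint_ranges_raise(self):
        d = self.donor()
        other = sp.Spectrum(np.arange(900.0, 950.0), np.ones(50), "emission")
        with pytest.raises(InvalidArgumentError):
            sp.decompose_mixture(other, d, self.acceptor())


class TestIntegrateBand:
    def test_constant_band(self):
        s = sp.Spectrum(GRID, np.full(GRID.size, 2.0))
        assert sp.integrate_band(s, 500, 510) == pytest.approx(20.0)

    def test_triangular_peak_closed_form(self):
        # triangle apex 1 at 550, half-width 10 -> area 10
        vals = np.clip(1.0 - np.abs(GRID - 550) / 10.0, 0.0, None)
        s = sp.Spectrum(GRID, vals)
        assert sp.integrate_band(s, 540, 560) == pytest.approx(10.0, abs=1e-6)

    def test_additive_over_adjacent_bands(self):
        s = gaussian_spectrum(530, 20, 1.0)
        whole = sp.integrate_band(s, 500, 560)
        parts = sp.integrate_band(s, 500, 531.7) + sp.integrate_band(s, 531.7, 560)
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_band_outside_grid_raises(self):
        s = gaussian_spectrum(530, 20, 1.0)
        with pytest.raises(InvalidArgumentError):
            sp.integrate_band(s, 300, 500)


class TestEstimatorFormulas:
    def test_donor_quenching_no_quenching(self):
        q = sp.FretSpectralQuantities(I_DA=100, I_D=100, A_D=0.1, A_DA=0.1)
        assert sp.efret_donor_quenching(q) == pytest.approx(0.0)

    def test_donor_quenching_complete(self):
        q = sp.FretSpectralQuantities(I_DA=0, I_D=100, A_D=0.1, A_DA=0.1)
        assert sp.efret_donor_quenching(q) == pytest.approx(1.0)

    def test_donor_quenching_arithmetic(self):
        q = sp.FretSpectralQuantities(I_DA=80, I_D=100, A_D=0.10, A_DA=0.10)
        assert sp.efret_donor_quenching(q) == pytest.approx(0.20)

    def test_stimulated_emission_no_enhancement(self):
        q = sp.FretSpectralQuantities(I_AD=100, I_A=100, A_A=0.1, A_AD=0.1, A_DA=0.1)
        assert sp.efret_stimulated_emission(q) == pytest.approx(0.0)

    def test_stimulated_emission_arithmetic(self):
        q = sp.FretSpectralQuantities(I_AD=120, I_A=100, A_A=0.10, A_AD=0.10, A_DA=0.10)
        assert sp.efret_stimulated_emission(q) == pytest.approx(0.20)

    def test_stimulated_emission_negative_flagged_by_sign(self):
        q = sp.FretSpectralQuantities(I_AD=80, I_A=100, A_A=0.10, A_AD=0.10, A_DA=0.10)
        assert sp.efret_stimulated_emission(q) < 0

    def test_zero_denominators_raise(self):
        with pytest.raises(InvalidArgumentError):
            sp.efret_donor_quenching(sp.FretSpectralQuantities(I_D=0, A_DA=0.1))
        with pytest.raises(InvalidArgumentError):
            sp.efret_stimulated_emission(sp.FretSpectralQuantities(I_A=0, A_DA=0.1))


class TestEmissionRatio:
    def test_flat_spectrum(self):
        s = sp.Spectrum(GRID, np.ones(GRID.size))
        assert sp.emission_ratio(s) == pytest.approx(1.0)

    def test_two_gaussian_closed_form(self):
        a_d, a_a = 1.0, 0.8
        vals = a_d * np.exp(-0.5 * ((GRID - 530) / 20) ** 2) + a_a * np.exp(
            -0.5 * ((GRID - 595) / 22) ** 2
        )
        s = sp.Spectrum(GRID, vals)
        expected = (
            a_d * np.exp(-0.5 * ((590 - 530) / 20) ** 2) + a_a * np.exp(-0.5 * ((590 - 595) / 22) ** 2)
        ) / (
            a_d * np.exp(-0.5 * ((523 - 530) / 20) ** 2) + a_a * np.exp(-0.5 * ((523 - 595) / 22) ** 2)
        )
        assert sp.emission_ratio(s) == pytest.approx(expected, rel=1e-6)

    def test_wavelength_outside_grid_raises(self):
        s = sp.Spectrum(np.arange(550.0, 650.0), np.ones(100))
        with pytest.raises(InvalidArgumentError):
            sp.emission_ratio(s, 590, 523)

    def test_increases_with_ground_truth_efficiency(self):
        ratios = []
        for e in (0.05, 0.15, 0.25, 0.35):
            bundle = sd.make_synthetic_spectra(e)
            ratios.append(sp.emission_ratio(bundle.mixture_em))
        assert np.all(np.diff(ratios) > 0)


class TestMolarRatio:
    def test_equal_concentration_unity(self):
        assert sp.molar_ratio(0.5, 50000, 0.5, 50000) == pytest.approx(1.0)

    def test_bound_atto_example(self):
        # Agp2 + Atto-495 with the 0.7 bound-dye correction
        ratio = sp.molar_ratio(0.0448, 80000, 0.813, 81300, correction=0.7)
        assert ratio == pytest.approx(0.08, abs=0.0005)

    def test_correction_scales_inversely(self):
        base = sp.molar_ratio(0.1, 80000, 0.5, 80000, correction=1.0)
        halved = sp.molar_ratio(0.1, 80000, 0.5, 80000, correction=0.5)
        assert halved == pytest.approx(2 * base)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(InvalidArgumentError):
            sp.molar_ratio(0.0, 80000, 0.5, 80000)


@pytest.mark.parametrize("truth", [0.1, 0.2, 0.3])
def test_estimators_agree_on_synthetic_spectra(truth):
    """Both estimators recover the same efficiency within the noise level."""
    bundle = sd.make_synthetic_spectra(truth, noise_sd=0.01, seed=42)
    e_dq, e_se, _ = sp.estimate_fret_from_spectra(
        bundle.donor_abs, bundle.acceptor_abs, bundle.mixture_abs,
        bundle.donor_em, bundle.acceptor_em, bundle.mixture_em,
    )
    assert e_dq == pytest.approx(truth, abs=0.05)
    assert e_se == pytest.approx(truth, abs=0.05)
    assert e_dq == pytest.approx(e_se, abs=0.05)


def test_spectrum_io_round_trip(tmp_path):
    s = gaussian_spectrum(530, 20, 1.0)
    path = tmp_path / "spec.txt"
    sp.write_spectrum(path, s, header="test emission")
    back = sp.read_spectrum(path)
    np.testing.assert_allclose(back.wavelengths, s.wavelengths, rtol=1e-5)
    np.testing.assert_allclose(back.values, s.values, rtol=1e-4, atol=1e-8)


def test_spectrum_validation():
    with pytest.raises(InvalidArgumentError):
        sp.Spectrum(np.array([500.0, 500.0, 501.0]), np.zeros(3))
    with pytest.raises(InvalidArgumentError):
        sp.Spectrum(np.array([500.0, 501.0]), np.array([-0.5, 0.1]), kind="absorbance")
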