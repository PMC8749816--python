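"""Spectral assessment: noise estimate, windows, fluorescence unmixing, ratios."""

import numpy as np
import pytest

from ipdtmon.spectra import (
    FLUORESCENCE_PEAK_WINDOW,
    SpectralResult,
    SpectrumError,
    FitDegeneracyError,
    assess_spectrum,
    fit_fluorescence,
    integrate_transmission,
    is_detectable,
    noise_level,
    threshold_equivalent_intensity,
    transmission_ratio,
)
from ipdtmon.synthetic import _ppix_shape

from conftest import make_spectrum


class TestNoiseLevel:
    def test_recovers_generator_sd(self, spectrum_factory, rng):
        sp = spectrum_factory(lambda wl: 3.0 + rng.normal(0, 0.5, wl.size))
        est = noise_level(sp)
        assert est == pytest.approx(0.5, rel=0.2)

    def test_constant_spectrum_degenerate(self, spectrum_factory):
        sp = spectrum_factory(lambda wl: np.full(wl.size, 7.0))
        with pytest.warns(UserWarning, match="degenerate"):
            assert noise_level(sp) == 0.0

    def test_peak_outside_window_ignored(self, spectrum_factory, rng):
        noise = rng.normal(0, 0.5, 582)
        plain = spectrum_factory(lambda wl: noise[: wl.size])
        peaked = spectrum_factory(
            lambda wl: noise[: wl.size] + 100.0 * np.exp(-((wl - 635.0) ** 2) / 18.0)
        )
        assert noise_level(peaked) == pytest.approx(noise_level(plain), rel=1e-6)

    def test_window_absent_is_input_error(self):
        sp = make_spectrum(np.arange(600.0, 760.0), np.zeros(160))
        with pytest.raises(SpectrumError):
            noise_level(sp)


class TestIntegrateTransmission:
    def test_flat_window(self, spectrum_factory):
        sp = spectrum_factory(lambda wl: np.ones(wl.size))
        assert integrate_transmission(sp) == pytest.approx(16.0, rel=1e-9)

    def test_zero_spectrum(self, spectrum_factory):
        sp = spectrum_factory(lambda wl: np.zeros(wl.size))
        assert integrate_transmission(sp) == 0.0

    def test_triangle_closed_form(self, spectrum_factory):
        # triangular peak of height 2 spanning exactly 626-642 nm: area = 16
        def tri(wl):
            up = np.clip((wl - 626.0) / 8.0, 0, 1)
            down = np.clip((642.0 - wl) / 8.0, 0, 1)
            return 2.0 * np.minimum(up, down)

        sp = spectrum_factory(tri)
        assert integrate_transmission(sp) == pytest.approx(16.0, rel=1e-9)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 3.0])
    def test_linearity(self, spectrum_factory, rng, alpha):
        shape = rng.uniform(0, 5, 582)
        sp = spectrum_factory(lambda wl: shape[: wl.size])
        scaled = spectrum_factory(lambda wl: alpha * shape[: wl.size])
        assert integrate_transmission(scaled) == pytest.approx(
            alpha * integrate_transmission(sp), abs=1e-12
        )

    def test_window_absent_is_input_error(self):
        sp = make_spectrum(np.arange(500.0, 600.0), np.zeros(100))
        with pytest.raises(SpectrumError):
            integrate_transmission(sp)


class TestFitFluorescence:
    def test_exact_two_component_recovery(self, basis, spectrum_factory):
        def shape(wl):
            p, a = basis.resampled(wl)
            return 2.0 * p + 0.0 * a

        sp = spectrum_factory(shape)
        a, b, i_f = fit_fluorescence(sp, basis)
        assert a == pytest.approx(2.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)
        lo, hi = FLUORESCENCE_PEAK_WINDOW
        win = (basis.wavelengths >= lo) & (basis.wavelengths <= hi)
        assert i_f == pytest.approx(2.0 * basis.ppix[win].max(), rel=1e-6)

    def test_zero_spectrum(self, basis, spectrum_factory):
        sp = spectrum_factory(lambda wl: np.zeros(wl.size))
        assert fit_fluorescence(sp, basis) == (0.0, 0.0, 0.0)

    def test_noisy_recovery_within_5_percent(self, basis, spectrum_factory, rng):
        def shape(wl):
            p, a = basis.resampled(wl)
            return 1.5 * p + 0.7 * a + rng.normal(0, 0.01, wl.size)

        a, b, _ = fit_fluorescence(spectrum_factory(shape), basis)
        assert a == pytest.approx(1.5, rel=0.05)
        assert b == pytest.approx(0.7, rel=0.05)

    def test_noiseless_residual_negligible(self, basis, spectrum_factory):
        def shape(wl):
            p, a = basis.resampled(wl)
            return 0.8 * p + 1.3 * a

        sp = spectrum_factory(shape)
        a, b, _ = fit_fluorescence(sp, basis)
        wl = sp.wavelengths
        mask = (wl >= 650) & (wl <= 750)
        p, au = basis.resampled(wl[mask])
        resid = np.linalg.norm(sp.intensities[mask] - a * p - b * au)
        assert resid <= 1e-9 * np.linalg.norm(sp.intensities[mask])

    def test_collinear_bases_raise(self, basis, spectrum_factory):
        from ipdtmon.spectra import FluorescenceBasis

        bad = FluorescenceBasis(basis.wavelengths, basis.ppix, basis.ppix.copy())
        sp = spectrum_factory(lambda wl: np.ones(wl.size))
        with pytest.raises(FitDegeneracyError):
            fit_fluorescence(sp, bad)


class TestDetectability:
    def test_threshold_is_strict(self, spectrum_factory):
        sp = spectrum_factory(
            lambda wl: 4.0 * np.exp(-((wl - 635.0) ** 2) / 2.0)
        )
        assert is_detectable(sp, (626, 642), noise=1.0)
        sp3 = spectrum_factory(lambda wl: 3.0 * np.exp(-((wl - 635.0) ** 2) / 2.0))
        assert not is_detectable(sp3, (626, 642), noise=1.0)

    @pytest.mark.parametrize("scale", [1.0, 2.0, 10.0, 100.0])
    def test_monotone_in_signal_scale(self, spectrum_factory, scale):
        # scaling the signal up never flips detectable -> undetectable
        base = spectrum_factory(lambda wl: 3.5 * np.exp(-((wl - 635.0) ** 2) / 2.0))
        scaled = spectrum_factory(
            lambda wl: scale * 3.5 * np.exp(-((wl - 635.0) ** 2) / 2.0)
        )
        assert is_detectable(base, (626, 642), 1.0) <= is_detectable(scaled, (626, 642), 1.0)

    def test_bleached_ppix_is_undetectable(self, basis, spectrum_factory, rng):
        # post-iPDT spectrum: treatment light present, zero PpIX amplitude
        def shape(wl):
            _, auto = basis.resampled(wl)
            return (
                50.0 * np.exp(-((wl - 635.0) ** 2) / 18.0)
                + 0.5 * auto
                + rng.normal(0, 0.3, wl.size)
            )

        res = assess_spectrum(spectrum_factory(shape), basis)
        assert res.transmission_detectable
        assert not res.fluorescence_detectable


class TestTransmissionRatio:
    @staticmethod
    def result(i_t, detectable, noise=1.0):
        return SpectralResult(
            i_t=i_t, i_f=0.0, a=0.0, b=0.0, noise=noise,
            transmission_detectable=detectable, fluorescence_detectable=False,
        )

    def test_plain_ratio(self):
        r, q = transmission_ratio(self.result(10.0, True), self.result(2.0, True))
        assert (r, q) == (5.0, "measured")

    def test_pre_undetectable_defines_zero(self):
        r, q = transmission_ratio(self.result(0.5, False), self.result(2.0, True))
        assert (r, q) == (0.0, "pre-undetectable")

    def test_post_undetectable_lower_bound(self):
        r, q = transmission_ratio(
            self.result(100.0, True), self.result(0.0, False), threshold_equivalent=1.5
        )
        assert q == "lower-bound"
        assert r == pytest.approx(100.0 / 1.5)

    def test_default_threshold_equivalent(self):
        post = self.result(0.0, False, noise=2.0)
        r, q = transmission_ratio(self.result(96.0, True), post)
        assert q == "lower-bound"
        assert r == pytest.approx(96.0 / threshold_equivalent_intensity(2.0))
        assert threshold_equivalent_intensity(2.0) == pytest.approx(3 * 2.0 * 16)

    def test_inconsistent_post_flags(self):
        with pytest.raises(ValueError):
            transmission_ratio(self.result(10.0, True), self.result(0.0, True))

    def test_ratio_uncertainty_propagation(self, rng):
        # two independent 8% intensity errors propagate to ~sqrt(2)*8% on R, < 20%
        draws = (1 + 0.08 * rng.standard_normal(10_000)) / (
            1 + 0.08 * rng.standard_normal(10_000)
        )
        rel_sd = draws.std() / draws.mean()
        assert rel_sd < 0.20
        assert rel_sd == pytest.approx(np.sqrt(2) * 0.08, rel=0.15)
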