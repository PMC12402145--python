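"""LP/RP nitrogen-index extraction: baseline, peaks, fits, ratios."""

import numpy as np
import pytest

from plaquetime.isotopes import EnrichmentParams, N15_NATURAL, isotopologue_pattern, theoretical_peak_ratio
from plaquetime.simulate import render_pattern_spectrum
from plaquetime.spectral import (
    SQRT_2LN2,
    AsymmetricGaussianModel,
    NoPeakError,
    SpectralConfig,
    Spectrum,
    _asym_gauss,
    als_baseline,
    detect_peaks,
    fit_window,
    nitrogen_index_lp,
    nitrogen_index_rp,
    select_main_peak,
)


class TestAlsBaseline:
    def test_constant_signal_is_its_own_baseline(self):
        y = np.full(50, 3.7)
        res = als_baseline(y)
        assert np.allclose(res.baseline, 3.7, atol=1e-6)
        assert np.all(res.corrected >= 0)

    def test_all_zero(self):
        res = als_baseline(np.zeros(20))
        assert np.allclose(res.baseline, 0.0, atol=1e-9)
        assert np.allclose(res.corrected, 0.0)

    def test_recovers_linear_drift_under_peak(self, rng):
        x = np.linspace(0, 100, 400)
        drift = 20.0 + 0.1 * x
        peak = 10.0 * np.exp(-((x - 50) ** 2) / (2 * 2.0 ** 2))
        noise = rng.normal(0, 10.0 / 50, x.size)  # SNR 50 on the peak
        res = als_baseline(drift + peak + noise, lam=1e5)
        off_peak = (x < 35) | (x > 65)
        rel = np.abs(res.baseline[off_peak] - drift[off_peak]) / drift[off_peak]
        assert np.median(rel) < 0.02

    def test_baseline_never_exceeds_running_max(self, rng):
        y = np.abs(rng.normal(5, 1, 100))
        res = als_baseline(y)
        assert res.baseline.max() <= y.max() + 1e-9
        assert np.all(res.corrected >= 0)

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            als_baseline(np.ones(5))

    def test_rejects_bad_params(self):
        y = np.ones(20)
        for kw in ({"lam": 0}, {"p": 0.0}, {"p": 1.0}, {"maxit": 0}):
            with pytest.raises(ValueError):
                als_baseline(y, **kw)


class TestPeakDetection:
    def test_two_peaks(self):
        assert detect_peaks(np.array([0, 1, 0, 2, 0.0])).tolist() == [1, 3]

    def test_monotone_ramp_has_none(self):
        assert detect_peaks(np.arange(10.0)).size == 0

    def test_plateau_resolves_to_lowest_index(self):
        assert detect_peaks(np.array([0, 3, 3, 3, 0.0])).tolist() == [1]

    def test_main_peak_tie_breaks_low(self):
        y = np.array([0, 3, 0, 3, 0.0])
        assert select_main_peak(detect_peaks(y), y) == 1

    def test_main_peak_by_intensity(self):
        y = np.array([0, 1, 0, 5, 0.0])
        assert select_main_peak(detect_peaks(y), y) == 3

    def test_empty_peak_list_raises_distinct_error(self):
        with pytest.raises(NoPeakError):
            select_main_peak([], np.zeros(5))


class TestFitWindow:
    def test_default_width_from_resolving_power(self):
        mz = np.arange(4480.0, 4550.0, 0.5)
        inten = np.ones_like(mz)
        sp = Spectrum(mz, inten, mode="LP", resolving_power=1000)
        peak = int(np.argmin(np.abs(mz - 4515)))
        wx, _, clipped = fit_window(sp, peak)
        assert not clipped
        # 3 x instrument FWHM = 3 x 4515/1000 = 13.5 Da each side
        assert wx[0] == pytest.approx(4515 - 13.5, abs=0.5)
        assert wx[-1] == pytest.approx(4515 + 13.5, abs=0.5)

    def test_edge_peak_clipped_and_flagged(self):
        mz = np.arange(4480.0, 4550.0, 0.5)
        sp = Spectrum(mz, np.ones_like(mz), mode="LP", resolving_power=1000)
        _, _, clipped = fit_window(sp, 2)
        assert clipped

    def test_too_few_points_rejected(self):
        mz = np.arange(4480.0, 4550.0, 5.0)
        sp = Spectrum(mz, np.ones_like(mz), mode="LP", resolving_power=1000)
        with pytest.raises(ValueError):
            fit_window(sp, 7, half_width=5.0)


class TestAsymmetricGaussianFit:
    def test_symmetric_noiseless(self):
        x = np.linspace(-10, 10, 200)
        y = _asym_gauss(x, 5.0, 0.0, 2.0, 2.0)
        fit = AsymmetricGaussianModel(x, y).fit()
        assert fit.sigma_left == pytest.approx(2.0, abs=1e-3)
        assert fit.sigma_right == pytest.approx(2.0, abs=1e-3)
        assert fit.fwhm == pytest.approx(4 * SQRT_2LN2, abs=5e-3)
        assert fit.r_squared > 0.999

    def test_asymmetric_noiseless(self):
        x = np.linspace(-10, 15, 300)
        y = _asym_gauss(x, 3.0, 1.0, 1.5, 3.0)
        fit = AsymmetricGaussianModel(x, y).fit()
        for got, true in ((fit.amplitude, 3.0), (fit.center, 1.0),
                          (fit.sigma_left, 1.5), (fit.sigma_right, 3.0)):
            assert got == pytest.approx(true, abs=1e-2)

    def test_noisy_recovery_median_within_5pct(self):
        # 100-seed recovery at SNR 20
        x = np.linspace(-12, 12, 240)
        errs, r2s = [], []
        for seed in range(100):
            r = np.random.default_rng(seed)
            y = _asym_gauss(x, 4.0, 0.0, 1.5, 3.0) + r.normal(0, 4.0 / 20, x.size)
            fit = AsymmetricGaussianModel(x, y).fit()
            errs.append(max(abs(fit.sigma_left - 1.5) / 1.5,
                            abs(fit.sigma_right - 3.0) / 3.0,
                            abs(fit.amplitude - 4.0) / 4.0))
            r2s.append(fit.r_squared)
        assert np.median(errs) < 0.05
        assert np.median(r2s) > 0.90


class TestNitrogenIndexLP:
    def test_fwhm_nondecreasing_in_enrichment(self, abeta_comp):
        qs = np.arange(0.05, 0.41, 0.05)
        vals = []
        for q in qs:
            pat = isotopologue_pattern(abeta_comp, EnrichmentParams(q=q))
            sp = render_pattern_spectrum(pat, mode="LP", snr=20.0, seed=7)
            ni = nitrogen_index_lp(sp)
            assert ni.qc_pass
            vals.append(ni.value)
        assert np.all(np.diff(vals) >= 0)

    def test_natural_peak_width_bracketed_by_variance_additivity(
            self, abeta_natural_pattern):
        # the envelope FWHM must exceed the bare instrument FWHM and stay
        # below the quadrature sum (the isotope envelope is right-skewed,
        # so its variance overstates its FWHM contribution)
        sp = render_pattern_spectrum(abeta_natural_pattern, mode="LP",
                                     snr=np.inf, seed=0)
        ni = nitrogen_index_lp(sp)
        inst_fwhm = 4515.0 / 1000.0
        pat = abeta_natural_pattern
        mu = np.average(pat.masses, weights=pat.abundances)
        var = np.average((pat.masses - mu) ** 2, weights=pat.abundances)
        quadrature = np.sqrt(inst_fwhm ** 2 + (2 * SQRT_2LN2) ** 2 * var)
        assert inst_fwhm < ni.value <= quadrature
        assert ni.value == pytest.approx(quadrature, rel=0.25)

    def test_flat_noise_fails_qc(self, rng):
        mz = np.arange(4470.0, 4600.0, 0.1)
        sp = Spectrum(mz, np.abs(rng.normal(1, 0.3, mz.size)), mode="LP",
                      resolving_power=1000)
        assert not nitrogen_index_lp(sp).qc_pass

    def test_mode_guard(self):
        mz = np.arange(4505.0, 4545.0, 0.04)
        sp = Spectrum(mz, np.ones_like(mz), mode="RP", resolving_power=15000)
        with pytest.raises(ValueError):
            nitrogen_index_lp(sp)


class TestNitrogenIndexRP:
    @pytest.mark.parametrize("q", [0.10, N15_NATURAL])
    def test_noiseless_matches_theoretical_ratio(self, abeta_comp, q):
        pat = isotopologue_pattern(abeta_comp, EnrichmentParams(q=q), charge=1)
        sp = render_pattern_spectrum(pat, mode="RP", snr=np.inf, seed=0)
        ni = nitrogen_index_rp(sp)
        assert ni.qc_pass
        assert ni.value == pytest.approx(theoretical_peak_ratio(pat, 4, 3),
                                         rel=0.02)

    def test_monotone_in_enrichment_noiseless(self, abeta_comp):
        vals = []
        for q in (0.0, 0.05, 0.10, 0.15, 0.20, 0.25):
            pat = isotopologue_pattern(abeta_comp, EnrichmentParams(q=q), charge=1)
            sp = render_pattern_spectrum(pat, mode="RP", snr=np.inf, seed=0)
            vals.append(nitrogen_index_rp(sp).value)
        assert np.all(np.diff(vals) > 0)

    def test_unresolvable_resolving_power_fails_qc(self, abeta_comp):
        pat = isotopologue_pattern(abeta_comp, EnrichmentParams(), charge=1)
        sp = render_pattern_spectrum(pat, mode="RP", snr=np.inf, seed=0)
        low = Spectrum(sp.mz, sp.intensity, mode="RP", resolving_power=1000)
        ni = nitrogen_index_rp(low)
        assert not ni.qc_pass


class TestRankingProperty:
    @pytest.mark.parametrize("mode,func,snr,pairs", [
        ("LP", nitrogen_index_lp, 20.0,
         ((0.05, 0.15), (0.10, 0.30), (0.15, 0.25))),
        # RP pairs stay where the 3rd/4th isotopologues (counted from the
        # monoisotopic bin) clear the noise floor: their abundance falls
        # steeply with enrichment, so the usable range shrinks with SNR
        ("RP", nitrogen_index_rp, 20.0, ((N15_NATURAL, 0.05),)),
        ("RP", nitrogen_index_rp, 100.0, ((N15_NATURAL, 0.05), (0.05, 0.10))),
    ])
    def test_index_order_follows_enrichment(self, abeta_comp, mode, func,
                                            snr, pairs):
        # same noise seed, q1 < q2 -> index(q1) < index(q2)
        for q1, q2 in pairs:
            v = []
            for q in (q1, q2):
                pat = isotopologue_pattern(abeta_comp, EnrichmentParams(q=q),
                                           charge=1)
                sp = render_pattern_spectrum(pat, mode=mode, snr=snr, seed=11)
                ni = func(sp)
                assert ni.qc_pass, ni.reason
                v.append(ni.value)
            assert v[0] < v[1]

    def test_rp_rejects_unmeasurable_high_enrichment(self, abeta_comp):
        pat = isotopologue_pattern(abeta_comp, EnrichmentParams(q=0.30), charge=1)
        sp = render_pattern_spectrum(pat, mode="RP", snr=20.0, seed=11)
        assert not nitrogen_index_rp(sp).qc_pass
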