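"""CSA sorting and amide-I deconvolution on ground-truth synthetic data."""

import numpy as np
import pytest

from silkbundle import experiment as E
from silkbundle import synthetic as S


class TestCsaSorting:
    def test_nearest_center(self):
        scheme = E.CsaSortScheme()
        assert scheme.assign(0.0021) == 1
        assert scheme.assign(0.023) == 5

    def test_tie_breaks_toward_smaller_center(self):
        scheme = E.CsaSortScheme()
        assert scheme.assign(0.0045) == 1   # equidistant 0.002 / 0.007

    def test_every_positive_csa_maps(self):
        scheme = E.CsaSortScheme()
        for csa in np.geomspace(1e-4, 0.1, 50):
            assert 1 <= scheme.assign(csa) <= 5

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            E.sort_curves([])

    def test_cohort_recovery_within_one_sd(self):
        spec = S.SyntheticCohortSpec(n_per_sort=12)
        curves, truth = S.gen_cohort(spec, seed=5)
        agg = E.sort_curves(curves)
        assert set(agg) == {1, 2, 3, 4, 5}
        for label, d in agg.items():
            t = truth[label]
            sd_mod = spec.modulus_sd[label - 1]
            assert abs(d["modulus_mean"] - t["modulus_gpa"]) < sd_mod
            sd_tough = spec.toughness_sd[label - 1]
            assert abs(d["toughness_mean"] - t["toughness_mj_m3"]) < sd_tough

    def test_order_invariance(self):
        curves, _ = S.gen_cohort(S.SyntheticCohortSpec(n_per_sort=4), seed=2)
        a = E.sort_curves(curves)
        b = E.sort_curves(list(reversed(curves)))
        for label in a:
            assert a[label]["modulus_mean"] == pytest.approx(
                b[label]["modulus_mean"], rel=1e-12)


class TestSecondDerivativePeaks:
    def test_three_separated_gaussians(self):
        layout = ((1615.0, 9.0, "beta-sheet"),
                  (1655.0, 9.0, "random coil/helix"),
                  (1695.0, 9.0, "turn"))
        spec = S.gen_ftir_spectrum(40.0, peak_layout=layout, noise_sd=0.0)
        centers = E.second_derivative_peaks(spec)
        assert len(centers) == 3
        for true_c in (1615, 1655, 1695):
            assert np.abs(centers - true_c).min() <= 2.0

    def test_single_gaussian(self):
        layout = ((1650.0, 10.0, "random coil/helix"),)
        spec = S.gen_ftir_spectrum(0.0, peak_layout=layout)
        centers = E.second_derivative_peaks(spec)
        assert len(centers) == 1
        assert centers[0] == pytest.approx(1650.0, abs=1.0)

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        w = np.arange(1400.0, 1750.0)
        spec = E.FTIRSpectrum(w, 1e-6 * rng.standard_normal(len(w)))
        with pytest.raises((E.PeakPickError, ValueError)):
            E.second_derivative_peaks(spec)

    def test_window_not_covered_raises(self):
        spec = E.FTIRSpectrum(np.arange(1650.0, 1750.0), np.ones(100))
        with pytest.raises(ValueError):
            E.second_derivative_peaks(spec)


class TestAmideIDeconvolution:
    def test_noise_free_recovery_exact(self):
        spec = S.gen_ftir_spectrum(40.0, noise_sd=0.0)
        res = E.AmideIModel(spec).fit()
        assert res.beta_fraction == pytest.approx(40.0, abs=0.5)
        assert not res.flagged

    def test_component_sum_residual_small(self):
        spec = S.gen_ftir_spectrum(35.0, noise_sd=0.0)
        res = E.AmideIModel(spec).fit()
        assert res.residual_fraction <= 0.02

    def test_recovery_grid_within_3_points(self):
        # the reported spreads on real spectra are +-3-5 points
        for beta in (20.0, 30.0, 40.0, 50.0):
            for seed in (0, 1, 2):
                spec = S.gen_ftir_spectrum(beta, noise_sd=0.01, seed=seed)
                res = E.AmideIModel(spec).fit()
                assert abs(res.beta_fraction - beta) <= 3.0, (beta, seed)

    def test_single_beta_peak_is_all_beta(self):
        layout = ((1622.0, 10.0, "beta-sheet"),)
        spec = S.gen_ftir_spectrum(100.0, peak_layout=layout)
        res = E.AmideIModel(spec).fit()
        assert res.beta_fraction == pytest.approx(100.0)

    def test_replicates_report_spread(self):
        vals = [E.AmideIModel(S.gen_ftir_spectrum(40.0, noise_sd=0.02,
                                                  seed=s)).fit().beta_fraction
                for s in range(5)]
        assert np.std(vals) > 0
        assert abs(np.mean(vals) - 40.0) < 3.0

    def test_summary_mentions_beta(self):
        res = E.AmideIModel(S.gen_ftir_spectrum(40.0)).fit()
        assert "beta-sheet fraction" in res.summary()


class TestNormalizationAndDichroism:
    def test_normalized_at_anchor(self):
        spec = S.gen_ftir_spectrum(40.0).normalize()
        at_anchor = np.interp(1450.0, spec.wavenumber, spec.absorbance)
        assert at_anchor == pytest.approx(1.0, rel=1e-6)

    def test_descending_grid_is_sorted(self):
        w = np.arange(1750.0, 1400.0, -1.0)
        spec = E.FTIRSpectrum(w, np.ones(len(w)))
        assert np.all(np.diff(spec.wavenumber) > 0)

    def test_dichroic_ratio(self):
        par = S.gen_ftir_spectrum(60.0, seed=1)
        perp = S.gen_ftir_spectrum(30.0, seed=1)
        ratio = E.dichroic_ratio(par, perp, band=1620.0)
        assert ratio > 1.0
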