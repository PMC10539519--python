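"""Two-Lorentzian deconvolution, populations and van't Hoff fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import lmfit

from confdesign.thermo import (R_GAS, LorentzianPeak, Spectrum1D, TwoStateThermo,
                               deconvolute_two_lorentzians, fit_vant_hoff,
                               gibbs_at_temperature, ln_keq_vant_hoff,
                               populations_from_peaks)
from confdesign.synthetic import make_two_state_spectra, make_vant_hoff_series

HEX = dict(dh_ref=-9.9, ds_ref=-0.032, dcp=0.972)


def _spectrum(peaks, baseline=0.0, lo=-63.0, hi=-59.0, n=400, temperature=298.0):
    x = np.linspace(lo, hi, n)
    y = np.full_like(x, baseline)
    for p in peaks:
        y = y + p.evaluate(x)
    return Spectrum1D(x, y, temperature)


class TestLorentzian:
    def test_area_formula_matches_numerical_integration(self):
        """π·amplitude·hwhm is the analytic area; a ±w·hwhm window captures
        the fraction (2/π)·arctan(w) of it (heavy Lorentzian tails)."""
        p = LorentzianPeak(-61.0, 0.12, 3.0)
        f = lambda x: p.amplitude / (1 + ((x - p.center) / p.hwhm) ** 2)
        num50, _ = quad(f, p.center - 50 * p.hwhm, p.center + 50 * p.hwhm, limit=500)
        assert num50 == pytest.approx(p.area * 2.0 / math.pi * math.atan(50.0), rel=1e-9)
        num_wide, _ = quad(f, p.center - 700 * p.hwhm, p.center + 700 * p.hwhm, limit=500)
        assert num_wide == pytest.approx(p.area, rel=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LorentzianPeak(0.0, -0.1, 1.0)
        with pytest.raises(ValueError):
            LorentzianPeak(0.0, 0.1, -1.0)


class TestDeconvolution:
    def test_noiseless_parameters_recovered(self):
        true_a = LorentzianPeak(-60.4, 0.12, 2.0)
        true_b = LorentzianPeak(-61.6, 0.08, 5.0)
        s = _spectrum([true_a, true_b], baseline=0.3)
        pa, pb, bl, resid = deconvolute_two_lorentzians(s)
        # ordered by center descending: pa is the downfield peak
        assert pa.center == pytest.approx(true_a.center, abs=1e-6)
        assert pb.center == pytest.approx(true_b.center, abs=1e-6)
        assert pa.hwhm == pytest.approx(true_a.hwhm, rel=1e-6)
        assert pb.area == pytest.approx(true_b.area, rel=1e-6)
        assert bl == pytest.approx(0.3, abs=1e-6)
        assert resid < 1e-6

    def test_single_peak_input_flags_degenerate(self):
        s = _spectrum([LorentzianPeak(-61.0, 0.1, 4.0)])
        with pytest.warns(UserWarning, match="degenerate"):
            pa, pb, _, _ = deconvolute_two_lorentzians(s)
        assert min(pa.area, pb.area) < 1e-4 * max(pa.area, pb.area)

    def test_two_peak_fit_beats_single_lorentzian(self):
        s = _spectrum([LorentzianPeak(-60.4, 0.12, 2.0), LorentzianPeak(-61.6, 0.08, 5.0)])
        *_, resid2 = deconvolute_two_lorentzians(s)
        single = (lmfit.models.LorentzianModel() + lmfit.models.ConstantModel(prefix="b_"))
        params = single.make_params(center=-61.0, sigma=0.1, amplitude=1.0, b_c=0.0)
        res1 = single.fit(s.intensity, params, x=s.axis)
        assert resid2 <= float(np.linalg.norm(res1.residual)) + 1e-12

    def test_too_few_points_rejected(self):
        x = np.linspace(-62, -60, 10)
        with pytest.raises(ValueError, match="20"):
            deconvolute_two_lorentzians(Spectrum1D(x, np.ones_like(x), 298.0))


class TestPopulations:
    def test_equal_areas(self):
        a = LorentzianPeak(-60.4, 0.1, 1.0)
        b = LorentzianPeak(-61.6, 0.1, 1.0)
        pa, pb, keq = populations_from_peaks(a, b)
        assert (pa, pb) == (0.5, 0.5)
        assert keq == 1.0

    def test_three_to_one_ratio(self):
        upfield = LorentzianPeak(-61.6, 0.1, 3.0)   # closed by default
        downfield = LorentzianPeak(-60.4, 0.1, 1.0)
        _, _, keq = populations_from_peaks(upfield, downfield)
        assert keq == pytest.approx(3.0, rel=1e-12)
        _, _, inv = populations_from_peaks(upfield, downfield, closed="downfield")
        assert inv == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_populations_sum_to_one(self, rng):
        for _ in range(10):
            a = LorentzianPeak(-60.4, rng.uniform(0.05, 0.3), rng.uniform(0.1, 5))
            b = LorentzianPeak(-61.6, rng.uniform(0.05, 0.3), rng.uniform(0.1, 5))
            pa, pb, _ = populations_from_peaks(a, b)
            assert pa + pb == pytest.approx(1.0, abs=1e-12)

    def test_fitted_fixture_matches_generator_populations(self):
        spectra = make_two_state_spectra(**HEX, temperatures=[288.0])
        keq_true = math.exp(float(ln_keq_vant_hoff(288.0, **HEX)))
        pa, pb, _, _ = deconvolute_two_lorentzians(spectra[0])
        _, _, keq = populations_from_peaks(pa, pb)
        assert keq == pytest.approx(keq_true, rel=1e-4)


class TestVantHoff:
    def test_noiseless_nonlinear_recovery(self):
        obs = make_vant_hoff_series(**HEX)
        fit = fit_vant_hoff(obs, model="nonlinear")
        assert fit.dh_ref == pytest.approx(HEX["dh_ref"], rel=1e-6)
        assert fit.ds_ref == pytest.approx(HEX["ds_ref"], rel=1e-6)
        assert fit.dcp == pytest.approx(HEX["dcp"], rel=1e-6)

    def test_linear_slope_is_minus_dh_over_r(self):
        obs = make_vant_hoff_series(dh_ref=-5.0, ds_ref=-0.01, dcp=0.0)
        fit = fit_vant_hoff(obs, model="linear")
        t = np.array([o[0] for o in obs])
        lnk = np.log([o[1] for o in obs])
        slope = np.polyfit(1.0 / t, lnk, 1)[0]
        assert slope == pytest.approx(-fit.dh_ref / R_GAS, rel=1e-9)
        assert fit.dcp == 0.0

    def test_nonlinear_residual_not_worse_on_curved_data(self):
        obs = make_vant_hoff_series(**HEX)
        lin = fit_vant_hoff(obs, model="linear")
        non = fit_vant_hoff(obs, model="nonlinear")
        t = np.array([o[0] for o in obs])
        lnk = np.log([o[1] for o in obs])
        r_lin = np.linalg.norm(lnk - lin.ln_keq(t))
        r_non = np.linalg.norm(lnk - non.ln_keq(t))
        assert r_non <= r_lin + 1e-12

    def test_insufficient_points_rejected(self):
        obs = make_vant_hoff_series(**HEX, temperatures=[278.0, 288.0, 298.0])
        with pytest.raises(ValueError, match="≥4"):
            fit_vant_hoff(obs, model="nonlinear")


class TestGibbs:
    def test_closed_form_at_reference_temperature(self):
        t = TwoStateThermo(-9.9, -0.032, 0.972)
        assert gibbs_at_temperature(t, 298.0) == \
            pytest.approx(-9.9 - 298.0 * -0.032, rel=1e-12)

    def test_consistent_with_keq_identity(self):
        t = TwoStateThermo(**HEX)
        for temp in (278.0, 288.0, 298.0, 308.0, 350.0):
            lhs = -R_GAS * temp * float(t.ln_keq(temp))
            assert gibbs_at_temperature(t, temp) == pytest.approx(lhs, abs=1e-9)

    def test_noise_recovery_within_reported_confidence(self):
        """1% ln-Keq noise: parameters inside their t-based 95% CIs ≥90% of 500 runs."""
        from scipy import stats

        true = (HEX["dh_ref"], HEX["ds_ref"], HEX["dcp"])
        tq = stats.t.ppf(0.975, 7 - 3)
        hits = 0
        n = 500
        for i in range(n):
            obs = make_vant_hoff_series(**HEX, noise_sd=0.01, seed=40_000 + i)
            f = fit_vant_hoff(obs)
            est = (f.dh_ref, f.ds_ref, f.dcp)
            sig = (f.uncertainties["dh_ref"], f.uncertainties["ds_ref"],
                   f.uncertainties["dcp"])
            if all(abs(e - t0) <= tq * s for e, t0, s in zip(est, true, sig)):
                hits += 1
        assert hits >= 0.90 * n
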