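"""Device-law unit and property tests: antiambipolar, monotone OECT, amplifier."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coecn.devices import (AmplifierParams, AntiambipolarParams, OECTParams,
                           ParameterDomainError, amplifier_output,
                           antiambipolar_current, fit_antiambipolar,
                           oect_current, read_transfer_csv, rise_time_10_90,
                           switching_time, two_species_current)

REF = AntiambipolarParams(I_peak0=5e-6, V_P0=1.0, sigma_rise=0.15,
                          sigma_fall=0.15, V_DS_ref=0.325)


class TestAntiambipolar:
    def test_peak_value_at_VP(self):
        # at the peak gate voltage the current equals I_peak (max by construction)
        assert antiambipolar_current(1.0, 0.325, REF) == pytest.approx(5e-6, rel=1e-4)

    def test_one_sigma_closed_form(self):
        # 5 uA * exp(-0.5) at one width above the peak
        I = antiambipolar_current(1.15, 0.325, REF)
        assert I == pytest.approx(5e-6 * np.exp(-0.5), rel=1e-3)

    def test_gaussian_tail_negligible(self):
        assert antiambipolar_current(1.0 + 10 * 0.15, 0.325, REF) < 1e-20 * 5e-6

    def test_zero_drain_bias_gives_zero_current(self):
        assert antiambipolar_current(1.0, 0.0, REF) == 0.0

    def test_negative_drain_bias_rejected(self):
        with pytest.raises(ParameterDomainError):
            antiambipolar_current(1.0, -0.1, REF)

    def test_negative_computed_peak_rejected(self):
        p = AntiambipolarParams(I_peak0=1e-6, V_P0=1.0, sigma_rise=0.1,
                                sigma_fall=0.1, V_DS_ref=0.5, k_peak=1e-5)
        with pytest.raises(ParameterDomainError):
            antiambipolar_current(1.0, 0.0, p)

    @given(vp=st.floats(0.5, 1.2), sr=st.floats(0.02, 0.3),
           sf=st.floats(0.02, 0.3), vds=st.floats(0.1, 0.6))
    def test_unimodal_in_gate_voltage(self, vp, sr, sf, vds):
        # the discrete derivative on a fine grid changes sign exactly once
        p = AntiambipolarParams(I_peak0=1e-5, V_P0=vp, sigma_rise=sr,
                                sigma_fall=sf, V_DS_ref=vds)
        vg = np.linspace(vp - 5 * sr, vp + 5 * sf, 2001)
        I = antiambipolar_current(vg, vds, p)
        signs = np.sign(np.diff(I))
        changes = np.count_nonzero(np.diff(signs[signs != 0]))
        assert changes == 1
        assert np.all(I >= 0)
        assert abs(vg[np.argmax(I)] - vp) < 2 * (vg[1] - vg[0])

    def test_peak_and_width_grow_with_drain_bias(self):
        p = AntiambipolarParams(I_peak0=5e-6, V_P0=1.0, sigma_rise=0.1,
                                sigma_fall=0.1, V_DS_ref=0.3, k_peak=5e-6,
                                k_VP=0.05, k_sigma=0.3)
        vg = np.linspace(0.2, 1.8, 4001)

        def peak_and_fwhm(vds):
            I = np.asarray(antiambipolar_current(vg, vds, p))
            above = vg[I >= I.max() / 2]
            return I.max(), above[-1] - above[0]

        peaks, widths = zip(*(peak_and_fwhm(v) for v in (0.2, 0.3, 0.45, 0.6)))
        assert np.all(np.diff(peaks) > 0)
        assert np.all(np.diff(widths) > 0)

    def test_continuity_across_peak(self):
        p = AntiambipolarParams(I_peak0=5e-6, V_P0=1.0, sigma_rise=0.05,
                                sigma_fall=0.2, V_DS_ref=0.3)
        vg = np.linspace(0.9, 1.1, 20001)
        I = np.asarray(antiambipolar_current(vg, 0.3, p))
        assert np.max(np.abs(np.diff(I))) < 1e-3 * p.I_peak0


class TestTwoSpecies:
    P = AntiambipolarParams(I_peak0=1e-5, V_P0=1.0, sigma_rise=0.1,
                            sigma_fall=0.1, form="two_species",
                            V_Na_s=0.4, mu_Na_s=2e-4, V_Na_m=0.9,
                            mu_Na_m=1e-6, w_m=0.05)

    def test_below_threshold_zero(self):
        assert two_species_current(0.3, 0.3, self.P) == 0.0

    def test_full_conversion_kills_current(self):
        # far above the multiply-charged onset with ~zero converted mobility
        from dataclasses import replace
        p = replace(self.P, mu_Na_m=1e-12)
        high = two_species_current(2.5, 0.3, p)
        assert high < 1e-3 * two_species_current(0.9, 0.3, p)

    def test_rises_then_falls(self):
        vg = np.linspace(0.0, 2.0, 2001)
        I = np.asarray(two_species_current(vg, 0.3, self.P))
        imax = np.argmax(I)
        assert 0 < imax < len(vg) - 1
        assert I[imax] > I[-1] and I[imax] > I[0]

    def test_peak_location_regression(self):
        # dense 1-D grid search oracle, frozen values
        vg = np.linspace(0.0, 2.0, 200001)
        I = np.asarray(two_species_current(vg, 0.3, self.P))
        assert vg[np.argmax(I)] == pytest.approx(0.82514, abs=1e-3)
        assert I.max() == pytest.approx(1.35050e-5, rel=1e-3)

    def test_no_conversion_limit_equals_oect_law(self):
        # with equal prefactors the law reduces to a standard transistor
        from dataclasses import replace
        p = replace(self.P, mu_Na_m=2e-4 * (1 - 1e-12))
        k = OECTParams(V_T=p.V_Na_s, K_g=p.mu_Na_s)
        vg = np.linspace(0.0, 2.0, 101)
        for vds in (0.1, 0.3, 0.8):
            np.testing.assert_allclose(
                np.asarray(two_species_current(vg, vds, p)),
                np.asarray(oect_current(vg, vds, k)), rtol=1e-6, atol=1e-15)


class TestOECT:
    K = OECTParams(V_T=0.3, K_g=1e-3)

    def test_threshold_zero(self):
        assert oect_current(0.3, 0.5, self.K) == 0.0

    def test_saturation_closed_form(self):
        # K_g = 1 mA/V^2, overdrive 0.2 V, saturated -> 20 uA
        assert oect_current(0.5, 1.0, self.K) == pytest.approx(20e-6, rel=1e-9)

    def test_zero_drain_bias(self):
        assert oect_current(1.5, 0.0, self.K) == 0.0

    @given(v1=st.floats(0.0, 2.0), v2=st.floats(0.0, 2.0),
           d1=st.floats(0.0, 1.0), d2=st.floats(0.0, 1.0))
    def test_monotone_in_both_arguments(self, v1, v2, d1, d2):
        lo, hi = sorted((v1, v2))
        dlo, dhi = sorted((d1, d2))
        assert oect_current(lo, dlo, self.K) <= oect_current(hi, dlo, self.K) + 1e-18
        assert oect_current(hi, dlo, self.K) <= oect_current(hi, dhi, self.K) + 1e-18

    def test_continuity_at_regime_boundary(self):
        vgs = np.linspace(0.3, 1.5, 40001)
        I = np.asarray(oect_current(vgs, 0.4, self.K))
        assert np.max(np.abs(np.diff(I))) < 1e-3 * I.max()

    def test_subthreshold_swing_smooths_threshold(self):
        soft = OECTParams(V_T=0.3, K_g=1e-3, V_ss=0.03)
        assert oect_current(0.25, 0.5, soft) > 0
        # far above threshold the soft law converges to the hard one
        assert oect_current(1.0, 1.0, soft) == pytest.approx(
            oect_current(1.0, 1.0, self.K), rel=1e-3)


class TestAmplifier:
    AMP = AmplifierParams()

    def test_printed_calibration_pairs(self):
        # resting membrane 0.175 V -> 1.2 V on the Na gate; spike peak
        # 0.34 V -> 0.8 V
        assert amplifier_output(0.175, self.AMP) == pytest.approx(1.2, abs=1e-3)
        assert amplifier_output(0.34, self.AMP) == pytest.approx(0.8, abs=1e-3)

    def test_rail_clamp(self):
        assert amplifier_output(10.0, self.AMP) == self.AMP.rail_low
        assert amplifier_output(-10.0, self.AMP) == self.AMP.rail_high

    def test_strictly_decreasing_between_rails(self):
        v = np.linspace(0.12, 0.45, 100)
        out = np.asarray(amplifier_output(v, self.AMP))
        inside = (out > self.AMP.rail_low) & (out < self.AMP.rail_high)
        assert np.all(np.diff(out[inside]) < 0)

    def test_non_inverting_gain_rejected(self):
        with pytest.raises(ParameterDomainError):
            AmplifierParams(gain=1.0)


class TestStepResponse:
    def test_rise_time_of_first_order_voltage(self):
        # pure exponential: 10-90% rise = ln(9) * tau
        tau = 1e-3
        t = np.linspace(0, 10 * tau, 10000)
        y = 1 - np.exp(-t / tau)
        assert rise_time_10_90(t, y) == pytest.approx(np.log(9) * tau, rel=1e-3)

    def test_switching_time_scales_with_gate_RC(self):
        k1 = OECTParams(V_T=0.25, K_g=0.1, C_g=1e-7, R_g_intrinsic=1e3)
        k2 = OECTParams(V_T=0.25, K_g=0.1, C_g=1e-7, R_g_intrinsic=2e3)
        assert switching_time(k2) == pytest.approx(2 * switching_time(k1), rel=1e-3)


class TestTransferFit:
    def test_round_trip_on_synthetic_curve(self, tmp_path):
        import pandas as pd

        truth = AntiambipolarParams(I_peak0=8e-6, V_P0=0.95, sigma_rise=0.12,
                                    sigma_fall=0.18, V_DS_ref=0.4,
                                    k_peak=4e-6, k_VP=0.06, k_sigma=0.2)
        rng = np.random.default_rng(7)
        rows = []
        for vds in (0.3, 0.4, 0.5):
            vg = np.linspace(0.3, 1.7, 80)
            I = np.asarray(antiambipolar_current(vg, vds, truth))
            I = I + rng.normal(0, 2e-9, I.shape)
            rows.append(pd.DataFrame({"V_G_V": vg, "V_DS_V": vds, "I_D_A": I}))
        table = pd.concat(rows, ignore_index=True)
        path = tmp_path / "transfer.csv"
        table.to_csv(path, index=False)

        fit = fit_antiambipolar(read_transfer_csv(path))
        assert fit.I_peak0 == pytest.approx(truth.I_peak0, rel=0.02)
        assert fit.V_P0 == pytest.approx(truth.V_P0, abs=0.01)
        assert fit.sigma_rise == pytest.approx(truth.sigma_rise, rel=0.1)
        assert fit.sigma_fall == pytest.approx(truth.sigma_fall, rel=0.1)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_transfer_csv(path)
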