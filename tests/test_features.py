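"""Spike detection, classification and ISI-statistics tests on constructed
waveforms, plus battery behaviour on the reference neuron."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coecn.circuit import SimulationTrace
from coecn.features import (NoExcitabilityError, SpikeTrain,
                            classify_excitability, detect_spikes,
                            energy_metrics, skipping_statistics, steady_rate)


def make_trace(t, v, I_in=None, I_Na=None, I_K=None):
    z = np.zeros_like(t)
    return SimulationTrace(t=t, V_mem=v, V_gk=z.copy(),
                           I_in=z.copy() if I_in is None else I_in,
                           I_Na=z.copy() if I_Na is None else I_Na,
                           I_K=z.copy() if I_K is None else I_K)


class TestDetectSpikes:
    def test_subthreshold_trace_has_no_spikes(self):
        t = np.linspace(0, 1, 1000)
        tr = make_trace(t, np.full_like(t, 0.1))
        assert len(detect_spikes(tr, 0.25)) == 0

    def test_sawtooth_count_matches_frequency(self, sawtooth_trace):
        # 5 Hz sawtooth over 4 s crosses the threshold 20 times
        train = detect_spikes(sawtooth_trace, 0.25)
        assert len(train) == 20
        assert steady_rate(train, 4.0) == pytest.approx(5.0, rel=1e-3)

    def test_interpolation_consistency_under_resampling(self):
        # doubling the sampling density moves each spike by < half a sample
        rng = np.random.default_rng(3)
        t1 = np.arange(0, 2, 1e-3)
        t2 = np.arange(0, 2, 5e-4)
        f = lambda t: 0.2 + 0.15 * np.sin(2 * np.pi * 7 * t)
        s1 = detect_spikes(make_trace(t1, f(t1)), 0.25).spike_times
        s2 = detect_spikes(make_trace(t2, f(t2)), 0.25).spike_times
        assert len(s1) == len(s2)
        assert np.max(np.abs(s1 - s2)) < 0.5e-3

    @given(thr_lo=st.floats(0.12, 0.38), dthr=st.floats(0.001, 0.2))
    def test_monotone_in_threshold(self, thr_lo, dthr):
        # spikes of graded amplitude: a higher threshold never finds more
        rng = np.random.default_rng(11)
        t = np.arange(0, 2, 1e-3)
        v = np.full_like(t, 0.05)
        for k, height in enumerate(rng.uniform(0.15, 0.45, 18)):
            centre = 0.06 + 0.105 * k
            v += height * np.exp(-0.5 * ((t - centre) / 0.008) ** 2)
        tr = make_trace(t, v)
        assert len(detect_spikes(tr, thr_lo + dthr)) <= len(detect_spikes(tr, thr_lo))

    def test_refractory_enforcement(self):
        t = np.arange(0, 1, 1e-4)
        v = 0.1 + 0.3 * (np.sin(2 * np.pi * 50 * t) > 0.9)
        tr = make_trace(t, v)
        free = detect_spikes(tr, 0.25)
        gated = detect_spikes(tr, 0.25, refractory_min=0.05)
        assert len(gated) < len(free)
        assert np.all(np.diff(gated.spike_times) >= 0.05)

    def test_spike_train_invariants(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.2, 0.1]), 0.25)
        with pytest.raises(ValueError):
            SpikeTrain(np.array([0.1, 0.11]), 0.25, refractory_min=0.05)


class TestClassifier:
    def _onset_trace(self, spike_times, T=3.5, t_on=0.25):
        t = np.arange(0, T, 1e-3)
        v = np.full_like(t, 0.1)
        for s in spike_times:
            v[(t >= s) & (t < s + 0.005)] = 0.35
        I = np.where(t >= t_on, 2e-6, 0.0)
        return make_trace(t, v, I_in=I)

    def test_onset_only_spikes_are_class3(self):
        onset = self._onset_trace([0.3, 0.35])
        assert classify_excitability(
            np.zeros(5), onset) == "class3_phasic_bursting"
        single = self._onset_trace([0.3])
        assert classify_excitability(
            np.zeros(5), single) == "class3_phasic_spiking"

    def test_abrupt_rate_onset_is_class2(self):
        onset = self._onset_trace([0.3, 0.8, 1.3, 1.8, 2.3, 2.8, 3.3])
        f_I = np.array([0.0, 0.0, 8.0, 9.0, 10.0])
        assert classify_excitability(f_I, onset) == "class2"

    def test_continuous_rate_growth_is_class1(self):
        onset = self._onset_trace([0.3, 0.8, 1.3, 1.8, 2.3, 2.8, 3.3])
        f_I = np.array([0.0, 1.0, 4.0, 7.0, 10.0])
        assert classify_excitability(f_I, onset) == "class1"

    def test_no_spikes_anywhere_raises(self):
        onset = self._onset_trace([])
        with pytest.raises(NoExcitabilityError):
            classify_excitability(np.zeros(5), onset)

    def test_resampling_invariance(self):
        onset = self._onset_trace([0.3, 0.35])
        dense = self._onset_trace([0.3, 0.35])
        dense_t = np.arange(0, 3.5, 5e-4)
        dense = make_trace(dense_t, np.interp(dense_t, onset.t, onset.V_mem),
                           I_in=np.interp(dense_t, onset.t, onset.I_in))
        f_I = np.zeros(5)
        assert (classify_excitability(f_I, onset)
                == classify_excitability(f_I, dense))


class TestSkipping:
    def test_noiseless_periodic_train(self):
        train = np.arange(30) * 0.125
        f, skip, multi = skipping_statistics([train])
        assert f == pytest.approx(8.0, rel=1e-6)
        assert skip == 0.0
        assert multi == 1.0

    def test_deleted_spikes_counted_as_skips(self):
        # delete every third spike: of the remaining ISIs, half are doubled
        base = np.arange(60) * 0.125
        kept = np.delete(base, np.arange(2, 60, 3))
        f, skip, multi = skipping_statistics([kept])
        assert f == pytest.approx(8.0, rel=0.02)
        assert skip == pytest.approx(0.5, abs=0.03)
        assert multi == 1.0

    def test_shuffled_surrogate_destroys_multimodality(self):
        # negative control: exponential ISIs have no preferred period
        rng = np.random.default_rng(0)
        isis = rng.exponential(0.125, 400)
        train = np.cumsum(isis)
        _f, _skip, multi = skipping_statistics([train])
        base = np.arange(60) * 0.125
        kept = np.delete(base, np.arange(2, 60, 3))
        _f2, _s2, multi_periodic = skipping_statistics([kept])
        assert multi < multi_periodic

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            skipping_statistics([np.array([0.0, 0.1])])


class TestEnergyMetrics:
    def test_rectangular_sodium_pulse_integral(self):
        # I_Na = 10 uA for 10 ms once per 100 ms period at E_Na = 0.5 V:
        # energy per period = 0.5 V * 10 uA * 10 ms = 50 nJ
        from coecn import configs

        from dataclasses import replace

        # C_gNa = 0 removes the amplifier charging term, leaving only the
        # battery branches, so the integral is computable by hand
        p = replace(configs.config_a(), C_gNa=0.0)
        t = np.arange(0, 1.0, 1e-5)
        v = np.full_like(t, 0.1)
        I_Na = np.zeros_like(t)
        for k in range(10):
            t0 = 0.02 + 0.1 * k
            v[(t >= t0) & (t < t0 + 0.005)] = 0.35  # marker spikes
            I_Na[(t >= t0) & (t < t0 + 0.01)] = 10e-6
        tr = make_trace(t, v, I_Na=I_Na)
        peak, energy = energy_metrics(tr, p)
        # constant V_mem between spikes -> no amplifier term; no K term
        assert energy == pytest.approx(50e-9, rel=0.05)
        assert peak >= 0.5 * 10e-6

    def test_dead_trace_has_no_steady_period(self):
        t = np.arange(0, 1.0, 1e-4)
        tr = make_trace(t, np.full_like(t, 0.1))
        from coecn import configs
        with pytest.raises(RuntimeError, match="steady"):
            energy_metrics(tr, configs.config_a())


class TestBatteryOnReferenceNeuron:
    def test_all_pulse_protocol_features_detected(self):
        # the shipped ~5 Hz neuron exhibits the full pulse-protocol battery
        from coecn import configs
        from coecn.features import feature_battery

        rep = feature_battery(
            configs.config_a(), solver=configs.default_solver("config-a"),
            features=("tonic", "latency", "integration", "refractoriness",
                      "resonance", "threshold_variability", "rebound",
                      "accommodation"))
        assert rep.tonic and rep.tonic_rate == pytest.approx(5.0, rel=0.03)
        assert rep.latency and rep.integration and rep.refractoriness
        assert rep.resonance and rep.threshold_variability
        assert rep.rebound and rep.accommodation

    def test_dead_circuit_reports_everything_false(self):
        # a circuit with no sodium current cannot express any feature
        from dataclasses import replace

        from coecn import configs
        from coecn.electrolyte import Electrolyte, Modulator
        from coecn.features import feature_battery

        kill = Electrolyte(modulators=(Modulator("GABA", 10.0,
                                                 peak_atten=1.0),))
        p = replace(configs.config_a(), na_electrolyte=kill)
        rep = feature_battery(
            p, solver=configs.default_solver("config-a"),
            features=("tonic", "integration", "rebound", "accommodation"))
        assert not rep.tonic and not rep.integration
        assert not rep.rebound and not rep.accommodation
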