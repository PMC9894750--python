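# Methods

## The model

`coecn` simulates a conductance-based organic electrochemical neuron: a
two-transistor circuit in which an *antiambipolar* OECT (drain current rises
and then falls with gate voltage — a Gaussian-shaped transfer curve) plays
the voltage-gated sodium channel, and a conventional monotone OECT plays the
delayed-rectifier potassium channel. The state is two voltages,

```
(C_mem + C_int) dV_mem/dt = I_in(t) + I_Na − I_K − G_L (V_mem − E_L)
R_dk · C_gK     dV_gk/dt  = V_mem − V_gk
```

with

```
I_Na = I_A(amp(V_mem), max(E_Na − V_mem, 0))      (antiambipolar law)
I_K  = I_O(V_gk − E_K,  max(V_mem − E_K, 0))      (monotone OECT law)
```

The inverting amplifier `amp(V) = clamp(g·V + b, rails)` maps the membrane
voltage onto the Na-OECT gate so that depolarisation sweeps the gate *down*
through the transfer-curve peak V_P: approaching the peak is regenerative
(activation), passing it collapses the current (inactivation) — the circuit
analogue of Na-channel gating. The K-OECT gate follows the membrane through
the delay resistor R_dk into the K gate capacitance C_gK, so the potassium
current peaks after the sodium surge, repolarises the node, and transiently
drives it below rest (hyperpolarisation). Effective drain biases float with
the membrane: `E_Na − V_mem` for the sodium branch, `V_mem − E_K` for the
potassium branch.

### Device laws

The Gaussian law (default) is

```
I_A(V_G, V_DS) = I_peak(V_DS) · exp(−(V_G − V_P(V_DS))² / 2σ(V_DS)²)
                 · tanh(V_DS / V_DS_lin)
```

with `I_peak`, `V_P` and `σ` affine in `V_DS` around a reference bias
(peak growth, peak shift and width broadening with drain bias), separate
rise/fall widths, and a `tanh` linear-regime roll-off (width 50 mV) that
guarantees zero current at zero drain bias — ~1 at the operating bias, but
essential so the membrane cannot charge past E_Na. A physically motivated
*two-species* alternative (mobile singly-charged species converting to a
low-mobility multiply-charged species above a second onset voltage, logistic
conversion) is provided behind the same interface; the two coincide with the
standard transistor law in the no-conversion limit. Both are stand-ins
fitted to the same phenomenology; the analytic form used in the original
SPICE models is not public.

The monotone OECT uses the standard quadratic law (linear/saturation
regimes, hard threshold). An optional subthreshold swing `V_ss` replaces the
hard overdrive with an EKV-style softplus, giving the exponential
weak-inversion tail real electrochemical transistors show; the default of 0
keeps the ideal law, and the shipped configurations use the ideal law.

### Electrolyte modulation

Electrolyte composition maps to parameter shifts, not to channel dynamics:
ions shift V_P log-linearly (Nernstian, `−(s/z)·log10(c/c_ref)`, default
slope 59 mV/decade, halved for divalents), modulator molecules shift V_P and
V_K linearly in concentration and attenuate the peak current
multiplicatively with a floor at zero. Acetylcholine is an experimentally
established no-op; the GABA, glutamine, Ca²⁺ and NaCl-sensing coefficients
are calibration constants (marked as such in `electrolyte.py` /
`configs.py`) chosen so the shipped neuron reproduces the documented
endpoint behaviours. Concentrations are piecewise-constant per simulation
segment; diffusion and depletion are out of scope.

## Reference configurations

All device constants are calibrations that realise the printed operating
points of the reference circuit; they are not measured single-device values.

| | config-a | config-b | config-c |
|---|---|---|---|
| role | slow neuron for pulsed protocols | fast neuron, energy bookkeeping | OECT-amplifier variant |
| C_mem | 1 µF | — | — |
| C_int | 150 nF | 100 nF | 90 nF |
| R_dk | 470 kΩ | 19.5 kΩ | 19.5 kΩ |
| E_K | −50 mV | −12 mV | −12 mV |
| I_peak0 | 10 µA | 5 µA | 5 µA |
| K_g | 0.4 A/V² | 0.24 A/V² | 0.24 A/V² |
| amplifier | −2.424 / 1.624 V | same | −2.8 / 1.655 V |
| tonic rate at 2 µA | 5.0 Hz | 80.2 Hz | 100.2 Hz |

Shared constants: E_Na = 0.5 V, V_P0 = 0.87 V, σ = 30 mV, V_K = 0.245 V,
C_gK = 0.7 µF, G_L = 6 µS, E_L = 175 mV, rails [0.5, 1.4] V. The amplifier
gain/offset of the slow neuron are fixed by the printed operating pairs
(0.175 V → 1.2 V, 0.34 V → 0.8 V). The two Na-OECT current scales correspond
to the wide- and narrow-channel device variants; `C_gNa` (the Na gate load
seen by the amplifier output stage, 137 nF in config-b) only enters the
power bookkeeping.

Why these numbers are tight: with I_in = 2 µA into ~1.15 µF the recharge
slope is bounded by 2 V/s, so a 200 ms period forces the Na activation zone
high (threshold ≈ 0.29 V) and a deep after-spike undershoot; simultaneously
the excitability-class switch requires the K-OECT to intercept the
subthreshold climb within a few mV of E_K. A grid search over
(V_P0, σ, I_peak0, V_K, K_g, C_gK, C_int, G_L) located the narrow region
where all printed operating points coexist.

### Power bookkeeping

Instantaneous supply power is
`P(t) = |E_Na·I_Na| + |E_K·I_K| + V_rail·|C_gNa·dV_G/dt|` — the two battery
branches plus the amplifier output stage, whose current is modelled as the
Na-OECT gate charging current. Energy per spike integrates P over the last
full interspike period; peak power is the maximum over that period. In the
fast neuron the amplifier term dominates (the battery branches contribute
≈8 nJ of the ≈173 nJ), which is what allows ~175 nJ/spike and ~60 µW peaks
to coexist with µA-scale channel currents at sub-volt supplies. The original
bookkeeping behind the printed numbers is not specified; this decomposition
is the package's own, stated definition.

## Analysis layer

* **Spike detection** — upward threshold crossings (default 0.25 V, midway
  between rest and peak) with linear interpolation and an optional
  refractory minimum. Steady rate = 1/mean(ISI) after discarding the first
  20 % of the window.
* **Excitability classes** — class 3 if all spikes of a long strong step
  fall within the 300 ms onset window (≥2 spikes: phasic bursting, else
  phasic spiking); else class 2 if the smallest nonzero f–I rate exceeds
  60 % of the top-of-grid rate (abrupt firing onset); else class 1. The
  onset probe uses the largest grid amplitude because a phasic neuron at low
  drive produces no spikes at all. The f–I grid spans 0.5–6 µA.
* **Spike skipping** — base period = mode of the pooled ISI histogram
  (refined as the modal-cluster mean); each ISI is assigned its nearest
  integer multiple k of the base period (25 % tolerance); skip fraction =
  fraction with k ≥ 2; multimodality = fraction within tolerance of any
  multiple.
* **Feature battery** — each behaviour is decided by an explicit stimulus
  protocol and rule (integration: pulse pair sums at 20 ms but not 500 ms
  gaps; refractoriness: the second suprathreshold pulse fails below ~0.2 s;
  resonance: the pair fires at 50–80 ms gaps only; threshold variability: a
  preceding hyperpolarising pulse enables an otherwise-subthreshold test
  pulse; rebound: a spike within 200 ms of releasing a hyperpolarising
  step; accommodation: a step spikes where the equal-endpoint slow ramp does
  not; latency: first-spike delay decreasing in amplitude). The resonator
  behaviours (resonance, rebound, threshold variability) run at the class-2
  operating point (E_K = −65 mV, 2 µA holding current), where the
  subthreshold state is an underdamped focus with ~9 Hz ringing — the
  package's analogue of a per-behaviour settings table, overridable per
  feature.
* **Hodgkin–Huxley oracle** — the canonical 1952 squid-axon model (modern
  convention, rest ≈ −65 mV) produces traces in the same container, so the
  same battery validates the detectors on tonic spiking, latency and
  refractoriness with no circuit calibration in the loop.

## Numerical choices

Adaptive LSODA (rtol 1e−7, atol 1e−10) is the default integrator; the
integration is split at every stimulus-segment boundary so the solver cannot
step over a short pulse while coasting at equilibrium. Noisy inputs use
fixed-step RK4 (classic, bit-reproducible; ensemble runs are vectorised
across noise seeds) with the Ornstein–Uhlenbeck input generated by its exact
discretisation on a fixed 0.1 ms grid and linearly interpolated, so the
realised path is independent of the solver. Output sampling is 50 µs for the
slow neuron and 5 µs for the fast ones (resolving the spike edges that the
power integral needs). Halving the tolerances moves spike times by well
under 0.1 % of the period. The resting state is found by a damped Newton
solve from V_mem = E_L (with fallback starts) and verified linearly stable
via the 2×2 Jacobian.

## Known limitations and honest caveats

* The slow neuron at 2 µA is *bistable*: a stable subthreshold balance
  point (the K branch absorbing the input below the Na zone) coexists with
  the tonic cycle. Deterministically, a neuron silenced into that state
  (e.g. by GABA) does not re-ignite on washout without a perturbation;
  reversibility therefore means exact recovery of the device parameters and
  of from-rest excitability. For the same reason noise-induced spike
  skipping is demonstrated at the fast neuron's class-2 point (E_K =
  −16 mV), where escape and knock-out rates are comparable and the base
  frequency stays within ±10 % while the skip fraction grows with noise.
* The spike peak of the slow neuron computes to 0.35 V against the nominal
  ~0.34 V; the shape tests carry a ±0.04 V band.
* Frequency monotonicity in (C_mem, R_dk) is checked at 4 µA: at 2 µA some
  scaled-up grid corners fall below rheobase and the comparison is void.
* Fabrication, electrochemistry, temperature, electrode impedances and any
  in-vivo coupling are out of scope; concentrations are static per segment;
  the amplifier is a saturating linear map, not a transistor-level model.
* Simulated durations (2–5 s per run, ensembles of 7 seeds per noise level)
  are chosen to give ≥10 interspike intervals per estimate at each
  operating point.
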