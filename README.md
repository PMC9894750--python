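# coecn

A circuit-level simulator for **conductance-based organic electrochemical
neurons** (c-OECNs): spiking circuits built from two organic
electrochemical transistors (OECTs) in which an *antiambipolar* device — one
whose drain current rises and then falls with gate voltage, tracing a
Gaussian-shaped transfer curve — emulates the activation/inactivation of the
neuronal sodium channel, and a monotone OECT behind an RC delay emulates the
delayed potassium channel. The package is for researchers in neuromorphic
bioelectronics who want to explore these circuits at the desk: device laws,
ion/neurotransmitter modulation of the transfer curves, stiff ODE
integration of the two-node circuit, and an analysis layer that detects
spikes and classifies the standard battery of neurocomputational features.

The circuit model is

```
(C_mem + C_int) dV_mem/dt = I_in(t) + I_Na − I_K − G_L (V_mem − E_L)
R_dk · C_gK     dV_gk/dt  = V_mem − V_gk

I_Na = I_peak(V_DS) · exp(−(V_G − V_P(V_DS))²/2σ²),   V_G = amp(V_mem),  V_DS = E_Na − V_mem
I_K  = K_g·((V_GS − V_K)·V_DS − V_DS²/2 | saturation),  V_GS = V_gk − E_K,  V_DS = V_mem − E_K
```

where `amp` is an inverting amplifier that sweeps the Na-OECT gate from
~1.2 V at rest down through the transfer-curve peak V_P as the membrane
depolarises. Rising membrane voltage first recruits the sodium current
(regenerative), then quenches it (inactivation); the delayed potassium
current repolarises and transiently hyperpolarises the node. Electrolyte
composition enters as parameter shifts: ions move V_P Nernstianly,
neurotransmitters/amino acids (GABA, glutamine, dopamine) shift V_P and
attenuate the peak current, Ca²⁺ lowers the K-OECT threshold V_K.

A canonical Hodgkin–Huxley squid-axon model is included as an independent
oracle for the analysis layer, and the shipped reference configurations
reproduce the headline operating points of the reference circuit: 5 Hz / 80
Hz / 100 Hz tonic spiking, 175 mV rest, ~0.34 V peak, ~175 nJ per spike at
~60 µW, the E_K- and Ca²⁺-driven excitability-class sequence
(class 1 → class 2 → phasic bursting → phasic spiking), noise-induced spike
skipping at a preserved base frequency, and event-based NaCl / glutamine
sensing windows.

## Worked example

```python
from coecn import configs, circuit, features, stimuli

p = configs.config_a()                      # the ~5 Hz reference neuron
solver = configs.default_solver("config-a")
trace = circuit.simulate(p, stimuli.constant(2e-6), 5.0, solver=solver)

train = features.detect_spikes(trace)       # threshold 0.25 V
print(f"rate    {features.steady_rate(train, 5.0):.2f} Hz")
print(f"rest    {circuit.resting_state(p).V_mem*1e3:.1f} mV")
print(f"peak    {trace.V_mem.max()*1e3:.0f} mV")
print(f"trough  {trace.V_mem.min()*1e3:.0f} mV")
```

prints

```
rate    5.00 Hz
rest    175.0 mV
peak    351 mV
trough  37 mV
```

— a 2 µA input drives tonic spiking at 5.00 Hz from a 175 mV rest, each
action potential peaking near 0.35 V and undershooting the resting value
(hyperpolarisation) before the next cycle. Sweeping the potassium battery
walks the neuron through the excitability classes:

```python
from coecn.experiments import run_class_switch_scan
run_class_switch_scan(p, [-0.050, -0.065, -0.070, -0.072], solver=solver)
# ['class1', 'class2', 'class3_phasic_bursting', 'class3_phasic_spiking']
```

The same sequence appears when Ca²⁺ is added to the K-OECT electrolyte
instead (`run_ca_modulation`), and `coecn.features.feature_battery` scores
the full pulse-protocol battery (latency, integration, refractoriness,
resonance, threshold variability, rebound, accommodation) on any
configuration.

A command-line interface mirrors the library:

```
coecn simulate --preset config-a --out run/       # trace CSV + manifest
coecn battery  --preset config-a --out run/       # feature report JSON
coecn class-scan --preset config-a --out run/
coecn conc-scan --preset sensing-nacl --analyte NaCl --grid-mm 12.5,25,50,100
coecn hh --out run/                               # Hodgkin–Huxley oracle
```

Every run writes a `manifest.json` (configuration digest, solver settings,
seed) sufficient to reproduce it bit-identically.

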