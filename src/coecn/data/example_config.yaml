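# Example experiment configuration: the ~5 Hz reference neuron driven by a
# constant 2 uA input.  Any omitted block falls back to the named base
# configuration.  All keys carry unit suffixes.
base: config-a
circuit:
  E_K_V: -0.050
stimulus:
  baseline_A: 2.0e-6
simulation:
  t_end_s: 5.0
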