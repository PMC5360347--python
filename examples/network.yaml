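# Three-neuron master-slave loop: the validation configuration.
# Neuron 1 (master, 60 ms) excites neuron 2 (slave, 70 ms) via g12;
# neuron 2 excites the interneuron 3 (80 ms) via g23; neuron 3 feeds
# inhibition back onto neuron 2 via g32.
periods:
  P1i: 60
  P2i: 70
  P3i: 80
synapses:
  g12: 0.015
  g23: 0.0275
  g32: 0.002
run:
  seed: 1
  n_phases: 50
  cycles: 100
  discard: 20
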