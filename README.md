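# prcnet

Phase-response-curve (PRC) prediction of phase-locked firing patterns in a
three-neuron master–slave network with an inhibitory feedback loop.

Neural oscillators in real circuits receive **several** synaptic inputs per
cycle, while the classical PRC formalism describes the resetting caused by a
single input. `prcnet` implements the generalized, multi-input phase
resetting: the composed resetting of *n* stimuli per cycle is obtained by
applying the ordinary single-stimulus PRC recursively on successively
modified periods,

```
P0 = Pi,    Pk = P(k-1) · (1 + F(tsk / P(k-1))),    F(n) = Pn/Pi − 1,
```

and uses it to predict — from **open-loop** measurements only — the
existence and the stability of the locked firing pattern of a small
recurrent circuit, which is then checked against direct **closed-loop**
simulation.

The circuit is the classic master–slave loop: a pacemaker neuron 1
(intrinsic period `P1i = 60 ms`) excites the slave neuron 2 (`P2i = 70 ms`,
conductance `g12`), the slave excites an interneuron 3 (`P3i = 80 ms`,
`g23`), and the interneuron feeds inhibition back onto the slave (`g32`).
Within each locked cycle the slave is inhibited at `t2sa` after its spike,
excited at `t2sb`, and recovers for `t2r`. Steady state requires

```
P2i · (1 + F2⁽²⁾(t2sa*, t2sb*)) = P1i            (slave, two inputs)
P3i · (1 + F3( (P1i − t2sa*)/P3i )) = P1i        (interneuron, one input)
```

which the package solves with numerically measured PRC tables (cubic-spline
interpolated) or with the SNIC normal form `F(φ) = c·(1 − cos 2πφ)`. The
stability of a solution follows from the 2×2 linearization of the
cycle-to-cycle timing map, built from the PRC slopes at the steady phases;
the mode is stable iff both eigenvalues lie inside the unit circle.

Neurons are dimensionless type-1 Morris–Lecar oscillators (class I
excitability, SNIC onset); synapses are first-order kinetic conductances.
All model and coupling parameters are explicit configuration values — the
package needs no external data.

## Worked example

```python
from prcnet import NetworkSpec, calibrate_network, run_validation

result = run_validation(seed=1)           # full pipeline, ~2 min on 1 CPU
m = result.measurement.steady             # closed loop
p = result.predicted                      # open-loop fixed point
print(f"closed loop : t2sa={m['t2sa']:.2f}  t2sb={m['t2sb']:.2f} "
      f"period={m['period']:.2f}")
print(f"open loop   : t2sa*={p.t2sa:.2f}  t2sb*={p.t2sb:.2f}")
print("eigenvalues :", [f"{abs(e):.3f}" for e in result.stability.eigenvalues],
      result.stability.verdict)
print(f"c(g12) slope: {result.coupling_sweep['slope']:.3f}")
```

prints

```
closed loop : t2sa=15.17  t2sb=40.21 period=60.00
open loop   : t2sa*=15.26  t2sb*=40.08
eigenvalues : ['0.328', '0.682'] stable
c(g12) slope: -6.028
```

Reading: after bias-current calibration to 60/70/80 ms, the fully coupled
network (`g12 = 0.015`, `g32 = 0.002`, `g23 = 0.0275`) entrains to the
master's 60 ms period with the interneuron firing 15.17 ms and the master
40.21 ms after each slave spike. The open-loop prediction — built only from
three single-stimulus PRCs measured on isolated neurons — reproduces those
times to better than 1% and classifies the mode as stable (spectral radius
0.68: perturbations decay by ~1/3 per cycle). The last line is the slope of
the affine map from the master→slave conductance to the fitted normal-form
coefficient, estimated over a weak-coupling sweep.

The same pipeline is scriptable from the shell:

```
prcnet net validate examples/network.yaml -o out/
prcnet prc measure examples/network.yaml --pathway 23 -o prc_23.csv
prcnet lock solve examples/network.yaml
```

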