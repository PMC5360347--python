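# Methods

This note documents the models, measurement protocols, numerical choices
and known limitations behind `prcnet`. Nothing here states a number that
the test suite or `scripts/acceptance.py` does not itself compute.

## Neuron model

Single-compartment Morris–Lecar oscillator in dimensionless form
(voltages normalized by the calcium reversal potential 120 mV,
conductances by 4 mS/cm², currents by 480 µA/cm²):

```
dV/dt = −gCa·m∞(V)·(V−ECa) − gK·w·(V−EK) − gLeak·(V−ELeak) + I0 − i_syn
dw/dt = φ · cosh((V−Vw½)/(2·Vw_slope)) · (w∞(V) − w)
x∞(V) = (1 + tanh((V−Vx½)/Vx_slope)) / 2       for x ∈ {m, w}
```

Default parameters are the type-1 (class I) set: `gCa=1.33, gK=2.0,
gLeak=0.5, ECa=1.0, EK=−0.7, ELeak=−0.5, Vm½=−0.01, Vm_slope=0.15,
Vw½=0.1, Vw_slope=0.145, φ=0.6, I0=0.070`. Two typographic conventions
had to be fixed:

* the potassium time constant is the **reciprocal** of the cosh
  (`τ(V) = 1/cosh(·)`), the standard ML form — an arccosh reading is
  undefined for arguments below 1 and yields no oscillator;
* the transmitter sigmoid of the synapse (below) is **rising** in the
  presynaptic potential, `T(Vpre) = 1/(1 + exp(−(Vpre − 0.2)·24))`,
  half-activated at 0.2 (24 mV): the only reading under which
  presynaptic depolarization releases transmitter.

One model time unit is identified with 1 ms, so the intrinsic periods
60/70/80 of the study configuration are literal simulation durations.

Near its SNIC bifurcation this cell is class I: the firing period
diverges as `I0` approaches rheobase (≈0.0695) from above and decreases
monotonically with `I0`, until a depolarization-block fixed point takes
over (≈0.078). All bias currents used here live inside that oscillatory
window; they are obtained by **calibration** (bracketed root search on
the period-vs-I0 curve, default bracket (0.0694, 0.0745), tolerance
0.05 ms), never hard-coded, because the period at a printed `I0` depends
on integration details at the fourth decimal.

## Synapse model

First-order kinetics, one state per connection:
`s' = α·T(Vpre)·(1−s) − β·s` with `α=15`, `β=1.5` (ms⁻¹), postsynaptic
current `gsyn·s·(Vpost − Esyn)`, `Esyn = 0` (excitatory) or `−0.6`
(inhibitory). `T` is effectively a spike detector: at the voltage floor
of the cycle it is ~10⁻⁶, during the spike ~1, so `s` rises only while
the presynaptic cell spikes and decays with time constant 1/β ≈ 0.67 ms.

## Integration and spike detection

`scipy.integrate.solve_ivp` (RK45), `rtol=1e−8`, `atol=1e−10`
(limit-cycle anchoring uses 1e−10/1e−12), solution sampled every 0.02
time units. Spikes are upward zero crossings of V located by linear
interpolation between samples; at these tolerances the crossing times
are reproducible to well under 0.01 ms, which matters because the
headline timing quantities are quoted to 0.1 ms. The phase reference
φ=0 is the crossing itself; no refractory logic is needed for ML at
these parameters. Period measurement discards 5 transient cycles and
averages 10 (cycle-to-cycle spread is asserted below 0.1%).

## PRC measurement (open loop)

The postsynaptic neuron is settled on its limit cycle (8 cycles) and its
state at an upward crossing cached. For each phase φ of a 50-point grid
on [0.02, 0.98] (end points excluded: a stimulus exactly at the spike is
causally ambiguous), a single presynaptic spike is delivered at
`ts = φ·Pi`: the presynaptic voltage template — one full free-running
cycle of the presynaptic neuron, aligned so its own upward crossing sits
at `ts` — drives the synapse ODE; outside the template the presynaptic
cell is held at its cycle minimum (transmitter release negligible). The
perturbed cycle length P1 is the time from the reference crossing to the
next spike, and `F(φ) = P1/Pi − 1` (negative = advance). An error is
raised if no spike occurs within 3·Pi ("stimulus suppressed firing").
Only the first-order (same-cycle) resetting is tabulated.

Tables are interpolated with a natural cubic spline; evaluation and
differentiation outside the measured grid are refused rather than
extrapolated. A triangular current-pulse stimulus is available as an
alternative shape (amplitude and duration must be given explicitly); the
synaptic-event protocol is the default, since the synapse model defines
exactly what an input *is* in the closed loop.

## Normal form and the c(g) calibration

Type-1 PRCs near the SNIC are fit by `F(φ) = c·(1 − cos 2πφ)` with the
period held fixed, leaving a single linear coefficient with a
closed-form least-squares solution. **Convention:** `c` is the signed
half-amplitude of the resetting itself (`F_min = 2c` for excitatory
input), not a frequency-scaled coefficient. This is the only convention
under which the three quantities the formalism connects — the fitted
c(g) maps, the closed-form root condition
`cos(2π·(P1i−t2sa*)/P3i) = 1 − (P1i/P3i − 1)/c23`, and the
minimum-coupling bound `|c23| ≥ (1 − P1i/P3i)/2` — are mutually
consistent with resettings bounded below by −1.

The calibration `c(g)` is fit by OLS over a sweep of measured PRCs. The
default sweep is five conductances in [0.002, 0.012] — the
weak-coupling regime, bracketing the inhibitory coupling of the study
network and staying below its excitatory one — because the linear
response saturates visibly beyond g ≈ 0.015: a strong excitatory input
fires the cell almost immediately over a widening range of phases, the
PRC flattens against its causal floor `F ≥ φ − 1`, and the fitted |c|
grows sublinearly. A secant fit across the saturated range (e.g.
0.005–0.05) underestimates the weak-coupling slope by ~30%; the sweep
range is therefore part of the calibration's definition and is reported
with it.

## Fixed points, branch choice, stability

Roots of the scalar residuals are found by scanning a 2000-point grid
and bisecting every sign change (`brentq`, |residual| < 1e−10); grids
rather than derivative methods because tabulated PRCs are splines. Both
residuals of every returned mode are re-verified to 1e−8. `t2r* = P1i −
t2sb*` holds by construction and is exposed, not solved for.

Several (t2sa*, t2sb*) candidates generally coexist (the unimodal PRC
crosses any reachable level twice). The **primary** mode is the first
stable one in (t2sa, t2sb) order — stability is what makes a mode
observable; in the study configuration exactly one candidate is stable.

The stability matrix is

```
A = [[(1−m3)(1−b), (m3−1)·m2b], [−b, 1−m2b]],
b = m2a·(1 + F2exc(φ2b*) − m2b·φ2b*)
```

with slopes m2a (inhibitory PRC at φ2a* = t2sa*/P2i), m2b (excitatory
PRC at φ2b* = t2sb*/(P2i·α)), m3 (interneuron PRC at φ3* = ts3*/P3i).
This form was re-derived here as the exact Jacobian of the nonlinear
cycle-to-cycle timing map, which the package also exposes
(`timing_map_step`); the test suite checks the analytic matrix against a
central-difference Jacobian of that map. (In the course of the
derivation an inconsistent intermediate form of `b` — missing the factor
m2b on φ2b* — was identified as typographic and discarded.) Verdicts:
stable iff the spectral radius is < 1, with a ±1e−6 band reported as
"marginal"; the trace/determinant classification (P(±1) > 0 for real
roots, Det < 1 for complex) is cross-checked against brute-force
iteration of the map on random matrices.

## Closed-loop simulation

The 9-state system (three neurons, three synapse states) is integrated
for 125 master periods; each neuron starts at a seeded random phase of
its own limit cycle, synapses at zero. After discarding 20 slave cycles,
each cycle must contain exactly one interneuron spike followed by one
master spike (ties at a boundary, within 1e−6, go to the later cycle);
any other pattern raises an explicit mismatch error rather than
mis-assigning spikes. Convergence of each timing sequence means a
trailing-10-cycle spread ≤ 0.05 ms; the steady value is the trailing
mean. The per-cycle bookkeeping identity `P1 = t2r[n−1] + t2sb[n]` is
asserted on every steady cycle. With the stable mode's spectral radius
≈ 0.68, 20 discard cycles leave transients below 10⁻³ ms.

## What the validation shows — and a known discrepancy

With everything above, the open-loop prediction matches the closed loop
to better than 1% (t2sa* 15.26 vs 15.17 ms; t2sb* 40.08 vs 40.21 ms):
the first-order, instantaneous-resetting approximation is essentially
exact for this circuit at these couplings. Previously reported values
for this circuit quote a *larger* prediction error (~18% on t2sa*, with
correspondingly different predicted times 18.0/44.1 ms and eigenvalues
0.489/0.779); they derive from open-loop PRCs generated with a
triangularly shaped stimulus whose amplitude and duration were not
specified, and no triangular parameterization we scanned reproduces PRC
tables consistent with those numbers (a pulse strong enough to match the
implied amplitude drives immediate firing, which skews the PRC
differently).
The package therefore reports what its own — fully specified — protocol
computes. The closed-loop quantities and the weak-coupling calibration
slope are protocol-independent and agree with the reference values.

## Synthetic fixtures

The fixture generator produces (i) perfectly periodic spike trains with
prescribed offsets — the extraction oracle: offsets are recovered
exactly; (ii) normal-form PRC tables with optional Gaussian noise of
stated σ (σ=0 by default; fits recover c to machine precision); (iii)
uniform random 2×2 matrices on [−2, 2] for the classification oracle.
These emulate the *shape* of real measurements, not their noise
structure: real PRC estimates carry correlated measurement error and
real spike trains jitter, so passing fixture tests demonstrates
correctness of the bookkeeping and algebra, not robustness to noise
(which the ODE-level tests cover only for deterministic dynamics).

## Problem sizes and runtime

Defaults used by the validation pipeline (and its tests): 50-phase PRC
grids for prediction, 25-phase grids for the five-point calibration
sweep, 125 simulated master cycles, three calibration root searches.
One full validation takes about two minutes on a single CPU; the
dominant costs are the three calibrations and the ~11 PRC tables
(each table = one short perturbation run per phase).

## Known limitations

* Only first-order resetting is modeled; stimuli whose effects straddle
  a spike (phases very near 0 or 1) are excluded by the grid.
* Only the 1:1:1 firing order (interneuron, then master, within each
  slave cycle) is extracted and predicted; other n:m patterns raise
  pattern-mismatch errors by design.
* Single-compartment deterministic neurons, instantaneous chemical
  synapses, no conduction delays, no noise, no plasticity.
* The c(g) calibration is meaningful only in its stated weak-coupling
  range (see above).
* `mode_surface` uses normal-form PRCs through the c(g) maps; its
  absolute times inherit the normal form's skew error relative to
  measured tables (a few ms in the study configuration).
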