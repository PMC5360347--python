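"""End-to-end validation: open-loop prediction vs closed-loop simulation.

The pipeline reproduces the study's validation protocol from scratch:

1. calibrate the three bias currents to intrinsic periods 60/70/80;
2. simulate the fully coupled network (g12 = 0.015, g32 = 0.002,
   g23 = 0.0275) from random initial phases and extract the converged
   timing variables (t2sa, t2sb, network period);
3. measure the three open-loop single-stimulus PRCs, solve the
   fixed-point equations for the predicted mode, and evaluate the
   return-map eigenvalues at it;
4. sweep the master-to-slave conductance in the weak-coupling regime and
   regress the fitted normal-form coefficient on g (the c(g) calibration
   slope).

Every quantity is computed at run time; the seed only enters through the
closed-loop initial phases (the converged mode is checked to be
seed-independent in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import NetworkSpec, calibrate_network
from .locking import NetworkConfig, PhaseLockedMode, solve_modes
from .model import limit_cycle
from .network import (
    ModeMeasurement,
    PatternMismatchError,
    compare_prediction,
    extract_mode,
    simulate_network,
)
from .prc import (
    PRCTable,
    calibrate_coupling_map,
    default_phase_grid,
    fit_normal_form,
    measure_prc,
)
from .stability import StabilityResult, stability_of_mode

__all__ = ["ValidationResult", "run_validation", "measure_network_prcs"]

#: Weak-coupling sweep for the c(g12) calibration: the affine relation
#: between the normal-form coefficient and the conductance holds below
#: ~0.015; stronger coupling saturates (the PRC is floored at phi - 1).
DEFAULT_SWEEP_G12 = (0.002, 0.0045, 0.007, 0.0095, 0.012)


@dataclass
class ValidationResult:
    network: NetworkConfig
    measurement: ModeMeasurement
    prcs: dict
    modes: list
    predicted: PhaseLockedMode | None
    stability: StabilityResult | None
    coupling_sweep: dict
    comparison: dict
    targets: dict = field(default_factory=dict)
    seed: int = 0


def measure_network_prcs(
    net: NetworkConfig,
    phases: Sequence[float] | None = None,
    *,
    cycles: dict | None = None,
) -> dict:
    """The three open-loop PRCs of the locked pattern.

    Returns ``{"F2_inh": ..., "F2_exc": ..., "F3": ...}``: the slave's
    response to the interneuron's inhibition (g32) and to the master's
    excitation (g12), and the interneuron's response to the slave's
    excitation (g23).  Pass pre-settled limit cycles in ``cycles``
    (keys 1, 2, 3) to avoid re-settling.
    """
    cyc = dict(cycles or {})
    for idx, params, hint in (
        (1, net.neuron1, net.P1i),
        (2, net.neuron2, net.P2i),
        (3, net.neuron3, net.P3i),
    ):
        if idx not in cyc:
            cyc[idx] = limit_cycle(params, period_hint=hint)
    common = dict(phases=phases)
    return {
        "F2_inh": measure_prc(
            net.neuron2, net.syn32, net.neuron3,
            post_cycle=cyc[2], pre_cycle=cyc[3],
            meta={"pathway": "32"}, **common,
        ),
        "F2_exc": measure_prc(
            net.neuron2, net.syn12, net.neuron1,
            post_cycle=cyc[2], pre_cycle=cyc[1],
            meta={"pathway": "12"}, **common,
        ),
        "F3": measure_prc(
            net.neuron3, net.syn23, net.neuron2,
            post_cycle=cyc[3], pre_cycle=cyc[2],
            meta={"pathway": "23"}, **common,
        ),
    }


def _closed_loop(net, lcs, seed, cycles, discard, max_attempts=3):
    duration = (discard + cycles + 5) * net.P1i
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        sub = (seed + 7919 * attempt) % (2**31)
        rng = np.random.default_rng(sub)
        y0 = np.concatenate(
            [lcs[i].state_at_phase(rng.uniform()) for i in (1, 2, 3)]
            + [np.zeros(3)]
        )
        trains, _ = simulate_network(net, duration, initial_state=y0)
        try:
            mm = extract_mode(trains, discard=discard)
        except PatternMismatchError as err:
            last_err = err
            continue
        if mm.converged:
            return mm, trains
        last_err = RuntimeError("closed-loop timing did not converge")
    raise RuntimeError(
        f"no converged locked mode from {max_attempts} initial-phase draws"
    ) from last_err


def run_validation(
    seed: int = 0,
    *,
    spec: NetworkSpec | None = None,
    network: NetworkConfig | None = None,
    n_phases: int = 50,
    cycles: int = 100,
    discard: int = 20,
    sweep_g12: Sequence[float] = DEFAULT_SWEEP_G12,
    sweep_phases: int = 25,
) -> ValidationResult:
    """Run the full open-loop vs closed-loop validation.

    ``n_phases`` is the PRC grid for the prediction, ``sweep_phases`` the
    (coarser) grid used per point of the c(g12) calibration sweep.
    Pass a pre-calibrated ``network`` to skip the bias-current search.
    """
    spec = spec or NetworkSpec()
    net = network if network is not None else calibrate_network(spec)
    lcs = {
        1: limit_cycle(net.neuron1, period_hint=net.P1i),
        2: limit_cycle(net.neuron2, period_hint=net.P2i),
        3: limit_cycle(net.neuron3, period_hint=net.P3i),
    }

    # --- closed loop ----------------------------------------------------
    measurement, _trains = _closed_loop(net, lcs, seed, cycles, discard)

    # --- open loop: PRCs, fixed point, stability ------------------------
    prcs = measure_network_prcs(net, default_phase_grid(n_phases), cycles=lcs)
    modes = solve_modes(
        prcs["F2_inh"], prcs["F2_exc"], prcs["F3"],
        net.P1i, net.P2i, net.P3i,
    )
    predicted, stab = None, None
    for mode in modes:
        res = stability_of_mode(
            mode, prcs["F2_inh"], prcs["F2_exc"], prcs["F3"], net.P2i, net.P3i
        )
        if res.verdict == "stable":
            predicted, stab = mode, res
            break
    if predicted is None and modes:
        predicted = modes[0]
        stab = stability_of_mode(
            predicted, prcs["F2_inh"], prcs["F2_exc"], prcs["F3"],
            net.P2i, net.P3i,
        )

    comparison = (
        compare_prediction(measurement, predicted) if predicted else {}
    )

    # --- c(g12) calibration sweep ---------------------------------------
    grid = default_phase_grid(sweep_phases)
    cs = []
    for g in sweep_g12:
        syn = type(net.syn12)(gsyn=g, Esyn=net.syn12.Esyn)
        table = measure_prc(
            net.neuron2, syn, net.neuron1, grid,
            post_cycle=lcs[2], pre_cycle=lcs[1], meta={"pathway": "12"},
        )
        cs.append(fit_normal_form(table).c)
    cal = calibrate_coupling_map(sweep_g12, cs, label="c12(g12)")
    sweep = {"g": list(sweep_g12), "c": cs, "slope": cal.slope,
             "intercept": cal.intercept}

    # --- targets --------------------------------------------------------
    n_cycles = len(measurement.period)
    targets = {
        "t1": {"value": measurement.steady["t2sa"], "n": n_cycles},
        "t2": {"value": measurement.steady["t2sb"], "n": n_cycles},
        "t7": {"value": measurement.steady["period"], "n": n_cycles},
    }
    if predicted is not None:
        targets["t3"] = {"value": predicted.t2sa, "n": n_phases}
        targets["t4"] = {"value": predicted.t2sb, "n": n_phases}
    if stab is not None:
        moduli = sorted(abs(ev) for ev in stab.eigenvalues)
        targets["t5"] = {"value": moduli[0], "n": n_phases}
        targets["t6"] = {"value": moduli[1], "n": n_phases}
    targets["t9"] = {"value": cal.slope, "n": len(list(sweep_g12))}

    return ValidationResult(
        network=net,
        measurement=measurement,
        prcs=prcs,
        modes=modes,
        predicted=predicted,
        stability=stab,
        coupling_sweep=sweep,
        comparison=comparison,
        targets=targets,
        seed=seed,
    )
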