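"""Closed-loop simulation of the three-neuron network and mode extraction.

The fully connected system is nine-dimensional: (V, w) for each neuron
plus one kinetic synapse state per connection (1->2 excitatory, 3->2
inhibitory, 2->3 excitatory), each driven continuously by its
presynaptic membrane potential.  Spike trains are read off by
interpolated upward zero crossings and the per-cycle timing variables of
the locked pattern are extracted relative to the slave neuron's spikes:
within one slave cycle, the interneuron fires t2sa after the slave's
spike, the master t2sb after it, and the slave recovers for t2r.  The
bookkeeping identity P1 = t2r[n-1] + t2sb[n] ties the three trains to
the master period on every steady cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .locking import NetworkConfig, PhaseLockedMode
from .model import (
    SpikeTrain,
    Trajectory,
    detect_spikes,
    integrate,
    limit_cycle,
    ml_derivatives,
    synapse_derivative,
)

__all__ = [
    "ModeMeasurement",
    "PatternMismatchError",
    "simulate_network",
    "extract_mode",
    "check_convergence",
    "compare_prediction",
]


class PatternMismatchError(RuntimeError):
    """A slave cycle does not contain exactly one interneuron spike
    followed by one master spike."""


@dataclass
class ModeMeasurement:
    """Per-cycle timing sequences and their steady values."""

    t2sa: np.ndarray
    t2sb: np.ndarray
    t2r: np.ndarray
    period: np.ndarray  # slave cycle length per cycle
    converged: bool
    steady: dict = field(default_factory=dict)

    def bookkeeping_residuals(self, P1: float | None = None) -> np.ndarray:
        """Residual of P1 = t2r[n-1] + t2sb[n] on successive cycles.

        With ``P1`` omitted the steady network period is used."""
        if P1 is None:
            P1 = self.steady.get("period", float(np.mean(self.period)))
        return self.t2r[:-1] + self.t2sb[1:] - P1


def _network_rhs(config: NetworkConfig):
    n1, n2, n3 = config.neuron1, config.neuron2, config.neuron3
    s12p, s32p, s23p = config.syn12, config.syn32, config.syn23

    def rhs(t, y):
        V1, w1, V2, w2, V3, w3, s12, s32, s23 = y
        i2 = s12p.gsyn * s12 * (V2 - s12p.Esyn) + s32p.gsyn * s32 * (V2 - s32p.Esyn)
        i3 = s23p.gsyn * s23 * (V3 - s23p.Esyn)
        dV1, dw1 = ml_derivatives((V1, w1), n1)
        dV2, dw2 = ml_derivatives((V2, w2), n2, i2)
        dV3, dw3 = ml_derivatives((V3, w3), n3, i3)
        return (
            dV1, dw1, dV2, dw2, dV3, dw3,
            synapse_derivative(s12, V1, s12p),
            synapse_derivative(s32, V3, s32p),
            synapse_derivative(s23, V2, s23p),
        )

    return rhs


def simulate_network(
    config: NetworkConfig,
    duration: float,
    *,
    initial_phases: Sequence[float] | None = None,
    seed: int | None = None,
    rtol: float = 1e-8,
    sample_dt: float = 0.02,
    initial_state: Sequence[float] | None = None,
    return_trajectory: bool = False,
):
    """Integrate the closed-loop network and return three spike trains.

    Each neuron starts on its free-running limit cycle at
    ``initial_phases`` (fractions of its own period); with ``seed`` the
    phases are drawn uniformly instead.  ``initial_state`` (9-vector)
    overrides both.  Synapse states start at zero.

    Returns ``(trains, trajectory)`` where ``trajectory`` is None unless
    ``return_trajectory`` is set.  Emits a "quiescent neuron" warning via
    the returned trains' lengths (callers check <3 spikes).
    """
    if initial_state is not None:
        y0 = np.asarray(initial_state, dtype=float)
        if y0.shape != (9,):
            raise ValueError("initial_state must have 9 components")
    else:
        if initial_phases is None:
            rng = np.random.default_rng(seed)
            initial_phases = rng.uniform(0.0, 1.0, size=3)
        phases = np.asarray(initial_phases, dtype=float)
        if phases.shape != (3,):
            raise ValueError("one initial phase per neuron is required")
        y0 = np.empty(9)
        for i, (params, hint) in enumerate(
            zip(
                (config.neuron1, config.neuron2, config.neuron3),
                config.periods,
            )
        ):
            lc = limit_cycle(params, period_hint=hint)
            y0[2 * i : 2 * i + 2] = lc.state_at_phase(phases[i])
        y0[6:] = 0.0

    traj = integrate(
        _network_rhs(config), y0, duration, rtol=rtol, sample_dt=sample_dt
    )
    trains = tuple(
        detect_spikes(traj, component=2 * i) for i in range(3)
    )
    return (trains, traj if return_trajectory else None)


def check_convergence(
    sequence: Sequence[float], tol: float = 0.05, window: int = 10
) -> tuple[bool, float]:
    """Steady-state test: max-min over the trailing window within tol.

    Returns ``(converged, trailing_mean)``; the mean is NaN when the
    sequence has not settled.
    """
    seq = np.asarray(sequence, dtype=float)
    if len(seq) < window:
        raise ValueError(f"sequence shorter than the window ({window})")
    tail = seq[-window:]
    if tail.max() - tail.min() <= tol:
        return True, float(tail.mean())
    return False, float("nan")


def extract_mode(
    trains: Sequence[SpikeTrain],
    discard: int = 20,
    *,
    tol: float = 0.05,
    window: int = 10,
    boundary_tol: float = 1e-6,
) -> ModeMeasurement:
    """Per-cycle timing variables from the three spike trains.

    Cycles are the slave neuron's interspike intervals after ``discard``
    initial cycles.  Each retained cycle must contain exactly one
    interneuron spike followed by one master spike (the locked firing
    order); otherwise :class:`PatternMismatchError` is raised.  Spikes
    within ``boundary_tol`` of a cycle boundary are assigned to the later
    cycle.
    """
    st1, st2, st3 = (np.asarray(tr.times, float) for tr in trains)
    if len(st2) < discard + window + 2:
        raise PatternMismatchError(
            f"slave train too short: {len(st2)} spikes for discard={discard}, "
            f"window={window}"
        )
    t2sa, t2sb, t2r, period = [], [], [], []
    for n in range(discard, len(st2) - 1):
        lo, hi = st2[n] + boundary_tol, st2[n + 1] + boundary_tol
        in3 = st3[(st3 >= lo) & (st3 < hi)]
        in1 = st1[(st1 >= lo) & (st1 < hi)]
        if len(in3) != 1 or len(in1) != 1 or not in3[0] < in1[0]:
            raise PatternMismatchError(
                f"cycle at t={st2[n]:.2f}: expected one interneuron spike then "
                f"one master spike, found {len(in3)} and {len(in1)}"
            )
        t2sa.append(in3[0] - st2[n])
        t2sb.append(in1[0] - st2[n])
        t2r.append(st2[n + 1] - in1[0])
        period.append(st2[n + 1] - st2[n])
    t2sa, t2sb = np.array(t2sa), np.array(t2sb)
    t2r, period = np.array(t2r), np.array(period)

    steady: dict = {}
    flags = []
    for name, seq in (
        ("t2sa", t2sa), ("t2sb", t2sb), ("t2r", t2r), ("period", period)
    ):
        ok, value = check_convergence(seq, tol=tol, window=window)
        flags.append(ok)
        steady[name] = value
        steady[name + "_spread"] = float(seq[-window:].max() - seq[-window:].min())
    return ModeMeasurement(
        t2sa=t2sa, t2sb=t2sb, t2r=t2r, period=period,
        converged=all(flags), steady=steady,
    )


def compare_prediction(
    measured: ModeMeasurement, predicted: PhaseLockedMode
) -> dict:
    """Absolute and percent errors of the open-loop prediction.

    Percent error is |pred - meas| / meas * 100.  Refuses unconverged
    measurements.
    """
    if not measured.converged:
        raise ValueError("measurement did not converge; refusing comparison")
    out = {}
    for name, pred in (("t2sa", predicted.t2sa), ("t2sb", predicted.t2sb)):
        meas = measured.steady[name]
        out[name] = {
            "measured": meas,
            "predicted": pred,
            "abs_error": abs(pred - meas),
            "pct_error": abs(pred - meas) / meas * 100.0,
        }
    return out
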