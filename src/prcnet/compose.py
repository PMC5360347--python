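"""Recursive composition of single-stimulus PRCs for multiple inputs.

When several stimuli arrive within one cycle and each resetting takes
effect essentially instantaneously, the net resetting follows by applying
the single-stimulus PRC recursively on successively modified periods:

    P0 = Pi
    Pk = P(k-1) * (1 + F_k(tsk / P(k-1)))        (tsk < P(k-1))

so that Pn = Pi * prod_k (1 + F_k(tsk/P(k-1))) and the composed resetting
is F(n) = Pn/Pi - 1.  For two stimuli this is

    F(2)(tsa, tsb) = (1 + Fa(tsa/Pi)) * (1 + Fb(tsb/Pa)) - 1.

Stimulus *times* (not phases) are the canonical inputs; each stimulus may
act through a different PRC (in the three-neuron network the slave's
first input is the interneuron's inhibition, the second the master's
excitation).  The composition is not commutative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ScheduleError",
    "StimulusSchedule",
    "MultiPRCResult",
    "compose_two",
    "compose_n",
]

PRCLike = Callable[[float], float]


class ScheduleError(ValueError):
    """A stimulus falls outside the transiently modified cycle."""


@dataclass
class StimulusSchedule:
    """Ordered stimulus times within one cycle, one PRC per stimulus."""

    times: Sequence[float]
    prcs: Sequence[PRCLike]

    def __post_init__(self) -> None:
        self.times = list(map(float, self.times))
        self.prcs = list(self.prcs)
        if len(self.times) != len(self.prcs):
            raise ValueError("one PRC per stimulus time is required")
        if len(self.times) == 0:
            raise ValueError("schedule must contain at least one stimulus")
        if any(t < 0 for t in self.times):
            raise ValueError("stimulus times must be non-negative")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ScheduleError("stimulus times must be strictly increasing")


@dataclass
class MultiPRCResult:
    """Composed resetting with the intermediate bookkeeping.

    ``periods`` holds P0=Pi, P1, ..., Pn; ``phases`` the per-stimulus
    phases phi_k = tsk / P(k-1).  ``resetting`` is F(n) = Pn/Pi - 1.
    """

    resetting: float
    periods: list[float] = field(default_factory=list)
    phases: list[float] = field(default_factory=list)

    @property
    def final_period(self) -> float:
        return self.periods[-1]


def compose_n(schedule: StimulusSchedule, Pi: float) -> MultiPRCResult:
    """Compose an arbitrary number of single-stimulus resettings.

    Raises :class:`ScheduleError` naming the offending stimulus when a
    time falls at or beyond the transiently modified period.
    """
    if Pi <= 0:
        raise ValueError("intrinsic period must be positive")
    periods = [float(Pi)]
    phases: list[float] = []
    for k, (ts, F) in enumerate(zip(schedule.times, schedule.prcs), start=1):
        P_prev = periods[-1]
        if ts >= P_prev:
            raise ScheduleError(
                f"stimulus {k} at t={ts:.6g} falls outside the transiently "
                f"modified period P{k - 1}={P_prev:.6g}"
            )
        phi = ts / P_prev
        P_new = P_prev * (1.0 + float(F(phi)))
        if P_new <= 0:
            raise ScheduleError(f"stimulus {k} drove the period non-positive")
        phases.append(phi)
        periods.append(P_new)
    return MultiPRCResult(
        resetting=periods[-1] / Pi - 1.0, periods=periods, phases=phases
    )


def compose_two(
    F_a: PRCLike, F_b: PRCLike, tsa: float, tsb: float, Pi: float
) -> MultiPRCResult:
    """Two-stimulus composition F(2)(tsa, tsb).

    ``F_a`` acts first at ``tsa``, ``F_b`` second at ``tsb`` (both
    measured from the reference spike; 0 <= tsa < tsb).  Raises
    :class:`ScheduleError` if the second stimulus misses the modified
    cycle (tsb >= Pa).
    """
    if tsa < 0 or tsb <= tsa:
        raise ValueError("stimulus times must satisfy 0 <= tsa < tsb")
    try:
        return compose_n(StimulusSchedule(times=[tsa, tsb], prcs=[F_a, F_b]), Pi)
    except ScheduleError as err:
        if "stimulus 2" in str(err):
            raise ScheduleError("second stimulus outside modified cycle") from err
        raise
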