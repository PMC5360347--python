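"""Morris-Lecar neuron, kinetic synapse, ODE driver and spike detection.

The single-compartment Morris-Lecar (ML) oscillator in its dimensionless
type-1 parameterization: membrane potential ``V`` obeys

    dV/dt = -gCa*m_inf(V)*(V-ECa) - gK*w*(V-EK) - gLeak*(V-ELeak) + I0 - i_syn

with instantaneous calcium activation ``m_inf`` and a delayed potassium
gate ``w`` relaxing toward ``w_inf(V)`` at rate ``phi*cosh((V-Vw_half)/
(2*Vw_slope))`` (the reciprocal-cosh time constant of the standard ML
model).  Voltages are normalized by the calcium reversal potential,
conductances by 4 mS/cm^2; one model time unit is identified with 1 ms.

Chemical synapses are first-order kinetic: the open-channel fraction ``s``
obeys ``s' = alpha*T(Vpre)*(1-s) - beta*s`` with a steep transmitter
sigmoid ``T`` of the presynaptic potential, and the postsynaptic current
is ``gsyn*s*(Vpost - Esyn)``.

Spikes are upward zero crossings of ``V``, located by linear interpolation
between trajectory samples; they define the phase reference phi = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import cosh, exp, tanh
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "MLNeuronParams",
    "SynapseParams",
    "NeuronState",
    "SynapseState",
    "SpikeTrain",
    "Trajectory",
    "LimitCycle",
    "PeriodEstimate",
    "NotOscillatingError",
    "IntegrationError",
    "CalibrationError",
    "ml_derivatives",
    "transmitter",
    "synapse_derivative",
    "integrate",
    "detect_spikes",
    "intrinsic_period",
    "calibrate_bias",
    "limit_cycle",
]

#: Reversal potentials of chemical synapses (dimensionless).
ESYN_EXCITATORY = 0.0
ESYN_INHIBITORY = -0.6


class NotOscillatingError(RuntimeError):
    """The neuron did not produce the required number of spikes."""


class IntegrationError(RuntimeError):
    """The ODE solution became non-finite or the solver failed."""


class CalibrationError(ValueError):
    """The bias-current bracket cannot reach the requested period."""


@dataclass(frozen=True)
class MLNeuronParams:
    """Dimensionless Morris-Lecar parameters (type-1 set by default)."""

    gCa: float = 1.33
    gK: float = 2.0
    gLeak: float = 0.5
    ECa: float = 1.0
    EK: float = -0.7
    ELeak: float = -0.5
    Vm_half: float = -0.01
    Vm_slope: float = 0.15
    Vw_half: float = 0.1
    Vw_slope: float = 0.145
    phi: float = 0.6
    I0: float = 0.070

    def __post_init__(self) -> None:
        if min(self.gCa, self.gK, self.gLeak) <= 0:
            raise ValueError("maximal conductances must be positive")
        if self.phi <= 0:
            raise ValueError("temperature factor phi must be positive")
        if self.Vm_slope == 0 or self.Vw_slope == 0:
            raise ValueError("gating slopes must be nonzero")

    def with_bias(self, I0: float) -> "MLNeuronParams":
        return replace(self, I0=I0)


@dataclass(frozen=True)
class SynapseParams:
    """First-order kinetic synapse.

    ``T_scale`` is the steepness of the transmitter sigmoid (24 = 120/5 in
    the normalized units); ``T_half`` its half-activation potential.
    """

    gsyn: float
    Esyn: float = ESYN_EXCITATORY
    alpha_on: float = 15.0
    beta_off: float = 1.5
    T_half: float = 0.2
    T_scale: float = 24.0

    def __post_init__(self) -> None:
        if self.gsyn < 0:
            raise ValueError("gsyn must be non-negative")
        if self.alpha_on <= 0 or self.beta_off <= 0:
            raise ValueError("kinetic rates must be positive")


@dataclass
class NeuronState:
    V: float
    w: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("gating variable w must lie in [0, 1]")


@dataclass
class SynapseState:
    s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("channel fraction s must lie in [0, 1]")


@dataclass
class SpikeTrain:
    """Ordered spike times of one neuron, in model time units."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def intervals(self) -> np.ndarray:
        return np.diff(self.times)


def m_inf(V: float, p: MLNeuronParams) -> float:
    """Instantaneous calcium activation."""
    return 0.5 * (1.0 + tanh((V - p.Vm_half) / p.Vm_slope))


def w_inf(V: float, p: MLNeuronParams) -> float:
    """Steady-state potassium activation."""
    return 0.5 * (1.0 + tanh((V - p.Vw_half) / p.Vw_slope))


def w_rate(V: float, p: MLNeuronParams) -> float:
    """Relaxation rate phi/tau(V) of the potassium gate."""
    return p.phi * cosh((V - p.Vw_half) / (2.0 * p.Vw_slope))


def ml_derivatives(
    state: NeuronState | tuple[float, float],
    params: MLNeuronParams,
    i_syn: float = 0.0,
) -> tuple[float, float]:
    """Time derivatives (dV/dt, dw/dt) of one ML neuron.

    ``i_syn`` is an outward synaptic current, subtracted from dV/dt.
    """
    if isinstance(state, NeuronState):
        V, w = state.V, state.w
    else:
        V, w = state
    p = params
    dV = (
        -p.gCa * m_inf(V, p) * (V - p.ECa)
        - p.gK * w * (V - p.EK)
        - p.gLeak * (V - p.ELeak)
        + p.I0
        - i_syn
    )
    dw = w_rate(V, p) * (w_inf(V, p) - w)
    return dV, dw


def transmitter(v_pre: float, params: SynapseParams) -> float:
    """Transmitter concentration T(Vpre): a rising sigmoid in [0, 1]."""
    x = params.T_scale * (v_pre - params.T_half)
    if x < -50.0:
        return 0.0
    if x > 50.0:
        return 1.0
    return 1.0 / (1.0 + exp(-x))


def synapse_derivative(
    s: SynapseState | float, v_pre: float, params: SynapseParams
) -> float:
    """ds/dt of the kinetic synapse driven by the presynaptic potential."""
    sv = s.s if isinstance(s, SynapseState) else s
    T = transmitter(v_pre, params)
    return params.alpha_on * T * (1.0 - sv) - params.beta_off * sv


@dataclass
class Trajectory:
    """Time-stamped solution samples; ``y`` has shape (n_states, n_times)."""

    t: np.ndarray
    y: np.ndarray

    def state_at(self, time: float) -> np.ndarray:
        """Linearly interpolated state vector at ``time``."""
        if not self.t[0] <= time <= self.t[-1]:
            raise ValueError("time outside trajectory range")
        i = int(np.searchsorted(self.t, time))
        if i == 0:
            return self.y[:, 0].copy()
        f = (time - self.t[i - 1]) / (self.t[i] - self.t[i - 1])
        return self.y[:, i - 1] * (1.0 - f) + self.y[:, i] * f


def integrate(
    system: Callable[[float, np.ndarray], Sequence[float]],
    initial: Sequence[float],
    duration: float,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_dt: float = 0.02,
    max_step: float = np.inf,
    method: str = "RK45",
) -> Trajectory:
    """Integrate ``dy/dt = system(t, y)`` over [0, duration].

    The solution is sampled every ``sample_dt`` time units (dense enough
    for interpolated spike detection).  Raises :class:`IntegrationError`
    with the failure time if the state becomes non-finite.
    """
    y0 = np.asarray(initial, dtype=float)
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0:
        return Trajectory(t=np.array([0.0]), y=y0[:, None].copy())
    t_eval = np.arange(0.0, duration + 0.5 * sample_dt, sample_dt)
    t_eval = t_eval[t_eval <= duration]
    if t_eval[-1] < duration:
        t_eval = np.append(t_eval, duration)
    sol = solve_ivp(
        system,
        (0.0, duration),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        max_step=max_step,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed at t={sol.t[-1]:.6g}: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.argmax(~np.all(np.isfinite(sol.y), axis=0))
        raise IntegrationError(f"non-finite state at t={sol.t[bad]:.6g}")
    return Trajectory(t=sol.t, y=sol.y)


def detect_spikes(
    trajectory: Trajectory | tuple[np.ndarray, np.ndarray],
    threshold: float = 0.0,
    component: int = 0,
) -> SpikeTrain:
    """Upward threshold crossings of ``V``, linearly interpolated.

    A crossing is a sample pair with ``V[i] < threshold <= V[i+1]``.
    Returns an empty train when there is no crossing.
    """
    if isinstance(trajectory, Trajectory):
        t, V = trajectory.t, trajectory.y[component]
    else:
        t, V = trajectory
        t = np.asarray(t, float)
        V = np.asarray(V, float)
    idx = np.nonzero((V[:-1] < threshold) & (V[1:] >= threshold))[0]
    if len(idx) == 0:
        return SpikeTrain(times=np.empty(0))
    frac = (threshold - V[idx]) / (V[idx + 1] - V[idx])
    return SpikeTrain(times=t[idx] + frac * (t[idx + 1] - t[idx]))


@dataclass
class PeriodEstimate:
    period: float
    spread: float
    n_cycles: int


def _free_rhs(params: MLNeuronParams) -> Callable:
    def rhs(t, y):
        return ml_derivatives((y[0], y[1]), params)

    return rhs


_DEFAULT_INITIAL = (-0.2, 0.1)


def intrinsic_period(
    params: MLNeuronParams,
    *,
    discard: int = 5,
    n_cycles: int = 10,
    horizon: float = 2000.0,
    rtol: float = 1e-8,
    sample_dt: float = 0.02,
    initial: Sequence[float] = _DEFAULT_INITIAL,
) -> PeriodEstimate:
    """Free-running period: mean interspike interval after a transient.

    ``discard`` initial cycles are dropped and up to ``n_cycles`` intervals
    averaged.  Raises :class:`NotOscillatingError` if fewer than
    ``discard + n_cycles + 1`` spikes occur within ``horizon``.
    """
    traj = integrate(
        _free_rhs(params), initial, horizon, rtol=rtol, sample_dt=sample_dt
    )
    train = detect_spikes(traj)
    needed = discard + n_cycles + 1
    if len(train) < needed:
        raise NotOscillatingError(
            f"only {len(train)} spikes in horizon {horizon} "
            f"(need {needed}); neuron not oscillating at I0={params.I0}"
        )
    isi = train.intervals()[discard : discard + n_cycles]
    return PeriodEstimate(
        period=float(isi.mean()), spread=float(isi.std()), n_cycles=len(isi)
    )


#: Default bias-current bracket for the type-1 set: the oscillatory window
#: between the saddle-node onset (~0.0695) and depolarization block.
DEFAULT_BIAS_BRACKET = (0.0694, 0.0745)


def calibrate_bias(
    params: MLNeuronParams,
    target_period: float,
    bracket: tuple[float, float] = DEFAULT_BIAS_BRACKET,
    *,
    tol: float = 0.05,
    period_kwargs: dict | None = None,
) -> float:
    """Bias current I0 whose free-running period matches ``target_period``.

    Exploits the class-I f-I curve: period decreases monotonically with I0,
    so a bracketing root search on period(I0) - target converges.  The
    returned I0 satisfies ``|period(I0) - target| <= tol``.
    """
    kw = dict(period_kwargs or {})
    lo, hi = bracket

    def period_of(I0: float) -> float:
        try:
            return intrinsic_period(params.with_bias(I0), **kw).period
        except NotOscillatingError:
            return np.inf

    p_hi = period_of(hi)
    p_lo = period_of(lo)
    if p_hi > target_period or p_lo < target_period:
        raise CalibrationError(
            f"target period {target_period} unreachable in bracket {bracket}: "
            f"period range [{p_hi:.4g}, {p_lo:.4g}]"
        )

    def residual(I0: float) -> float:
        p = period_of(I0)
        return (p if np.isfinite(p) else 1e9) - target_period

    I0 = brentq(residual, lo, hi, xtol=1e-10)
    achieved = period_of(I0)
    if abs(achieved - target_period) > tol:
        raise CalibrationError(
            f"calibration missed target: period {achieved:.4f} vs {target_period}"
        )
    return float(I0)


@dataclass
class LimitCycle:
    """One free-running cycle of a neuron, anchored at an upward crossing.

    ``state0`` is the (V, w) state at the phase reference; ``template`` a
    dense interpolant of the cycle on [0, period] used as a presynaptic
    voltage waveform.
    """

    params: MLNeuronParams
    period: float
    state0: np.ndarray
    template: Callable[[float], np.ndarray]

    def v_pre(self, tau: float) -> float:
        """Template membrane potential ``tau`` after the reference crossing.

        Outside [0, period) the neuron is represented at its cycle minimum
        (hyperpolarized, transmitter release negligible)."""
        if 0.0 <= tau < self.period:
            return float(self.template(tau)[0])
        return self.rest

    @property
    def rest(self) -> float:
        if not hasattr(self, "_rest"):
            tt = np.linspace(0.0, self.period, 400)
            self._rest = float(min(self.template(t)[0] for t in tt))
        return self._rest

    def state_at_phase(self, phase: float) -> np.ndarray:
        """Limit-cycle state at phase in [0, 1)."""
        return np.asarray(self.template((phase % 1.0) * self.period), dtype=float)


def limit_cycle(
    params: MLNeuronParams,
    *,
    settle_cycles: int = 8,
    period_hint: float | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> LimitCycle:
    """Settle onto the limit cycle and return its anchored description.

    The neuron runs free for ``settle_cycles`` periods (transient discard),
    the state at the penultimate upward crossing is refined by
    interpolation, and one further period is integrated with dense output
    to serve as the cycle template.
    """
    if period_hint is None:
        period_hint = intrinsic_period(params).period
    horizon = (settle_cycles + 1.5) * period_hint
    traj = integrate(
        _free_rhs(params), _DEFAULT_INITIAL, horizon,
        rtol=rtol, atol=atol, sample_dt=0.01,
    )
    train = detect_spikes(traj)
    if len(train) < settle_cycles:
        raise NotOscillatingError("neuron failed to settle onto a limit cycle")
    t_anchor = train.times[-2]
    y0 = traj.state_at(t_anchor)
    period = float(np.mean(train.intervals()[-3:]))
    sol = solve_ivp(
        _free_rhs(params), (0.0, period), y0,
        rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(sol.message)
    return LimitCycle(params=params, period=period, state0=y0, template=sol.sol)
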