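"""Single-stimulus phase response curves: measurement, normal form, fits.

The first-order PRC tabulates the relative change of the cycle that
contains a single perturbation, F(phi) = P1/Pi - 1 with phi = ts/Pi:
negative values are phase advances (the next spike comes earlier).  For a
class-I (SNIC) oscillator the PRC is unimodal and, near the bifurcation,
well approximated by the normal form

    F(phi) = c * (1 - cos(2*pi*phi)),

whose single coefficient ``c`` (the half-amplitude, signed) turns out to
be affine in the maximal synaptic conductance for weak coupling.  That
affine map c(g) is what :func:`calibrate_coupling_map` estimates.

Measurement is open loop: the postsynaptic neuron is settled on its limit
cycle, a single presynaptic spike -- one cycle of the presynaptic
neuron's free-running voltage, aligned so its upward zero crossing falls
at the stimulus time -- drives the kinetic synapse, and the perturbed
cycle length is read off the next spike.  A triangular current pulse is
available as an alternative stimulus shape.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from math import cos, pi, sin
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .model import (
    LimitCycle,
    MLNeuronParams,
    SynapseParams,
    NotOscillatingError,
    detect_spikes,
    integrate,
    limit_cycle,
    ml_derivatives,
    synapse_derivative,
)

__all__ = [
    "PRCTable",
    "NormalFormPRC",
    "NormalFormFit",
    "CouplingCalibration",
    "StimulusSuppressedError",
    "default_phase_grid",
    "measure_prc",
    "normal_form_value",
    "fit_normal_form",
    "calibrate_coupling_map",
    "prc_slope",
]


class StimulusSuppressedError(RuntimeError):
    """The stimulus prevented the neuron from firing within 3 cycles."""


def default_phase_grid(n: int = 50) -> np.ndarray:
    """Evenly spaced phases in [0.02, 0.98]; end points are excluded to
    avoid the causality ambiguity of a stimulus exactly at the spike."""
    return np.linspace(0.02, 0.98, n)


@dataclass
class PRCTable:
    """Tabulated first-order resetting F(phi) on a phase grid.

    Evaluation and differentiation go through a cubic-spline interpolant;
    phases outside the measured grid are refused rather than extrapolated.
    """

    phases: np.ndarray
    values: np.ndarray
    period: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.phases.ndim != 1 or self.phases.shape != self.values.shape:
            raise ValueError("phases and values must be matching 1-d arrays")
        if not np.all(np.diff(self.phases) > 0):
            raise ValueError("phases must be strictly increasing")
        if np.any(self.values <= -1.0):
            raise ValueError("resetting must satisfy F > -1 (positive period)")
        if self.period <= 0:
            raise ValueError("intrinsic period must be positive")
        self._spline = CubicSpline(self.phases, self.values, bc_type="natural")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.phases[0]), float(self.phases[-1])

    def _check(self, phi) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        lo, hi = self.domain
        eps = 1e-9
        if np.any(phi < lo - eps) or np.any(phi > hi + eps):
            raise ValueError(
                f"phase outside measured PRC domain [{lo:.3g}, {hi:.3g}]"
            )
        return np.clip(phi, lo, hi)

    def __call__(self, phi):
        out = self._spline(self._check(phi))
        return float(out) if np.isscalar(phi) or np.ndim(phi) == 0 else out

    def slope(self, phi):
        out = self._spline(self._check(phi), 1)
        return float(out) if np.isscalar(phi) or np.ndim(phi) == 0 else out

    def fmin(self) -> float:
        """Minimum of the interpolated PRC over the measured domain."""
        grid = np.linspace(*self.domain, 2001)
        return float(self._spline(grid).min())

    # --- CSV round trip -------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        header = [f"# period={self.period!r}"]
        header += [f"# {k}={v!r}" for k, v in sorted(self.meta.items())]
        df = pd.DataFrame({"phi": self.phases, "F": self.values})
        text = "\n".join(header) + "\n" + df.to_csv(index=False)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "PRCTable":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta: dict = {}
        lines = text.splitlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            key, _, val = line.lstrip("# ").partition("=")
            try:
                meta[key] = eval(val, {}, {})  # noqa: S307 - own header format
            except Exception:
                meta[key] = val
        df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
        period = float(meta.pop("period"))
        return cls(
            phases=df["phi"].to_numpy(), values=df["F"].to_numpy(),
            period=period, meta=meta,
        )


@dataclass
class NormalFormPRC:
    """SNIC normal form F(phi) = c * (1 - cos(2*pi*phi)).

    ``c`` is the signed half-amplitude (negative: pure advances, the
    excitatory type-1 shape).  F(0) = 0 and F is 1-periodic.
    """

    c: float
    period: float

    @property
    def domain(self) -> tuple[float, float]:
        return (-np.inf, np.inf)

    def __call__(self, phi):
        phi = np.asarray(phi, dtype=float)
        out = self.c * (1.0 - np.cos(2.0 * np.pi * phi))
        return float(out) if out.ndim == 0 else out

    def slope(self, phi):
        phi = np.asarray(phi, dtype=float)
        out = 2.0 * np.pi * self.c * np.sin(2.0 * np.pi * phi)
        return float(out) if out.ndim == 0 else out

    def fmin(self) -> float:
        return min(0.0, 2.0 * self.c)

    def table(self, phases: np.ndarray | None = None) -> PRCTable:
        """Sample the normal form onto a PRCTable grid."""
        if phases is None:
            phases = default_phase_grid()
        return PRCTable(
            phases=phases, values=self(phases), period=self.period,
            meta={"source": "normal_form", "c": self.c},
        )


def normal_form_value(prc: NormalFormPRC, phi: float) -> float:
    """Resetting of the normal form at phase ``phi``."""
    return prc(phi)


def _triangular_pulse(amplitude: float, duration: float) -> Callable[[float], float]:
    def pulse(tau: float) -> float:
        if not 0.0 <= tau < duration:
            return 0.0
        u = tau / duration
        return amplitude * (2.0 * u if u < 0.5 else 2.0 * (1.0 - u))

    return pulse


def measure_prc(
    post: MLNeuronParams,
    syn: SynapseParams | None,
    pre: MLNeuronParams | None,
    phases: Sequence[float] | None = None,
    *,
    stimulus: str = "synaptic",
    tri_amplitude: float | None = None,
    tri_duration: float = 2.0,
    post_cycle: LimitCycle | None = None,
    pre_cycle: LimitCycle | None = None,
    rtol: float = 1e-8,
    sample_dt: float = 0.02,
    meta: dict | None = None,
) -> PRCTable:
    """Open-loop measurement of the first-order single-stimulus PRC.

    For each phase the postsynaptic neuron starts at its phase reference
    on the limit cycle (equivalent to letting it run free for the settle
    cycles), a single stimulus is delivered at ``ts = phi * Pi``, and the
    perturbed cycle length P1 (reference crossing to next crossing) gives
    F = P1/Pi - 1.

    ``stimulus`` is ``"synaptic"`` (default: one presynaptic template
    spike driving the kinetic synapse) or ``"triangular"`` (current pulse
    of peak ``tri_amplitude`` -- positive depolarizes -- and base
    ``tri_duration``; no synapse state is integrated).

    Pass ``post_cycle``/``pre_cycle`` to reuse settled limit cycles across
    repeated measurements.
    """
    if phases is None:
        phases = default_phase_grid()
    phases = np.asarray(phases, dtype=float)
    if np.any(phases < 0.0) or np.any(phases >= 1.0):
        raise ValueError("phase grid must lie in [0, 1)")

    if post_cycle is None:
        post_cycle = limit_cycle(post)
    Pi = post_cycle.period
    y0 = post_cycle.state0

    if stimulus == "synaptic":
        if syn is None:
            raise ValueError("synaptic stimulus needs synapse parameters")
        if syn.gsyn > 0 and pre_cycle is None:
            if pre is None:
                raise ValueError("synaptic stimulus needs a presynaptic neuron")
            pre_cycle = limit_cycle(pre)
    elif stimulus == "triangular":
        if tri_amplitude is None:
            raise ValueError("triangular stimulus needs an explicit amplitude")
    else:
        raise ValueError(f"unknown stimulus shape {stimulus!r}")

    values = np.empty_like(phases)
    for k, phi in enumerate(phases):
        ts = phi * Pi
        if stimulus == "synaptic" and syn.gsyn > 0:
            P1 = _perturbed_period_synaptic(
                post, syn, post_cycle, pre_cycle, ts, rtol, sample_dt
            )
        elif stimulus == "synaptic":
            P1 = _perturbed_period_current(
                post, post_cycle, lambda tau: 0.0, ts, 0.0, rtol, sample_dt
            )
        else:
            P1 = _perturbed_period_current(
                post,
                post_cycle,
                _triangular_pulse(tri_amplitude, tri_duration),
                ts,
                tri_duration,
                rtol,
                sample_dt,
            )
        values[k] = P1 / Pi - 1.0

    info = {"stimulus": stimulus}
    if stimulus == "synaptic":
        info.update(gsyn=syn.gsyn, Esyn=syn.Esyn)
    else:
        info.update(amplitude=tri_amplitude, duration=tri_duration)
    info.update(meta or {})
    return PRCTable(phases=phases, values=values, period=Pi, meta=info)


def _first_spike(traj, t_end: float, Pi: float) -> float:
    train = detect_spikes(traj)
    times = train.times[train.times > 1e-6]
    if len(times) == 0:
        raise StimulusSuppressedError(
            f"no spike within {t_end:.1f} time units (3 cycles) after the stimulus"
        )
    return float(times[0])


def _perturbed_period_synaptic(
    post, syn, post_cycle, pre_cycle, ts, rtol, sample_dt
) -> float:
    Pi = post_cycle.period
    rest = pre_cycle.rest

    def rhs(t, y):
        V, w, s = y
        tau = t - ts
        v_pre = pre_cycle.v_pre(tau) if tau >= 0.0 else rest
        i_syn = syn.gsyn * s * (V - syn.Esyn)
        dV, dw = ml_derivatives((V, w), post, i_syn)
        return (dV, dw, synapse_derivative(s, v_pre, syn))

    t_end = ts + 3.0 * Pi
    traj = integrate(
        rhs, (post_cycle.state0[0], post_cycle.state0[1], 0.0), t_end,
        rtol=rtol, sample_dt=sample_dt, max_step=1.0,
    )
    return _first_spike(traj, t_end, Pi)


def _perturbed_period_current(
    post, post_cycle, pulse, ts, duration, rtol, sample_dt
) -> float:
    Pi = post_cycle.period

    def rhs(t, y):
        i_stim = -pulse(t - ts)  # positive pulse depolarizes
        return ml_derivatives((y[0], y[1]), post, i_stim)

    t_end = ts + 3.0 * Pi
    traj = integrate(
        rhs, post_cycle.state0, t_end, rtol=rtol, sample_dt=sample_dt,
        max_step=max(0.25 * duration, 0.25) if duration > 0 else np.inf,
    )
    return _first_spike(traj, t_end, Pi)


@dataclass
class NormalFormFit:
    """Least-squares normal-form coefficient with residual RMS."""

    c: float
    rms: float
    period: float

    def prc(self) -> NormalFormPRC:
        return NormalFormPRC(c=self.c, period=self.period)


def fit_normal_form(table: PRCTable) -> NormalFormFit:
    """Fit F(phi) = c*(1 - cos(2*pi*phi)) to a measured table.

    The period is held at the table's; the single linear coefficient has
    the closed-form least-squares solution c = <F, u>/<u, u> with
    u = 1 - cos(2*pi*phi).
    """
    if len(table.phases) < 5:
        raise ValueError("need at least 5 points to fit the normal form")
    u = 1.0 - np.cos(2.0 * np.pi * table.phases)
    denom = float(u @ u)
    c = float(table.values @ u) / denom if denom > 0 else 0.0
    resid = table.values - c * u
    return NormalFormFit(c=c, rms=float(np.sqrt(np.mean(resid**2))), period=table.period)


@dataclass
class CouplingCalibration:
    """Affine map c(g) = slope*g + intercept for one synapse pathway."""

    slope: float
    intercept: float
    label: str = ""
    n_points: int = 0

    def c_of_g(self, g: float) -> float:
        return self.slope * g + self.intercept

    def g_of_c(self, c: float) -> float:
        return (c - self.intercept) / self.slope


def calibrate_coupling_map(
    gs: Sequence[float], fitted_cs: Sequence[float], label: str = ""
) -> CouplingCalibration:
    """Ordinary least-squares affine fit of normal-form c against g."""
    gs = np.asarray(gs, dtype=float)
    cs = np.asarray(fitted_cs, dtype=float)
    if len(np.unique(gs)) < 3:
        raise ValueError("insufficient points: need >= 3 distinct g values")
    slope, intercept = np.polyfit(gs, cs, 1)
    return CouplingCalibration(
        slope=float(slope), intercept=float(intercept), label=label, n_points=len(gs)
    )


def prc_slope(table: PRCTable | NormalFormPRC, phi: float):
    """dF/dphi of the smooth interpolant (spline for tables, analytic for
    the normal form); extrapolation beyond a table's grid is refused."""
    return table.slope(phi)
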