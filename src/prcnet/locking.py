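"""Existence of phase-locked modes in the three-neuron loop network.

Topology: neuron 1 (pacemaker, period P1i) excites neuron 2 (slave,
P2i) through g12; neuron 2 excites the interneuron 3 (P3i) through g23;
neuron 3 feeds inhibition back onto neuron 2 through g32.  In the locked
pattern the slave receives two inputs per cycle -- the inhibition at
t2sa, the excitation at t2sb -- and recovers for t2r before firing.

Steady state requires every neuron to complete its (reset) cycle in one
master period:

    P2i * (1 + F2(2)(t2sa*, t2sb*)) = P1i
    P3i * (1 + F3(1)((P1i - t2sa*)/P3i)) = P1i

The second equation decouples: t2sa* solves
F3((P1i - t2sa*)/P3i) = P1i/P3i - 1, which for an excitatory (all
negative) F3 demands P1i < P3i < P1i/(1 + F3_min).  Substituting into the
first gives, with the inhibition factor alpha = 1 + F2_inh(t2sa*/P2i),

    F2_exc(t2sb*/(P2i*alpha)) = P1i/(P2i*alpha) - 1.

With the SNIC normal form F3 = c23*(1 - cos(2*pi*phi)) the first
condition inverts in closed form:
cos(2*pi*(P1i - t2sa*)/P3i) = 1 - (P1i/P3i - 1)/c23, which also bounds
the minimum coupling |c23| >= (1 - P1i/P3i)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import acos, pi
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import MLNeuronParams, SynapseParams
from .prc import CouplingCalibration, NormalFormPRC, PRCTable

__all__ = [
    "NetworkConfig",
    "PhaseLockedMode",
    "NoSolutionError",
    "DegenerateSolutionError",
    "solve_t2sa",
    "analytic_t2sa",
    "existence_bounds",
    "solve_t2sb",
    "solve_modes",
    "minimum_coupling",
    "mode_surface",
]


class NoSolutionError(RuntimeError):
    """The fixed-point residual has no root in the admissible domain."""


class DegenerateSolutionError(RuntimeError):
    """The residual is identically ~0: every point is a formal root."""


@dataclass
class NetworkConfig:
    """Three calibrated neurons plus the three synapses of the loop."""

    neuron1: MLNeuronParams
    neuron2: MLNeuronParams
    neuron3: MLNeuronParams
    syn12: SynapseParams  # 1 -> 2, excitatory
    syn23: SynapseParams  # 2 -> 3, excitatory
    syn32: SynapseParams  # 3 -> 2, inhibitory
    P1i: float = 60.0
    P2i: float = 70.0
    P3i: float = 80.0

    @property
    def periods(self) -> tuple[float, float, float]:
        return (self.P1i, self.P2i, self.P3i)


@dataclass
class PhaseLockedMode:
    """Steady stimulus/recovery times of the locked firing pattern."""

    t2sa: float
    t2sb: float
    alpha: float
    P1i: float
    branch: int = 0
    residuals: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if not self.t2sa < self.t2sb:
            raise ValueError("mode must order the two inputs: t2sa < t2sb")

    @property
    def ts3(self) -> float:
        """Interneuron stimulus time; equals P1i - t2sa at steady state."""
        return self.P1i - self.t2sa

    @property
    def t2r(self) -> float:
        """Recovery time; equals P1i - t2sb by construction."""
        return self.P1i - self.t2sb


PRCLike = Callable[[float], float]


def _bracketed_roots(
    residual: Callable[[float], float],
    lo: float,
    hi: float,
    n_grid: int = 2000,
    xtol: float = 1e-12,
) -> list[float]:
    """All sign-change roots of ``residual`` on (lo, hi): grid then brentq."""
    if hi <= lo:
        return []
    grid = np.linspace(lo, hi, n_grid + 1)
    vals = np.array([residual(g) for g in grid])
    roots: list[float] = []
    for i in range(n_grid):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0.0:
            roots.append(float(brentq(residual, grid[i], grid[i + 1], xtol=xtol)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def _domain_phase(prc) -> tuple[float, float]:
    lo, hi = getattr(prc, "domain", (-np.inf, np.inf))
    return lo, hi


def solve_t2sa(F3: PRCLike, P1i: float, P3i: float) -> list[float]:
    """All roots of F3((P1i - t2sa)/P3i) = P1i/P3i - 1 with t2sa in (0, P1i).

    The residual is scanned on a fine grid (step ~P1i/2000) restricted to
    the PRC's phase domain and each sign change is bisected.  Raises
    :class:`NoSolutionError` when the target level is out of reach.
    """
    target = P1i / P3i - 1.0
    lo_phi, hi_phi = _domain_phase(F3)
    # t2sa in (0, P1i) and (P1i - t2sa)/P3i inside the PRC domain
    lo = max(0.0, P1i - hi_phi * P3i)
    hi = min(P1i, P1i - lo_phi * P3i)

    def residual(t: float) -> float:
        return float(F3((P1i - t) / P3i)) - target

    roots = _bracketed_roots(residual, lo + 1e-9 * P1i, hi - 1e-9 * P1i)
    if not roots:
        raise NoSolutionError(
            f"no phase-locked t2sa: level P1i/P3i - 1 = {target:.4g} is "
            "outside the range of the interneuron PRC"
        )
    return sorted(roots)


def analytic_t2sa(
    c23: float, P1i: float, P3i: float
) -> list[tuple[float, int]]:
    """Closed-form roots under the normal form, with branch labels.

    Inverts cos(2*pi*(P1i - t2sa)/P3i) = 1 - (P1i/P3i - 1)/c23 and keeps
    the roots with t2sa in (0, P1i).  Returns an empty list when the
    right-hand side leaves [-1, 1] (no locked mode).
    """
    if c23 == 0.0:
        return []
    rhs = 1.0 - (P1i / P3i - 1.0) / c23
    if rhs < -1.0 or rhs > 1.0:
        return []
    theta = acos(rhs)  # in [0, pi]
    out: list[tuple[float, int]] = []
    for k in range(-3, 4):
        for sign, tag in ((+1, 0), (-1, 1)):
            phi3 = sign * theta / (2.0 * pi) + k
            t2sa = P1i - phi3 * P3i
            if 0.0 < t2sa < P1i:
                out.append((float(t2sa), 2 * k + tag))
    out.sort(key=lambda rt: rt[0])
    return out


def existence_bounds(F3_min: float, P1i: float) -> tuple[float, float]:
    """Admissible interneuron periods (P1i, P1i/(1 + F3_min)).

    ``F3_min`` is the (negative) minimum of the interneuron's excitatory
    PRC -- the strongest possible relative shortening.  Raises
    ``ValueError`` when F3_min >= 0 (empty interval)."""
    if F3_min >= 0.0:
        raise ValueError("empty interval: excitatory PRC must have F3_min < 0")
    return (P1i, P1i / (1.0 + F3_min))


def solve_t2sb(
    F2_inh: PRCLike,
    F2_exc: PRCLike,
    P1i: float,
    P2i: float,
    t2sa: float,
    *,
    zero_tol: float = 1e-12,
) -> list[float]:
    """Roots of F2_exc(t2sb/(P2i*alpha)) = P1i/(P2i*alpha) - 1.

    ``alpha = 1 + F2_inh(t2sa/P2i)`` is the period stretch left by the
    first (inhibitory) input.  Roots are sought in
    (t2sa, min(P1i, alpha*P2i)).  A residual that is identically ~0
    (e.g. zero excitation with P1i = alpha*P2i) raises
    :class:`DegenerateSolutionError` instead of returning an arbitrary
    root.
    """
    alpha = 1.0 + float(F2_inh(t2sa / P2i))
    Pa = alpha * P2i
    target = P1i / Pa - 1.0
    lo_phi, hi_phi = _domain_phase(F2_exc)
    lo = max(t2sa, lo_phi * Pa)
    hi = min(P1i, hi_phi * Pa, Pa)
    if hi <= lo:
        raise NoSolutionError("empty search interval for t2sb")

    def residual(t: float) -> float:
        return float(F2_exc(t / Pa)) - target

    probe = np.linspace(lo + 1e-9 * P1i, hi - 1e-9 * P1i, 101)
    if max(abs(residual(t)) for t in probe) < zero_tol:
        raise DegenerateSolutionError(
            "residual identically ~0: t2sb undetermined at this configuration"
        )
    roots = _bracketed_roots(residual, lo + 1e-9 * P1i, hi - 1e-9 * P1i)
    if not roots:
        raise NoSolutionError(
            f"no phase-locked t2sb for t2sa={t2sa:.4g} (alpha={alpha:.6g})"
        )
    return sorted(roots)


def _mode_residuals(
    mode_t2sa: float, mode_t2sb: float, F2_inh, F2_exc, F3, P1i, P2i, P3i
) -> tuple[float, float]:
    from .compose import compose_two

    r2 = (
        P2i * (1.0 + compose_two(F2_inh, F2_exc, mode_t2sa, mode_t2sb, P2i).resetting)
        - P1i
    )
    r3 = P3i * (1.0 + float(F3((P1i - mode_t2sa) / P3i))) - P1i
    return r2, r3


def solve_modes(
    F2_inh: PRCLike,
    F2_exc: PRCLike,
    F3: PRCLike,
    P1i: float,
    P2i: float,
    P3i: float,
    *,
    residual_tol: float = 1e-8,
) -> list[PhaseLockedMode]:
    """Enumerate candidate phase-locked modes (all root combinations).

    Each returned mode re-satisfies both steady-state residuals to
    ``residual_tol``; candidates whose t2sb root does not exceed t2sa are
    dropped.  Modes are ordered by (t2sa, t2sb) with ``branch`` indexing
    that order.
    """
    modes: list[PhaseLockedMode] = []
    for ta in solve_t2sa(F3, P1i, P3i):
        try:
            tbs = solve_t2sb(F2_inh, F2_exc, P1i, P2i, ta)
        except (NoSolutionError, DegenerateSolutionError):
            continue
        alpha = 1.0 + float(F2_inh(ta / P2i))
        for tb in tbs:
            if tb <= ta:
                continue
            r2, r3 = _mode_residuals(ta, tb, F2_inh, F2_exc, F3, P1i, P2i, P3i)
            if max(abs(r2), abs(r3)) > residual_tol:
                raise RuntimeError(
                    f"mode candidate failed residual re-check: |r2|={abs(r2):.2e}, "
                    f"|r3|={abs(r3):.2e}"
                )
            modes.append(
                PhaseLockedMode(
                    t2sa=ta, t2sb=tb, alpha=alpha, P1i=P1i, residuals=(r2, r3)
                )
            )
    for i, m in enumerate(modes):
        m.branch = i
    return modes


def minimum_coupling(
    period_ratio: float,
    calibration: CouplingCalibration,
    *,
    g_max: float = 1.0,
) -> float:
    """Smallest g23 that can lock an interneuron slower by ``period_ratio``.

    The normal-form existence bound requires the PRC amplitude to cover
    the needed shortening: |c23(g23)| >= (1 - 1/period_ratio)/2 with
    c23 < 0.  Solved through the affine calibration; returns ``inf`` when
    no g <= g_max reaches the bound.
    """
    if period_ratio <= 1.0:
        raise ValueError("period ratio P3i/P1i must exceed 1")
    needed = -(1.0 - 1.0 / period_ratio) / 2.0  # required (negative) c23
    if calibration.slope >= 0.0:
        return float("inf")
    g = (needed - calibration.intercept) / calibration.slope
    g = max(g, 0.0)
    return float(g) if g <= g_max else float("inf")


def mode_surface(
    P3i_values: Sequence[float],
    g23_values: Sequence[float],
    *,
    P1i: float,
    P2i: float,
    g12: float,
    g32: float,
    cal12: CouplingCalibration,
    cal23: CouplingCalibration,
    cal32: CouplingCalibration,
    stable_only: bool = True,
) -> pd.DataFrame:
    """Sweep (P3i, g23): the primary-branch locked mode per grid point.

    Normal-form PRCs are synthesized through the affine c(g) calibrations
    (fast enough for dense sweeps).  The primary branch is the
    smallest-(t2sa, t2sb) mode that the return map classifies as stable
    (set ``stable_only=False`` to take the first candidate regardless).
    Per-point failures are recorded as missing values, not raised.

    Returns a long-format frame with columns P3i, g23, t2sa, t2sb, t2r,
    exists.
    """
    from .stability import classify, mode_slopes, build_matrix

    F2_inh = NormalFormPRC(c=cal32.c_of_g(g32), period=P2i)
    F2_exc = NormalFormPRC(c=cal12.c_of_g(g12), period=P2i)
    rows = []
    for P3i in P3i_values:
        for g23 in g23_values:
            F3 = NormalFormPRC(c=cal23.c_of_g(g23), period=P3i)
            entry = {
                "P3i": P3i, "g23": g23,
                "t2sa": np.nan, "t2sb": np.nan, "t2r": np.nan, "exists": False,
            }
            try:
                modes = solve_modes(F2_inh, F2_exc, F3, P1i, P2i, P3i)
            except (NoSolutionError, DegenerateSolutionError):
                modes = []
            chosen = None
            for m in modes:
                if not stable_only:
                    chosen = m
                    break
                slopes = mode_slopes(m, F2_inh, F2_exc, F3, P2i, P3i)
                res = build_matrix(
                    slopes.m2a, slopes.m2b, slopes.m3,
                    float(F2_exc(slopes.phi2b)), slopes.phi2b,
                )
                if res.verdict == "stable":
                    chosen = m
                    break
            if chosen is not None:
                entry.update(
                    t2sa=chosen.t2sa, t2sb=chosen.t2sb, t2r=chosen.t2r, exists=True
                )
            rows.append(entry)
    return pd.DataFrame(rows)
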