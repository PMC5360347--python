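"""Linear stability of a phase-locked mode via the cycle-to-cycle map.

Perturbing the steady stimulus times, delta[n] = (dt2sa, dt2sb)[n], and
linearizing the two coupled timing recursions yields delta[n+1] = A
delta[n] with

    A = [[ (1-m3)(1-b),  (m3-1)*m2b ],
         [     -b,        1 - m2b   ]],   b = m2a*(1 + F2exc(phi2b*) - m2b*phi2b*)

where m2a, m2b, m3 are PRC slopes dF/dphi at the steady phases
phi2a* = t2sa*/P2i, phi2b* = t2sb*/(P2i*alpha) and phi3* = ts3*/P3i
(m2a from the inhibitory PRC, m2b from the excitatory one, m3 from the
interneuron's).  This matrix was re-derived here from the Jacobian of the
nonlinear timing map (exposed as :func:`timing_map_step` for direct
cross-checks).

The mode is stable iff both eigenvalues of A lie strictly inside the unit
circle; in trace/determinant coordinates this is the classical triangle
P(-1) = 1 + Tr + Det > 0, P(1) = 1 - Tr + Det > 0 for real roots and
Det < 1 for complex ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .locking import PhaseLockedMode

__all__ = [
    "ModeSlopes",
    "StabilityResult",
    "mode_slopes",
    "build_matrix",
    "classify",
    "iterate_map",
    "timing_map_step",
    "numerical_jacobian",
    "stability_of_mode",
]

PRCLike = Callable[[float], float]


class ModeSlopes(NamedTuple):
    m2a: float
    m2b: float
    m3: float
    phi2a: float
    phi2b: float
    phi3: float


@dataclass
class StabilityResult:
    """Return-map linearization and its verdict."""

    a11: float
    a12: float
    a21: float
    a22: float
    b: float
    trace: float
    det: float
    eigenvalues: tuple[complex, complex]
    verdict: str  # stable | unstable | marginal
    root_type: str  # real | complex

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])

    @property
    def spectral_radius(self) -> float:
        return max(abs(self.eigenvalues[0]), abs(self.eigenvalues[1]))


def mode_slopes(
    mode: PhaseLockedMode,
    F2_inh: PRCLike,
    F2_exc: PRCLike,
    F3: PRCLike,
    P2i: float,
    P3i: float,
) -> ModeSlopes:
    """PRC slopes at the steady phases of a locked mode.

    Raises whatever domain error the PRCs raise when a steady phase lies
    outside a measured table's grid.
    """
    phi2a = mode.t2sa / P2i
    phi2b = mode.t2sb / (P2i * mode.alpha)
    phi3 = mode.ts3 / P3i
    return ModeSlopes(
        m2a=float(F2_inh.slope(phi2a)),
        m2b=float(F2_exc.slope(phi2b)),
        m3=float(F3.slope(phi3)),
        phi2a=phi2a,
        phi2b=phi2b,
        phi3=phi3,
    )


def classify(
    trace: float, det: float, *, marginal_tol: float = 1e-6
) -> tuple[str, str]:
    """Verdict ("stable" | "unstable" | "marginal") and root type.

    Complex-conjugate roots (Det > Tr^2/4) are stable iff Det < 1; real
    roots iff both lie inside the unit interval, equivalent to
    P(-1) > 0 and P(1) > 0 with |Tr| bounded.  A spectral radius within
    ``marginal_tol`` of 1 is reported as "marginal".
    """
    disc = trace * trace / 4.0 - det
    if disc < 0.0:
        root_type = "complex"
        lam = trace / 2.0 + 1j * np.sqrt(-disc)
        radius = abs(lam)
    else:
        root_type = "real"
        sq = np.sqrt(disc)
        radius = max(abs(trace / 2.0 + sq), abs(trace / 2.0 - sq))
    if abs(radius - 1.0) <= marginal_tol:
        verdict = "marginal"
    else:
        verdict = "stable" if radius < 1.0 else "unstable"
    return verdict, root_type


def build_matrix(
    m2a: float, m2b: float, m3: float, F2b_at_mode: float, phi2b: float
) -> StabilityResult:
    """Assemble the linearized return map from slopes at the mode.

    ``F2b_at_mode`` is the excitatory PRC value F2exc(phi2b*) entering the
    coefficient b.
    """
    b = m2a * (1.0 + F2b_at_mode - m2b * phi2b)
    a11 = (1.0 - m3) * (1.0 - b)
    a12 = (m3 - 1.0) * m2b
    a21 = -b
    a22 = 1.0 - m2b
    trace = a11 + a22
    det = a11 * a22 - a12 * a21
    lam = np.linalg.eigvals(np.array([[a11, a12], [a21, a22]]))
    verdict, root_type = classify(trace, det)
    return StabilityResult(
        a11=a11, a12=a12, a21=a21, a22=a22, b=b,
        trace=trace, det=det,
        eigenvalues=(complex(lam[0]), complex(lam[1])),
        verdict=verdict, root_type=root_type,
    )


def iterate_map(
    matrix: np.ndarray, delta0: tuple[float, float], n_steps: int
) -> np.ndarray:
    """Iterate delta[n+1] = A delta[n]; rows are successive perturbations.

    The brute-force oracle behind :func:`classify`: the norm decays
    geometrically at the spectral radius for a stable map.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    A = np.asarray(matrix, dtype=float)
    out = np.empty((n_steps + 1, 2))
    out[0] = delta0
    for n in range(n_steps):
        out[n + 1] = A @ out[n]
    return out


def timing_map_step(
    t2sa: float,
    t2sb: float,
    F2_inh: PRCLike,
    F2_exc: PRCLike,
    F3: PRCLike,
    P1i: float,
    P2i: float,
    P3i: float,
) -> tuple[float, float]:
    """One step of the exact nonlinear cycle-to-cycle timing map.

    Advances (t2sa, t2sb)[n] -> [n+1] using the two-stimulus composition
    for the slave and the single-stimulus resetting for the interneuron.
    A fixed point of this map is a phase-locked mode; its numerical
    Jacobian is the independent check on :func:`build_matrix`.
    """
    alpha = 1.0 + float(F2_inh(t2sa / P2i))
    Pa = P2i * alpha
    P2 = Pa * (1.0 + float(F2_exc(t2sb / Pa)))
    t2sb_next = t2sb + P1i - P2
    ts3 = t2sb - t2sa + P1i - t2sb_next
    P3 = P3i * (1.0 + float(F3(ts3 / P3i)))
    t2sa_next = P3 - ts3 + 0.0
    return t2sa_next, t2sb_next


def numerical_jacobian(
    mode: PhaseLockedMode,
    F2_inh: PRCLike,
    F2_exc: PRCLike,
    F3: PRCLike,
    P1i: float,
    P2i: float,
    P3i: float,
    h: float = 1e-5,
) -> np.ndarray:
    """Central-difference Jacobian of the timing map at the mode."""
    x0 = np.array([mode.t2sa, mode.t2sb])
    J = np.empty((2, 2))
    for j in range(2):
        xp, xm = x0.copy(), x0.copy()
        xp[j] += h
        xm[j] -= h
        fp = timing_map_step(xp[0], xp[1], F2_inh, F2_exc, F3, P1i, P2i, P3i)
        fm = timing_map_step(xm[0], xm[1], F2_inh, F2_exc, F3, P1i, P2i, P3i)
        J[:, j] = (np.asarray(fp) - np.asarray(fm)) / (2.0 * h)
    return J


def stability_of_mode(
    mode: PhaseLockedMode,
    F2_inh: PRCLike,
    F2_exc: PRCLike,
    F3: PRCLike,
    P2i: float,
    P3i: float,
) -> StabilityResult:
    """Convenience: slopes at the mode, then the assembled verdict."""
    s = mode_slopes(mode, F2_inh, F2_exc, F3, P2i, P3i)
    return build_matrix(s.m2a, s.m2b, s.m3, float(F2_exc(s.phi2b)), s.phi2b)
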