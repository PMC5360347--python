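"""Fixed-point existence: roots, bounds, closed form, sweeps."""

import numpy as np
import pytest

from prcnet.compose import compose_two
from prcnet.locking import (
    DegenerateSolutionError,
    NoSolutionError,
    analytic_t2sa,
    existence_bounds,
    minimum_coupling,
    mode_surface,
    solve_modes,
    solve_t2sa,
    solve_t2sb,
)
from prcnet.prc import CouplingCalibration, NormalFormPRC


def zero(phi):
    return 0.0


class TestSolveT2sa:
    def test_equal_periods_root_at_multiples(self):
        """P1i -> P3i: no resetting is needed and the roots collapse onto
        the multiples t2sa* = k*P1i (exactly at the boundary when equal,
        so probe just above the limit)."""
        assert analytic_t2sa(-0.1, 60.0, 60.0) == []  # boundary roots only
        roots = [r for r, _ in analytic_t2sa(-0.1, 60.0, 60.006)]
        assert min(roots) < 1.0 and max(roots) > 59.0

    def test_excitatory_needs_slower_interneuron(self):
        """P1i > P3i with an all-advance PRC admits no locked mode."""
        F3 = NormalFormPRC(c=-0.1, period=50.0)
        with pytest.raises(NoSolutionError):
            solve_t2sa(F3, 60.0, 50.0)

    def test_strong_coupling_limit(self):
        """|c23| -> large: the root approaches t2sa* = P1i + k*P3i."""
        roots = analytic_t2sa(-200.0, 60.0, 80.0)
        ts = np.array([r for r, _ in roots])
        # k = -1 branch inside (0, P1i): t2sa ~ P1i - P3i + P3i = ... check
        # nearest-to-limit root: distance to {P1i - P3i*k} set
        candidates = np.array([60.0 - 80.0, 60.0, 60.0 + 80.0])
        dist = min(abs(t - c) for t in ts for c in candidates)
        assert dist < 1.0

    def test_analytic_empty_when_cosine_out_of_range(self):
        assert analytic_t2sa(-0.01, 60.0, 80.0) == []  # needs |c| >= 0.125

    def test_numeric_matches_analytic(self):
        c23, P1i, P3i = -0.19, 60.0, 80.0
        F3 = NormalFormPRC(c=c23, period=P3i)
        numeric = solve_t2sa(F3, P1i, P3i)
        analytic = sorted(r for r, _ in analytic_t2sa(c23, P1i, P3i))
        assert numeric == pytest.approx(analytic, abs=1e-6)

    def test_numeric_matches_analytic_randomized(self, rng):
        """100 random normal-form configurations: same root multisets."""
        checked = 0
        for _ in range(1000):
            if checked >= 100:
                break
            P1i = rng.uniform(40.0, 80.0)
            P3i = P1i * rng.uniform(1.05, 1.8)
            c23 = -rng.uniform(0.01, 0.45)
            analytic = sorted(r for r, _ in analytic_t2sa(c23, P1i, P3i))
            # skip configurations without interior solutions
            if not analytic:
                continue
            F3 = NormalFormPRC(c=c23, period=P3i)
            try:
                numeric = solve_t2sa(F3, P1i, P3i)
            except NoSolutionError:
                # all analytic roots sit on the domain boundary
                boundary = [
                    r for r in analytic
                    if min(r, P1i - r) < 1e-6 * P1i
                ]
                assert len(boundary) == len(analytic)
                continue
            interior = [r for r in analytic if 1e-6 * P1i < r < P1i * (1 - 1e-6)]
            assert numeric == pytest.approx(interior, abs=1e-6)
            checked += 1


class TestExistenceBounds:
    def test_quarter_reset_bounds(self):
        lo, hi = existence_bounds(-0.25, 60.0)
        assert (lo, hi) == (60.0, pytest.approx(80.0))

    def test_half_reset_bounds(self):
        assert existence_bounds(-0.5, 60.0)[1] == pytest.approx(120.0)

    def test_empty_for_nonnegative_minimum(self):
        with pytest.raises(ValueError):
            existence_bounds(0.0, 60.0)


class TestSolveT2sb:
    def test_reduces_to_single_input_when_alpha_is_one(self):
        """Zero inhibition: alpha = 1 and the condition collapses to the
        single-input fixed point of the excitatory PRC."""
        F2_exc = NormalFormPRC(c=-0.093, period=70.0)
        roots = solve_t2sb(zero, F2_exc, 60.0, 70.0, 10.0)
        for t in roots:
            assert F2_exc(t / 70.0) == pytest.approx(60.0 / 70.0 - 1.0, abs=1e-9)

    def test_no_excitation_no_solution(self):
        with pytest.raises(NoSolutionError):
            solve_t2sb(zero, zero, 60.0, 70.0, 10.0)

    def test_degenerate_configuration_reported(self):
        # alpha = 1 and P1i = P2i: residual identically zero
        with pytest.raises(DegenerateSolutionError):
            solve_t2sb(zero, zero, 70.0, 70.0, 10.0)


class TestSolveModes:
    def test_residuals_re_verified(self):
        F2_inh = NormalFormPRC(c=0.0147, period=70.0)
        F2_exc = NormalFormPRC(c=-0.093, period=70.0)
        F3 = NormalFormPRC(c=-0.19, period=80.0)
        modes = solve_modes(F2_inh, F2_exc, F3, 60.0, 70.0, 80.0)
        assert modes
        for m in modes:
            r2 = 70.0 * (
                1.0 + compose_two(F2_inh, F2_exc, m.t2sa, m.t2sb, 70.0).resetting
            ) - 60.0
            r3 = 80.0 * (1.0 + F3((60.0 - m.t2sa) / 80.0)) - 60.0
            assert abs(r2) < 1e-8 and abs(r3) < 1e-8
            # bookkeeping identities hold by construction
            assert m.t2r == pytest.approx(60.0 - m.t2sb)
            assert m.ts3 == pytest.approx(60.0 - m.t2sa)
            assert 0 < m.t2sa < m.t2sb


class TestMinimumCoupling:
    # affine map with negligible intercept, slope ~ -6.96 per the
    # measured interneuron calibration
    CAL = CouplingCalibration(slope=-6.9555, intercept=-0.0005, label="c23")

    def test_threshold_ratio_one_plus(self):
        """As P3i/P1i -> 1+ the needed amplitude -> 0: the minimum g is
        where c23 first turns negative."""
        g = minimum_coupling(1.0001, self.CAL)
        assert g == pytest.approx(self.CAL.g_of_c(0.0), abs=1e-3)

    def test_ratio_three_halves(self):
        assert minimum_coupling(1.5, self.CAL) == pytest.approx(0.024, abs=5e-4)

    def test_ratio_two(self):
        assert minimum_coupling(2.0, self.CAL) == pytest.approx(0.036, abs=5e-4)

    def test_unreachable_is_inf(self):
        assert minimum_coupling(1.5, self.CAL, g_max=0.01) == np.inf

    def test_wrong_sign_slope_is_inf(self):
        cal = CouplingCalibration(slope=2.0, intercept=0.0)
        assert minimum_coupling(1.5, cal) == np.inf


class TestModeSurface:
    CALS = dict(
        cal12=CouplingCalibration(slope=-6.1733, intercept=-0.0003),
        cal23=CouplingCalibration(slope=-6.9555, intercept=-0.0005),
        cal32=CouplingCalibration(slope=7.2764, intercept=0.0002),
    )

    def _surface(self, P2i=70.0, g12=0.015):
        return mode_surface(
            np.linspace(55.0, 100.0, 6),
            np.linspace(0.01, 0.05, 5),
            P1i=60.0, P2i=P2i, g12=g12, g32=0.002, **self.CALS,
        )

    def test_no_modes_for_fast_interneuron(self):
        frame = self._surface()
        assert not frame.loc[frame.P3i <= 60.0, "exists"].any()

    def test_stronger_excitation_widens_domain_and_delays_t2sb(self):
        weak = self._surface(g12=0.012)
        strong = self._surface(g12=0.05)
        assert strong["exists"].sum() >= weak["exists"].sum()
        both = weak["exists"] & strong["exists"]
        assert (
            strong.loc[both, "t2sb"].to_numpy()
            > weak.loc[both, "t2sb"].to_numpy()
        ).all()

    def test_matched_periods_widen_domain(self):
        hetero = self._surface(P2i=70.0)
        homo = self._surface(P2i=60.0)
        assert homo["exists"].sum() >= hetero["exists"].sum()
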