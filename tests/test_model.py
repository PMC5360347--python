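"""Neuron/synapse dynamics, integration, spike detection, calibration."""

import numpy as np
import pytest

from prcnet.model import (
    CalibrationError,
    MLNeuronParams,
    NotOscillatingError,
    SpikeTrain,
    SynapseParams,
    Trajectory,
    calibrate_bias,
    detect_spikes,
    integrate,
    intrinsic_period,
    limit_cycle,
    ml_derivatives,
    synapse_derivative,
    transmitter,
    w_inf,
)


class TestDerivatives:
    def test_gate_fixed_point(self, type1_params):
        """dw/dt vanishes exactly when w sits at its steady-state value."""
        V = -0.123
        _, dw = ml_derivatives((V, w_inf(V, type1_params)), type1_params)
        assert dw == pytest.approx(0.0, abs=1e-15)

    def test_half_activation_is_midpoint(self, type1_params):
        assert w_inf(type1_params.Vw_half, type1_params) == pytest.approx(0.5)

    def test_all_currents_off(self):
        """With conductances ~0 and no drive the membrane is stationary."""
        p = MLNeuronParams(gCa=1e-300, gK=1e-300, gLeak=1e-300, I0=0.0)
        dV, _ = ml_derivatives((0.1, 0.3), p, i_syn=0.0)
        assert dV == pytest.approx(0.0, abs=1e-12)

    def test_synaptic_current_subtracted(self, type1_params):
        dV0, _ = ml_derivatives((0.0, 0.2), type1_params, i_syn=0.0)
        dV1, _ = ml_derivatives((0.0, 0.2), type1_params, i_syn=0.25)
        assert dV0 - dV1 == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "s, v_pre, expected",
        [
            (1.0, 5.0, -1.5),  # saturated transmitter, full occupancy: pure decay
            (0.0, -5.0, 0.0),  # no transmitter, no channels: nothing happens
        ],
    )
    def test_synapse_limits(self, s, v_pre, expected):
        syn = SynapseParams(gsyn=0.01)
        assert synapse_derivative(s, v_pre, syn) == pytest.approx(expected, abs=1e-9)

    def test_transmitter_midpoint(self):
        syn = SynapseParams(gsyn=0.01)
        assert transmitter(syn.T_half, syn) == pytest.approx(0.5)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MLNeuronParams(gCa=-1.0)
        with pytest.raises(ValueError):
            SynapseParams(gsyn=-0.01)


class TestIntegrate:
    def test_harmonic_oscillator_round_trip(self):
        """x' = y, y' = -x returns to the start after one period 2*pi."""
        traj = integrate(lambda t, y: (y[1], -y[0]), (1.0, 0.0), 2 * np.pi,
                         rtol=1e-10, atol=1e-12)
        assert traj.y[:, -1] == pytest.approx([1.0, 0.0], abs=1e-6)

    def test_zero_duration(self):
        traj = integrate(lambda t, y: (0.0,), (3.0,), 0.0)
        assert traj.t.tolist() == [0.0]
        assert traj.y[0, 0] == 3.0

    def test_ml_period_is_stable(self, type1_params):
        """Successive interspike intervals of the free neuron agree to <0.1%."""
        traj = integrate(
            lambda t, y: ml_derivatives((y[0], y[1]), type1_params),
            (-0.2, 0.1), 800.0,
        )
        isi = detect_spikes(traj).intervals()[5:]
        assert len(isi) >= 5
        assert isi.std() / isi.mean() < 1e-3


class TestDetectSpikes:
    def test_sine_crossings(self):
        t = np.linspace(0.0, 30.0, 30001)
        train = detect_spikes((t, np.sin(2 * np.pi * t / 10.0)))
        # upward crossings at 10 and 20 (t=0 starts at the threshold itself)
        assert train.times == pytest.approx([10.0, 20.0], abs=1e-4)

    def test_constant_below_threshold_is_empty(self):
        t = np.linspace(0, 10, 11)
        assert len(detect_spikes((t, np.full(11, -0.3)))) == 0

    def test_linear_interpolation_between_two_samples(self):
        train = detect_spikes((np.array([1.0, 2.0]), np.array([-0.1, 0.1])))
        assert train.times == pytest.approx([1.5])

    def test_idempotent(self, type1_params):
        traj = integrate(
            lambda t, y: ml_derivatives((y[0], y[1]), type1_params),
            (-0.2, 0.1), 400.0,
        )
        a = detect_spikes(traj).times
        b = detect_spikes(traj).times
        assert np.array_equal(a, b)

    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([1.0, 1.0, 2.0]))


class TestIntrinsicPeriod:
    def test_default_bias_oscillates(self, type1_params):
        est = intrinsic_period(type1_params)
        assert est.period > 0
        assert est.spread / est.period < 1e-3

    def test_below_rheobase_raises(self, type1_params):
        with pytest.raises(NotOscillatingError):
            intrinsic_period(type1_params.with_bias(0.060), horizon=600.0)

    def test_initial_condition_invariance(self, type1_params):
        """After the transient the period does not depend on the start state."""
        a = intrinsic_period(type1_params, initial=(-0.2, 0.1)).period
        b = intrinsic_period(type1_params, initial=(-0.4, 0.02)).period
        assert abs(a - b) / a < 5e-3

    def test_period_monotone_in_bias(self, type1_params):
        """Class I f-I curve: period decreases with the bias current."""
        periods = [
            intrinsic_period(type1_params.with_bias(I0)).period
            for I0 in (0.0698, 0.0702, 0.0710, 0.0730)
        ]
        assert all(a > b for a, b in zip(periods, periods[1:]))

    def test_bounded_gates_along_trajectory(self, type1_params):
        traj = integrate(
            lambda t, y: ml_derivatives((y[0], y[1]), type1_params),
            (-0.2, 0.1), 400.0,
        )
        w = traj.y[1]
        assert w.min() >= 0.0 and w.max() <= 1.0


class TestCalibration:
    def test_round_trip(self, type1_params):
        """Calibrating to the period of a known bias recovers that bias."""
        target = intrinsic_period(type1_params.with_bias(0.0702)).period
        I0 = calibrate_bias(type1_params, target)
        assert I0 == pytest.approx(0.0702, abs=2e-5)

    def test_three_targets(self, network):
        """The calibrated network neurons hit 60/70/80 within tolerance."""
        for params, target in zip(
            (network.neuron1, network.neuron2, network.neuron3), (60, 70, 80)
        ):
            assert intrinsic_period(params).period == pytest.approx(target, abs=0.05)

    def test_unreachable_target(self, type1_params):
        with pytest.raises(CalibrationError):
            calibrate_bias(type1_params, 5.0)


class TestLimitCycle:
    def test_anchor_is_phase_reference(self, limit_cycles):
        """The stored state sits at the upward zero crossing (V ~ 0)."""
        for lc in limit_cycles.values():
            assert abs(lc.state0[0]) < 1e-4

    def test_template_is_periodic(self, limit_cycles):
        lc = limit_cycles[1]
        start = lc.template(0.0)
        end = lc.template(lc.period)
        assert start == pytest.approx(end, abs=1e-4)
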